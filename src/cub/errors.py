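"""Exception hierarchy with stable exit codes for the command line."""


class CubError(Exception):
    """Base class for all pipeline errors."""

    exit_code = 1


class FormatError(CubError):
    """Malformed or unparseable input (GenBank/FASTA), or an annotation
    that cannot yield a valid coding sequence."""

    exit_code = 3


class ConfigurationError(CubError):
    """Inconsistent or invalid run settings (e.g. mixed genetic codes
    without an explicit override)."""

    exit_code = 4


class ComputationError(CubError):
    """A statistic is undefined for the given input (empty composition,
    zero-variance regression, no valid ENC class, ...)."""

    exit_code = 5
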