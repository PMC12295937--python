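"""Relative synonymous codon usage and Wright's effective number of codons.

RSCU for codon *c* of an amino acid with family size :math:`n_a`:

.. math:: \\mathrm{RSCU}_c = n_a \\, x_c / \\sum_{c' \\in \\mathrm{family}} x_{c'}

so values sum to the family size within each family; 1 means uniform
synonymous usage, values above 1 mark preferred codons.

Wright's effective number of codons (ENC, also written Nc) summarizes
how far a gene departs from uniform synonymous usage. Per family the
codon homozygosity is estimated as

.. math:: \\hat F = (n \\sum_i p_i^2 - 1) / (n - 1)

with *n* the family's codon count and :math:`p_i` the within-family
codon frequencies; ENC sums family counts over degeneracy classes *k*:

.. math:: \\mathrm{ENC} = \\sum_k N_k / \\bar F_k

The class decomposition is derived from the active genetic code rather
than hard-coded for the standard code: the invertebrate mitochondrial
code (table 5) has twelve 2-fold, six 4-fold, one 6-fold and one 8-fold
family (ENC = 12/F̄2 + 6/F̄4 + 1/F̄6 + 1/F̄8, maximum 62), while the
standard code contributes its two 1-fold families directly (maximum 61).
A ``codonw_compat`` mode forces standard-code classes for comparison
with CodonW output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import ComputationError
from .genetic_code import GeneticCode, get_code, STANDARD
from .seq_io import CodonCounts


@dataclass
class RSCUTable:
    """Per-codon RSCU for one gene or one concatenated genome.

    ``rscu`` holds NaN for codons of amino acids never observed
    (missing, not zero).
    """

    scope: str
    aa: dict[str, str]
    counts: dict[str, int]
    rscu: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"codon": c, "aa": self.aa[c], "count": self.counts[c], "rscu": self.rscu[c]}
            for c in sorted(self.aa, key=lambda c: (self.aa[c], c))
        ]
        return pd.DataFrame(rows)

    def high_frequency(self) -> frozenset[str]:
        """Codons with RSCU strictly greater than 1."""
        return frozenset(c for c, v in self.rscu.items() if not math.isnan(v) and v > 1.0)


def rscu(counts: CodonCounts, code: GeneticCode) -> RSCUTable:
    """RSCU of every sense codon of the active code."""
    aa_map: dict[str, str] = {}
    count_map: dict[str, int] = {}
    rscu_map: dict[str, float] = {}
    for aa, family in code.families.items():
        fam_total = sum(counts[c] for c in family)
        n_a = len(family)
        for codon in family:
            aa_map[codon] = aa
            count_map[codon] = counts[codon]
            rscu_map[codon] = (
                math.nan if fam_total == 0 else n_a * counts[codon] / fam_total
            )
    return RSCUTable(scope=counts.scope, aa=aa_map, counts=count_map, rscu=rscu_map)


@dataclass
class HighFrequencyReport:
    """Shared and per-species-unique preferred-codon (RSCU > 1) sets."""

    per_species: dict[str, frozenset[str]]
    shared: frozenset[str]
    unique: dict[str, frozenset[str]]

    def third_bases(self, codons: frozenset[str]) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in codons:
            out[c[2]] = out.get(c[2], 0) + 1
        return out


def high_frequency_codons(tables: dict[str, RSCUTable]) -> HighFrequencyReport:
    """Intersect and difference the RSCU>1 codon sets of several species."""
    if not tables:
        raise ValueError("at least one RSCU table required")
    per_species = {sp: t.high_frequency() for sp, t in tables.items()}
    sets = list(per_species.values())
    shared = frozenset.intersection(*sets)
    unique = {
        sp: frozenset(s - frozenset.union(*(o for k, o in per_species.items() if k != sp)))
        if len(per_species) > 1
        else s
        for sp, s in per_species.items()
    }
    return HighFrequencyReport(per_species=per_species, shared=shared, unique=unique)


@dataclass
class EncResult:
    """Wright ENC with per-class homozygosity diagnostics."""

    enc: float
    class_f: dict[int, float]  # degeneracy class -> mean homozygosity F̄_k
    n_codons: int
    imputed_classes: frozenset[int] = field(default_factory=frozenset)
    max_enc: int = 61

    @property
    def exceeds_max(self) -> bool:
        """Finite-sample estimates can exceed the code's sense-codon count;
        the value is reported unclamped with this flag raised."""
        return self.enc > self.max_enc


def _family_homozygosity(family_counts: list[int]) -> tuple[int, float] | None:
    """(n, F̂) for one synonymous family; None when n < 2 (F undefined)."""
    n = sum(family_counts)
    if n < 2:
        return None
    s = sum((x / n) ** 2 for x in family_counts)
    return n, (n * s - 1.0) / (n - 1.0)


def enc(counts: CodonCounts, code: GeneticCode, codonw_compat: bool = False) -> EncResult:
    """Wright's ENC generalized to the degeneracy classes of ``code``.

    Families with fewer than 2 counted codons are skipped; a degeneracy
    class left with no valid family (or a non-positive mean F) gets its
    F̄ imputed from the nearest available classes, Wright's
    F̄3 ≈ (F̄2 + F̄4)/2 fallback generalized, and is recorded in
    ``imputed_classes``.

    ``codonw_compat`` scores the counts against standard-code families
    (codons that are stops under the standard code are ignored), for
    comparison with CodonW's output.
    """
    class_code = get_code(STANDARD) if codonw_compat else code
    per_class_f: dict[int, list[float]] = {k: [] for k in class_code.class_sizes}
    n_used = 0
    for family in class_code.families.values():
        fam_counts = [counts[c] for c in family]
        hf = _family_homozygosity(fam_counts)
        if len(family) == 1:
            continue  # 1-fold families contribute N_1 directly (F = 1)
        if hf is None:
            continue
        n, f = hf
        n_used += n
        per_class_f[len(family)].append(f)

    class_f: dict[int, float] = {}
    missing: list[int] = []
    for k in sorted(per_class_f):
        if k == 1:
            class_f[k] = 1.0
            continue
        fs = per_class_f[k]
        mean_f = sum(fs) / len(fs) if fs else float("nan")
        if fs and mean_f > 0:
            class_f[k] = mean_f
        else:
            missing.append(k)
    if len(missing) == len([k for k in per_class_f if k > 1]):
        raise ComputationError("ENC undefined: no degeneracy class has a valid family")

    imputed: set[int] = set()
    available = sorted(k for k in class_f if k > 1)
    for k in missing:
        below = max((a for a in available if a < k), default=None)
        above = min((a for a in available if a > k), default=None)
        if below is not None and above is not None:
            class_f[k] = (class_f[below] + class_f[above]) / 2.0
        else:
            class_f[k] = class_f[below if below is not None else above]
        imputed.add(k)

    total = 0.0
    for k, n_k in sorted(class_code.class_sizes.items()):
        total += n_k / class_f[k]
    return EncResult(
        enc=total,
        class_f=class_f,
        n_codons=n_used,
        imputed_classes=frozenset(imputed),
        max_enc=class_code.n_sense_codons,
    )


def enc_expected(gc3s: float) -> float:
    """Null-model ENC at a given GC3s, under purely compositional
    (mutational) codon usage:

    ENC = 2 + GC3s + 29 / [GC3s^2 + (1 - GC3s)^2]

    Points well below this curve indicate selection on codon usage.
    """
    if not 0.0 <= gc3s <= 1.0:
        raise ValueError(f"GC3s must lie in [0, 1], got {gc3s}")
    return 2.0 + gc3s + 29.0 / (gc3s**2 + (1.0 - gc3s) ** 2)
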