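"""Read annotated mitogenomes, extract frame-correct sense-strand CDS,
and read/write the flat formats the pipeline consumes and emits.

Coordinates are GenBank 1-based inclusive at the file boundary and
0-based half-open internally (Biopython's convention), which keeps
origin-spanning features on circular genomes representable without
special cases.

Mitochondrial annotations carry two quirks the extractor must handle:

* genes on the light strand are stored reverse-complemented in the
  deposited sequence and must be flipped back to sense orientation;
* some CDS end in ``T`` or ``TA`` — the TAA stop is completed
  post-transcriptionally by 3' polyadenylation of the mRNA, so the
  extractor pads with A residues and flags the gene.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature

from .errors import FormatError
from .genetic_code import GeneticCode, STOP_SYMBOL

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse-complement of an upper-case DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Feature:
    """One annotated gene: internal 0-based half-open coordinates."""

    gene: str
    type: str  # CDS | tRNA | rRNA
    start: int
    end: int
    strand: str  # '+' | '-'
    location: object = field(compare=False, default=None)  # Biopython location


@dataclass
class AnnotatedGenome:
    accession: str
    sequence: str
    features: list[Feature]
    circular: bool = True
    declared_tables: frozenset = frozenset()  # transl_table qualifiers seen

    @property
    def length(self) -> int:
        return len(self.sequence)

    def cds_features(self) -> list[Feature]:
        return [f for f in self.features if f.type == "CDS"]

    @property
    def coding_length(self) -> int:
        """Total annotated CDS span in bp (overlaps counted once each)."""
        return sum(f.end - f.start for f in self.cds_features())

    @property
    def coding_fraction(self) -> float:
        return coding_fraction(self.coding_length, self.length)


def coding_fraction(cds_length: int, genome_length: int) -> float:
    """Protein-coding fraction of a genome, in percent."""
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    return 100.0 * cds_length / genome_length


@dataclass(frozen=True)
class CodingSequence:
    """One in-frame sense-strand CDS with provenance."""

    gene: str
    nt: str
    strand: str = "+"
    stop_completed: bool = False

    @property
    def start_codon(self) -> str:
        return self.nt[:3]

    @property
    def stop_codon(self) -> str:
        return self.nt[-3:]

    @property
    def codons(self) -> list[str]:
        return [self.nt[i : i + 3] for i in range(0, len(self.nt), 3)]

    @property
    def sense_codons(self) -> list[str]:
        """Codons excluding the terminal stop."""
        return self.codons[:-1]


_FEATURE_TYPES = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}


def read_genbank(path: str | Path) -> AnnotatedGenome:
    """Parse a GenBank flat file into an :class:`AnnotatedGenome`.

    Captures CDS/tRNA/rRNA features with strand; other feature types are
    ignored. Raises :class:`FormatError` on missing sequence or an
    unparseable record.
    """
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises bare ValueError on bad files
        raise FormatError(f"{path}: not a readable single-record GenBank file: {exc}") from exc
    seq = str(record.seq).upper()
    if not seq or set(seq) == {"N"}:
        raise FormatError(f"{path}: record {record.id} has no usable sequence (missing ORIGIN?)")
    features: list[Feature] = []
    declared: set[int] = set()
    for feat in record.features:
        ftype = _FEATURE_TYPES.get(feat.type)
        if ftype is None:
            continue
        for t in feat.qualifiers.get("transl_table", []):
            declared.add(int(t))
        gene = _feature_name(feat)
        if feat.location is None:
            raise FormatError(f"{path}: feature {gene or feat.type} has no parseable location")
        strand = "-" if feat.location.strand == -1 else "+"
        features.append(
            Feature(
                gene=gene,
                type=ftype,
                start=int(feat.location.start),
                end=int(feat.location.end),
                strand=strand,
                location=feat.location,
            )
        )
    topology = (record.annotations.get("topology") or "").lower()
    return AnnotatedGenome(
        accession=record.id,
        sequence=seq,
        features=features,
        circular=topology != "linear",
        declared_tables=frozenset(declared),
    )


def _feature_name(feat: SeqFeature) -> str:
    for key in ("gene", "product", "locus_tag"):
        if key in feat.qualifiers:
            return feat.qualifiers[key][0]
    return feat.type


def extract_cds(genome: AnnotatedGenome, feature: Feature, code: GeneticCode) -> CodingSequence:
    """Extract one CDS to sense orientation and complete a truncated stop.

    Light-strand ('-') features are reverse-complemented. A trailing
    partial codon is padded with A only when it is a prefix of TAA
    (``T`` or ``TA``), mirroring stop completion by mRNA polyadenylation;
    any other frame remainder is a hard error, as is an internal stop.
    """
    if feature.type != "CDS":
        raise ValueError(f"feature {feature.gene} is not a CDS")
    if feature.location is not None:
        nt = str(feature.location.extract(Seq(genome.sequence)))
    else:
        nt = genome.sequence[feature.start : feature.end]
        if feature.strand == "-":
            nt = revcomp(nt)
    nt = nt.upper()

    stop_completed = False
    remainder = len(nt) % 3
    if remainder:
        tail = nt[-remainder:]
        if tail in ("T", "TA"):
            nt += "A" * (3 - remainder)
            stop_completed = True
        else:
            raise FormatError(
                f"{feature.gene}: length remainder {remainder} with tail {tail!r} "
                "is not completable to a TAA stop"
            )
    cds = CodingSequence(
        gene=feature.gene, nt=nt, strand=feature.strand, stop_completed=stop_completed
    )
    validate_cds(cds, code)
    return cds


def validate_cds(cds: CodingSequence, code: GeneticCode) -> None:
    """Check frame, terminal stop, and absence of internal stops."""
    if len(cds.nt) % 3:
        raise FormatError(f"{cds.gene}: length {len(cds.nt)} not divisible by 3")
    aa = "".join(
        code.codon_to_aa.get(c, "X") for c in cds.codons
    )  # codons with N translate as X
    if not aa.endswith(STOP_SYMBOL):
        raise FormatError(f"{cds.gene}: no terminal stop codon ({cds.stop_codon})")
    if STOP_SYMBOL in aa[:-1]:
        pos = aa.index(STOP_SYMBOL)
        raise FormatError(f"{cds.gene}: internal stop codon at codon {pos + 1}")


def extract_all_cds(genome: AnnotatedGenome, code: GeneticCode) -> list[CodingSequence]:
    return [extract_cds(genome, f, code) for f in genome.cds_features()]


@dataclass
class CodonCounts:
    """Codon -> count table for one gene or one concatenated genome."""

    counts: collections.Counter
    scope: str = ""

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        merged = collections.Counter(self.counts)
        merged.update(other.counts)
        return CodonCounts(counts=merged, scope=f"{self.scope}+{other.scope}")

    def __getitem__(self, codon: str) -> int:
        return self.counts.get(codon, 0)


def count_codons(
    cds: CodingSequence,
    code: GeneticCode,
    include_start: bool = True,
    exclude_ambiguous: bool = True,
) -> CodonCounts:
    """Count sense codons of one CDS.

    The terminal stop never enters the table. The start codon is counted
    as the sense codon it is read as (TTG as Leu, ATT as Ile) unless
    ``include_start`` is off. Codons containing ambiguous bases are
    dropped by default.
    """
    codons = cds.sense_codons
    if not include_start:
        codons = codons[1:]
    counter: collections.Counter = collections.Counter()
    for codon in codons:
        if exclude_ambiguous and set(codon) - set("ACGT"):
            continue
        if codon in code.stop_codons:
            continue  # defensive: stops never enter counts
        counter[codon] += 1
    return CodonCounts(counts=counter, scope=cds.gene)


def sum_counts(counts: Iterable[CodonCounts], scope: str = "genome") -> CodonCounts:
    merged: collections.Counter = collections.Counter()
    for c in counts:
        merged.update(c.counts)
    return CodonCounts(counts=merged, scope=scope)


# -- FASTA ----------------------------------------------------------------


def read_cds_fasta(path: str | Path, code: GeneticCode) -> list[CodingSequence]:
    """Read per-gene CDS from a multi-FASTA (header word = gene name)."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        cds = CodingSequence(gene=rec.id, nt=str(rec.seq).upper())
        validate_cds(cds, code)
        out.append(cds)
    if not out:
        raise FormatError(f"{path}: no FASTA records")
    return out


def write_cds_fasta(cds_list: Iterable[CodingSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for cds in cds_list:
            fh.write(f">{cds.gene}\n")
            for i in range(0, len(cds.nt), width):
                fh.write(cds.nt[i : i + width] + "\n")
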