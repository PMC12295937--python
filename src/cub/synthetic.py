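"""Synthetic mitogenome-like CDS sets with known mutation-pressure and
selection parameters.

The generator draws codons i.i.d. from a closed-form distribution over
the sense codons of the active genetic code:

* **mutation pressure** — a codon with ``k`` G/C bases and ``3 - k``
  A/T bases gets mutational weight ``g**k * (1 - g)**(3 - k)``, where
  ``g`` is the probability that a mutationally free base is G or C;
* **selection** — one preferred codon per synonymous family has its
  weight multiplied by ``1 + s``.

Because codons are independent, the expected composition (GC1/GC2/GC3,
GC12, GC3s) is computable exactly by enumerating the 62 (table 5) sense
codons, which gives every downstream diagnostic an analytic oracle:
``s = 0`` with ``g`` varying across genes reproduces the
mutation-dominated regime (neutrality slope near 1, genes on the
ENC expected curve), while large ``s`` pins third positions to the
preferred set (A/T-ending by default), dropping ENC below the curve
and flattening the slope.

All randomness flows from a single seed through per-gene
``SeedSequence`` spawn keys, so per-gene draws are order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .genetic_code import GeneticCode, get_code, INVERTEBRATE_MITO
from .seq_io import CodingSequence, revcomp

# canonical mitochondrial protein-coding gene complement
GENE_NAMES = (
    "cox1",
    "cox2",
    "cox3",
    "cob",
    "nad1",
    "nad2",
    "nad3",
    "nad4",
    "nad4l",
    "nad5",
    "nad6",
    "atp6",
    "atp8",
)
DEFAULT_LIGHT_STRAND = frozenset({"cox3", "atp6", "atp8", "nad3"})
DEFAULT_INCOMPLETE_STOP = frozenset({"atp6", "nad1", "nad3", "nad4l"})


def default_preferred_codons(code: GeneticCode) -> dict[str, str]:
    """One preferred codon per family: the first T-ending codon, else the
    first A-ending (so the preferred set is A/T-ending throughout)."""
    preferred = {}
    for aa, family in code.families.items():
        fam = sorted(family)
        pick = next((c for c in fam if c.endswith("T")), None)
        if pick is None:
            pick = next((c for c in fam if c.endswith("A")), fam[0])
        preferred[aa] = pick
    return preferred


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic mitogenome.

    ``gc_pressure`` may be overridden per gene via ``gc_pressure_per_gene``
    (length ``n_genes``), which is how mutation-regime test genomes spread
    GC across genes.
    """

    n_genes: int = 13
    codons_per_gene: tuple[int, int] = (50, 600)
    table_id: int = INVERTEBRATE_MITO
    gc_pressure: float = 0.35
    selection_strength: float = 0.0
    gc_pressure_per_gene: tuple[float, ...] | None = None
    light_strand_genes: frozenset[str] = DEFAULT_LIGHT_STRAND
    incomplete_stop_genes: frozenset[str] = DEFAULT_INCOMPLETE_STOP
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.gc_pressure < 1.0:
            raise ValueError("gc_pressure must lie in (0, 1)")
        if self.selection_strength < 0:
            raise ValueError("selection_strength must be >= 0")
        if self.gc_pressure_per_gene is not None and len(self.gc_pressure_per_gene) != self.n_genes:
            raise ValueError("gc_pressure_per_gene must have n_genes entries")

    @property
    def code(self) -> GeneticCode:
        return get_code(self.table_id)

    @property
    def preferred_codons(self) -> dict[str, str]:
        return default_preferred_codons(self.code)

    def gene_name(self, i: int) -> str:
        return GENE_NAMES[i] if i < len(GENE_NAMES) else f"gene{i + 1}"

    def gene_g(self, i: int) -> float:
        if self.gc_pressure_per_gene is not None:
            return self.gc_pressure_per_gene[i]
        return self.gc_pressure


def _gc_count(codon: str) -> int:
    return sum(1 for b in codon if b in "GC")


def codon_weights(
    code: GeneticCode, g: float, s: float = 0.0, preferred: dict[str, str] | None = None
) -> dict[str, float]:
    """Normalized sampling distribution over sense codons."""
    if preferred is None:
        preferred = default_preferred_codons(code)
    pref_set = set(preferred.values())
    w = {}
    for codon in sorted(code.sense_codons):
        k = _gc_count(codon)
        weight = g**k * (1.0 - g) ** (3 - k)
        if codon in pref_set:
            weight *= 1.0 + s
        w[codon] = weight
    total = sum(w.values())
    return {c: v / total for c, v in w.items()}


def expected_composition(
    code: GeneticCode, g: float, s: float = 0.0, preferred: dict[str, str] | None = None
) -> dict[str, float]:
    """Exact expected positional GC of the codon distribution — the
    analytic oracle for composition-level diagnostics."""
    w = codon_weights(code, g, s, preferred)
    gc1 = sum(p for c, p in w.items() if c[0] in "GC")
    gc2 = sum(p for c, p in w.items() if c[1] in "GC")
    gc3 = sum(p for c, p in w.items() if c[2] in "GC")
    gc3s = sum(p for c, p in w.items() if c[2] in "GC" and code.is_degenerate(c))
    degen = sum(p for c, p in w.items() if code.is_degenerate(c))
    return {
        "GC1": gc1,
        "GC2": gc2,
        "GC3": gc3,
        "GC12": (gc1 + gc2) / 2.0,
        "GCall": (gc1 + gc2 + gc3) / 3.0,
        "GC3s": gc3s / degen,
    }


def _gene_rng(seed: int, gene_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(gene_index,)))


def sample_gene(
    spec: SyntheticSpec,
    length: int | None = None,
    gene_index: int = 0,
    g: float | None = None,
    s: float | None = None,
) -> CodingSequence:
    """Draw one gene of ``length`` codons in total (start + body + stop).

    The first codon is a start codon of the active code, the appended
    stop is TAA/TAG; genes listed in ``incomplete_stop_genes`` are
    flagged ``stop_completed`` (the genome emitter writes their stop
    truncated to TA/T). Body codons are i.i.d. from
    :func:`codon_weights`, so sampled genes never contain internal stops.
    """
    rng = _gene_rng(spec.seed, gene_index)
    code = spec.code
    if g is None:
        g = spec.gene_g(gene_index)
    if s is None:
        s = spec.selection_strength
    if length is None:
        length = int(rng.integers(spec.codons_per_gene[0], spec.codons_per_gene[1] + 1))
    if length < 2:
        raise ValueError("length must be at least 2 codons (start + stop)")
    weights = codon_weights(code, g, s, spec.preferred_codons)
    codons = sorted(weights)
    probs = np.array([weights[c] for c in codons])
    body = rng.choice(codons, size=length - 2, p=probs)
    starts = sorted(code.start_codons & code.sense_codons)
    start = starts[int(rng.integers(len(starts)))]
    name = spec.gene_name(gene_index)
    incomplete = name in spec.incomplete_stop_genes
    stop = "TAA" if incomplete else ["TAA", "TAG"][int(rng.integers(2))]
    nt = start + "".join(body) + stop
    strand = "-" if name in spec.light_strand_genes else "+"
    return CodingSequence(gene=name, nt=nt, strand=strand, stop_completed=incomplete)


def sample_genome(spec: SyntheticSpec) -> tuple[list[CodingSequence], pd.DataFrame]:
    """All genes of one synthetic genome plus the per-gene truth table."""
    genes = []
    truth = []
    for i in range(spec.n_genes):
        cds = sample_gene(spec, gene_index=i)
        genes.append(cds)
        truth.append(
            {
                "gene": cds.gene,
                "g": spec.gene_g(i),
                "s": spec.selection_strength,
                "n_codons": len(cds.nt) // 3,
                "strand": cds.strand,
                "incomplete_stop": cds.stop_completed,
            }
        )
    return genes, pd.DataFrame(truth)


def emit_fixture_genome(spec: SyntheticSpec, path: str | Path) -> Path:
    """Write a circular GenBank record with the genome's CDS features plus
    placeholder tRNA/rRNA features; byte-stable for a fixed seed.

    Light-strand genes are stored reverse-complemented with strand -1;
    incomplete-stop genes are written with their terminal stop truncated
    to TA (completable by 3' polyadenylation on extraction).
    """
    path = Path(path)
    genes, _ = sample_genome(spec)
    rng = _gene_rng(spec.seed, 10_000)  # spacer/placeholder stream

    parts: list[str] = []
    features: list[SeqFeature] = []
    pos = 0

    def spacer(n: int) -> None:
        nonlocal pos
        block = "".join(rng.choice(list("AT"), size=n))
        parts.append(block)
        pos += n

    spacer(30)
    for cds in genes:
        nt = cds.nt
        if cds.stop_completed:  # truncate the TAA stop to TA in the genome
            nt = nt[:-1]
        if cds.strand == "-":
            stored = revcomp(nt)
            strand = -1
        else:
            stored = nt
            strand = +1
        start = pos
        parts.append(stored)
        pos += len(stored)
        qualifiers = {"gene": [cds.gene], "transl_table": [str(spec.table_id)]}
        if cds.stop_completed:
            qualifiers["note"] = ["TAA stop codon is completed by the addition of 3' A residues"]
        features.append(
            SeqFeature(
                FeatureLocation(start, pos, strand=strand),
                type="CDS",
                qualifiers=qualifiers,
            )
        )
        spacer(int(rng.integers(5, 31)))

    for i in range(22):
        start = pos
        spacer(65)
        features.append(
            SeqFeature(
                FeatureLocation(start, pos, strand=-1 if i % 3 == 0 else +1),
                type="tRNA",
                qualifiers={"gene": [f"trn{i + 1}"]},
            )
        )
    for name, n in (("rrnS", 700), ("rrnL", 950)):
        start = pos
        spacer(n)
        features.append(
            SeqFeature(
                FeatureLocation(start, pos, strand=+1),
                type="rRNA",
                qualifiers={"gene": [name]},
            )
        )
    spacer(40)

    record = SeqRecord(
        Seq("".join(parts)),
        id="SYNCUB01",
        name="SYNCUB01",
        description=f"synthetic mitogenome-like record (seed={spec.seed})",
        features=features,
        annotations={
            "molecule_type": "DNA",
            "topology": "circular",
            "data_file_division": "INV",
            "date": "01-JAN-2025",
            "accessions": ["SYNCUB01"],
        },
    )
    SeqIO.write(record, str(path), "genbank")
    return path


def three_species_specs(seed: int, s_values: Sequence[float] = (0.0, 1.0, 3.0)) -> dict[str, SyntheticSpec]:
    """Three synthetic 'species' differing in selection strength, for
    multi-species analyses (shared/unique preferred codons, per-species
    regressions)."""
    base = SyntheticSpec(seed=seed)
    return {
        f"species_{chr(ord('A') + i)}": replace(base, selection_strength=s, seed=seed + i)
        for i, s in enumerate(s_values)
    }
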