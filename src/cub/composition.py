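"""Nucleotide composition at genome, gene, and codon-position resolution.

Conventions:

* proportions are taken over counted bases only — ambiguous bases (N)
  are excluded from denominators, never attributed fractionally;
* AT skew = (A - T)/(A + T), GC skew = (G - C)/(G + C);
* GC1/GC2/GC3 are GC proportions at the three codon positions over all
  sense codons (terminal stop excluded); GC12 = (GC1 + GC2)/2;
* GC3s restricts the third position to codons whose amino acid has at
  least two synonymous codons under the active genetic code — under the
  invertebrate mitochondrial code (table 5) that is every sense codon,
  under the standard code Met and Trp drop out;
* A3/T3/G3/C3 are third-position base proportions over all sense codons
  by default; ``synonymous_only=True`` reproduces the A3s/T3s/G3s/C3s
  convention of codon-usage software that restricts to degenerate codons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ComputationError
from .genetic_code import GeneticCode
from .seq_io import CodingSequence

_GC = frozenset("GC")
_AT = frozenset("AT")


@dataclass(frozen=True)
class CompositionStats:
    """Base, skew, and (for coding sequences) positional composition."""

    pA: float
    pT: float
    pC: float
    pG: float
    at_content: float
    gc_content: float
    at_skew: float
    gc_skew: float
    # positional fields — None for plain (non-codon-resolved) sequences
    GC1: float | None = None
    GC2: float | None = None
    GC3: float | None = None
    GCall: float | None = None
    GC12: float | None = None
    GC3s: float | None = None
    A3: float | None = None
    T3: float | None = None
    G3: float | None = None
    C3: float | None = None


def base_composition(seq: str) -> CompositionStats:
    """Base proportions and skews of a DNA string (N excluded)."""
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ATCG"}
    total = sum(counts.values())
    if total == 0:
        raise ComputationError("composition undefined: no unambiguous bases")
    p = {b: counts[b] / total for b in "ATCG"}
    at, gc = _skews_or_nan(p["A"], p["T"], p["C"], p["G"])
    return CompositionStats(
        pA=p["A"],
        pT=p["T"],
        pC=p["C"],
        pG=p["G"],
        at_content=p["A"] + p["T"],
        gc_content=p["G"] + p["C"],
        at_skew=at,
        gc_skew=gc,
    )


def _skews_or_nan(pA: float, pT: float, pC: float, pG: float) -> tuple[float, float]:
    """Skews with NaN (rather than an error) on a zero denominator, for
    composition summaries of skewless sequences."""
    at = (pA - pT) / (pA + pT) if pA + pT > 0 else math.nan
    gc = (pG - pC) / (pG + pC) if pG + pC > 0 else math.nan
    return at, gc


def skews_from_proportions(pA: float, pT: float, pC: float, pG: float) -> tuple[float, float]:
    """AT and GC skew from base proportions (or counts)."""
    if pA + pT <= 0 or pG + pC <= 0:
        raise ComputationError("skew undefined: zero A+T or G+C denominator")
    return (pA - pT) / (pA + pT), (pG - pC) / (pG + pC)


def skews(comp: CompositionStats) -> tuple[float, float]:
    """AT and GC skew of an already-computed composition."""
    return skews_from_proportions(comp.pA, comp.pT, comp.pC, comp.pG)


def from_proportions(pA: float, pT: float, pC: float, pG: float) -> CompositionStats:
    """Build a :class:`CompositionStats` from reported base proportions
    (e.g. a published composition) so downstream operations can run on it."""
    at, gc = skews_from_proportions(pA, pT, pC, pG)
    return CompositionStats(
        pA=pA,
        pT=pT,
        pC=pC,
        pG=pG,
        at_content=pA + pT,
        gc_content=pG + pC,
        at_skew=at,
        gc_skew=gc,
    )


def _gc_fraction(bases: list[str]) -> float:
    return sum(1 for b in bases if b in _GC) / len(bases)


def positional_gc(
    cds: CodingSequence, code: GeneticCode, synonymous_only: bool = False
) -> CompositionStats:
    """Codon-position composition of one CDS (terminal stop excluded).

    Codons containing ambiguous bases are dropped from all denominators.
    """
    codons = [
        c for c in cds.sense_codons if not (set(c) - set("ACGT")) and c not in code.stop_codons
    ]
    if not codons:
        raise ComputationError(f"{cds.gene}: no sense codons for positional composition")

    pos1 = [c[0] for c in codons]
    pos2 = [c[1] for c in codons]
    pos3 = [c[2] for c in codons]
    gc1 = _gc_fraction(pos1)
    gc2 = _gc_fraction(pos2)
    gc3 = _gc_fraction(pos3)
    gc_all = _gc_fraction(pos1 + pos2 + pos3)

    syn3 = [c[2] for c in codons if code.is_degenerate(c)]
    if not syn3:
        raise ComputationError(f"{cds.gene}: no synonymously degenerate codons for GC3s")
    gc3s = _gc_fraction(syn3)

    third = syn3 if synonymous_only else pos3
    n3 = len(third)
    a3 = third.count("A") / n3
    t3 = third.count("T") / n3
    g3 = third.count("G") / n3
    c3 = third.count("C") / n3

    base = base_composition("".join(codons))
    return CompositionStats(
        pA=base.pA,
        pT=base.pT,
        pC=base.pC,
        pG=base.pG,
        at_content=base.at_content,
        gc_content=base.gc_content,
        at_skew=base.at_skew,
        gc_skew=base.gc_skew,
        GC1=gc1,
        GC2=gc2,
        GC3=gc3,
        GCall=gc_all,
        GC12=(gc1 + gc2) / 2.0,
        GC3s=gc3s,
        A3=a3,
        T3=t3,
        G3=g3,
        C3=c3,
    )
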