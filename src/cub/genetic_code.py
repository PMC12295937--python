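"""Genetic codes with derived synonymous-family structure.

Codon-usage statistics (RSCU, ENC, GC3s) are defined relative to the
synonymous families of a genetic code, not to the codon table alone.
This module wraps an NCBI translation table (via Biopython) and derives:

* ``families`` — amino acid -> frozenset of synonymous sense codons;
* ``class_sizes`` — degeneracy class -> number of families of that size,
  the decomposition Wright's effective-number-of-codons estimator sums
  over.

The invertebrate mitochondrial code (NCBI table 5) differs from the
standard code in ways that matter here: AGA/AGG encode Ser (an 8-fold
serine family), ATA encodes Met and TGA encodes Trp (so there are no
1-fold families and 62 sense codons instead of 61).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

BASES = "TCAG"
ALL_CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)
STOP_SYMBOL = "*"


@dataclass(frozen=True)
class GeneticCode:
    """An NCBI translation table plus derived synonymous-family structure."""

    table_id: int
    codon_to_aa: dict[str, str]  # DNA triplets; stop codons map to "*"
    start_codons: frozenset[str]
    stop_codons: frozenset[str]
    families: dict[str, frozenset[str]] = field(compare=False)
    class_sizes: Counter = field(compare=False)

    @classmethod
    def from_ncbi_id(cls, table_id: int) -> "GeneticCode":
        try:
            table = CodonTable.unambiguous_dna_by_id[table_id]
        except KeyError as exc:
            raise ValueError(f"unknown NCBI translation table id {table_id}") from exc
        codon_to_aa = {c: table.forward_table[c] for c in table.forward_table}
        for stop in table.stop_codons:
            codon_to_aa[stop] = STOP_SYMBOL
        fams: dict[str, set[str]] = {}
        for codon, aa in codon_to_aa.items():
            if aa != STOP_SYMBOL:
                fams.setdefault(aa, set()).add(codon)
        families = {aa: frozenset(cods) for aa, cods in fams.items()}
        class_sizes = Counter(len(cods) for cods in families.values())
        code = cls(
            table_id=table_id,
            codon_to_aa=codon_to_aa,
            start_codons=frozenset(table.start_codons),
            stop_codons=frozenset(table.stop_codons),
            families=families,
            class_sizes=class_sizes,
        )
        code._check()
        return code

    def _check(self) -> None:
        # each sense codon in exactly one family; family sizes sum to #sense
        seen: Counter = Counter()
        for cods in self.families.values():
            seen.update(cods)
        assert all(v == 1 for v in seen.values())
        n_sense = sum(k * v for k, v in self.class_sizes.items())
        assert n_sense == len(seen) == 64 - len(self.stop_codons)

    # -- queries -----------------------------------------------------------

    @property
    def sense_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.codon_to_aa.items() if aa != STOP_SYMBOL)

    @property
    def n_sense_codons(self) -> int:
        return 64 - len(self.stop_codons)

    def family_of(self, codon: str) -> frozenset[str]:
        return self.families[self.codon_to_aa[codon]]

    def is_degenerate(self, codon: str) -> bool:
        """True when the codon's amino acid has >= 2 synonymous codons."""
        aa = self.codon_to_aa.get(codon)
        return aa is not None and aa != STOP_SYMBOL and len(self.families[aa]) >= 2

    def translate(self, nt: str) -> str:
        """Translate an in-frame DNA string; stops render as '*'."""
        if len(nt) % 3:
            raise ValueError("sequence length not a multiple of 3")
        return "".join(self.codon_to_aa[nt[i : i + 3]] for i in range(0, len(nt), 3))


@lru_cache(maxsize=None)
def get_code(table_id: int) -> GeneticCode:
    """Cached accessor for :class:`GeneticCode` instances."""
    return GeneticCode.from_ncbi_id(table_id)


INVERTEBRATE_MITO = 5
STANDARD = 1
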