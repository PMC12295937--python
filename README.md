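# cub — codon usage bias analysis for mitochondrial protein-coding genes

Animal mitochondrial genomes carry 13 protein-coding genes (PCGs) whose
synonymous codon usage is shaped by two forces: **mutation pressure**
(compositional drive, acting on all codon positions alike) and **natural
selection** (e.g. translational efficiency, acting mostly on the
degenerate third position). `cub` implements the standard battery of
diagnostics molecular evolutionists use to tell the two apart, for
researchers analysing annotated mitogenomes — plus a synthetic genome
generator with known mutation/selection parameters, so every stage of
the pipeline can be validated against analytic expectations without any
downloads.

## Statistics implemented

- **RSCU** (relative synonymous codon usage) for codon *c* of an amino
  acid with family size *n*: `RSCU_c = n · x_c / Σ x_c'` over the
  synonymous family; values > 1 mark preferred codons. High-frequency
  codon sets are intersected across species.
- **ENC / Nc** (Wright's effective number of codons): per-family codon
  homozygosity `F̂ = (n Σ p_i² − 1)/(n − 1)`, averaged within degeneracy
  classes, `ENC = Σ_k N_k / F̄_k`. The class decomposition is derived
  from the active genetic code: the invertebrate mitochondrial code
  (NCBI table 5; AGA/AGG→Ser, ATA→Met, TGA→Trp) gives
  `12/F̄₂ + 6/F̄₄ + 1/F̄₆ + 1/F̄₈` with a maximum of 62, versus 61 for
  the standard code. ENC is plotted against GC3s with the null curve
  `ENC = 2 + GC3s + 29/[GC3s² + (1 − GC3s)²]`; genes below the curve
  suggest selection.
- **PR2-bias plot**: `G3/(G3+C3)` vs `A3/(A3+T3)` per gene; (0.5, 0.5)
  is the parity-rule-2 no-bias point.
- **Neutrality plot**: per-gene GC12 (mean of first- and second-position
  GC) regressed on GC3 by OLS; slope near 1 ⇒ mutation pressure
  dominates, flat slope ⇒ selection.
- **Pearson correlations** among GC1, GC2, GC3, GCall and ENC with
  per-test two-sided p-values and significance stars
  (\* p<0.05, \*\* p<0.01, \*\*\* p<0.001).

The extractor handles the annotation quirks of real mitogenomes:
light-strand genes (reverse-complemented to sense), and incomplete stop
codons (`T`/`TA`) completed by 3′ polyadenylation, padded with A and
flagged.

## Worked example

Simulate three "species" that differ only in selection strength toward
A/T-ending preferred codons, then analyse them end to end:

```sh
python analysis/01_simulate_genomes.py --seed 1
python analysis/02_extract_cds.py
python analysis/03_codon_bias_pipeline.py
python analysis/04_regime_diagnostics.py --seed 1
```

which prints (abridged):

```
species_A: 17469 bp, 13 CDS (4 light-strand), coding fraction 80.9%
stops completed by 3' A addition: 12
high-frequency codons shared by all species: 21
  third-base breakdown: {'T': 15, 'A': 6}
species_A: mean ENC 59.8 +/- 1.3 over 13 genes
species_B: mean ENC 48.1 +/- 1.6 over 13 genes
species_C: mean ENC 38.1 +/- 0.9 over 13 genes
analytic mutation-regime neutrality slope: 0.9740
mutation (s=0, g spread 0.2-0.8): slope +0.966 +/- 0.028, mean ENC 54.7
selection (s=10, g=0.35): slope -0.020 +/- 0.371, mean ENC 25.9
selection regime shows a flatter slope and lower ENC relative to the mutation regime
```

Read: as the selection strength `s` rises (species A→C), mean ENC falls
from the no-bias ceiling toward strongly biased usage, and the shared
preferred codons all end in T/A (the preferred set). With no selection
and GC mutation pressure spread across genes, the fitted neutrality
slope (0.966) matches the generator's closed-form expectation (0.974);
strong selection at fixed mutation pressure flattens the slope to ~0 and
drops ENC below the expected curve — exactly the signatures the three
diagnostic plots are designed to read.

The same pipeline runs on real annotated genomes:

```sh
cub analyze --genbank A.gb --genbank B.gb --code 5 --out results/
```

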