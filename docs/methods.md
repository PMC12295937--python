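# Methods

## Sequence handling

GenBank coordinates are 1-based inclusive at the file boundary and
0-based half-open internally (Biopython's convention), so
origin-spanning features on circular genomes need no special casing.
Light-strand features are reverse-complemented to sense orientation on
extraction. A CDS whose length leaves a remainder of 1 or 2 is padded
with A **only** when the trailing fragment is `T` or `TA` — i.e. a
prefix of the TAA stop completed by 3′ polyadenylation of the mRNA —
and flagged `stop_completed`; any other remainder is a hard format
error, as is an internal stop after extraction. This is deliberately
conservative: silent frame repair would corrupt every downstream
statistic.

Terminal stop codons never enter codon counts, RSCU, ENC, GC3s or
third-position composition. The start codon is counted as the sense
codon it is read as (TTG as Leu, ATT as Ile), matching common
codon-usage software; `include_start=False` is exposed because
published analyses do not always state their convention. Codons
containing ambiguous bases are dropped from counts and from every
positional denominator rather than attributed fractionally.

## Composition

Skews are `(A−T)/(A+T)` and `(G−C)/(G+C)`. GC1/GC2/GC3 are GC
proportions at the three codon positions over all counted sense codons;
`GC12 = (GC1+GC2)/2` exactly; GCall is taken over all three positions
(and equals the mean of GC1–GC3 whenever no codon is excluded). GC3s
restricts the third position to codons whose amino acid has ≥ 2
synonymous codons under the active code — under the invertebrate
mitochondrial code (table 5) that is every sense codon, under the
standard code Met and Trp drop out. A3/T3/G3/C3 are computed over **all**
sense codons' third positions by default, following the plain reading
of "nucleotide proportions at the third codon position";
`synonymous_only=True` reproduces the A3s/T3s/G3s/C3s convention of
CodonW-style tools. Report tables round proportions and skews to 3
decimal places; ENC is printed to 1 decimal place and stored at full
precision.

## ENC

Wright's estimator is generalized to the degeneracy classes of the
active genetic code instead of hard-coding the standard-code
decomposition: table 5 has no 1-fold families, an 8-fold Ser family,
and 62 sense codons, so its null ceiling is 62, not 61. Numerical
choices:

- families with fewer than 2 counted codons are skipped (F̂ is
  undefined at n = 1);
- a degeneracy class with no valid family — or a non-positive mean F̂,
  which small samples can produce — has its F̄ imputed as the mean of
  the nearest available classes below and above (one-sided if only one
  exists), the classical F̄₃ ≈ (F̄₂+F̄₄)/2 fallback generalized; imputed
  classes are recorded on the result;
- estimates above the code's sense-codon count are reported unclamped
  with an `exceeds_max` flag, since clamping would hide the
  finite-sample origin of such values;
- a `codonw_compat` mode scores counts against standard-code classes
  (codons that are stops there are ignored) for comparison with CodonW
  output, because published ENC values rarely state which code the tool
  assumed.

The expected-curve comparison uses
`ENC = 2 + GC3s + 29/[GC3s² + (1−GC3s)²]`. The curve's constants assume
the standard code's 61 sense codons; under table 5 unbiased genes sit
up to ~1.5 units *above* it at mid GC3s, which is why per-gene
deviation, not sign alone, should be read.

## Regression and correlations

The neutrality plot regresses GC12 on GC3 (GC3 as predictor — the
universal orientation of this plot). Slope, intercept, r², two-sided
p (t distribution, n−2 df) come from closed-form simple OLS; adjusted
R² uses the one-predictor Wherry formula and negative values are
reported as-is. Pearson correlations among GC1, GC2, GC3, GCall, ENC
carry per-test two-sided p-values with no multiple-testing correction,
because the star convention they feed is per-test; zero-variance
variables yield missing entries rather than errors.

## Synthetic genomes

The generator draws codons i.i.d. over the sense codons of the active
code. A codon with k G/C bases has mutational weight
`g^k (1−g)^(3−k)` — `g` is the probability that a mutationally free
base is G or C — and one preferred codon per synonymous family has its
weight multiplied by `1 + s`. The preferred set defaults to the first
T-ending (else A-ending) codon of each family, mirroring the A/T-ending
preference typical of invertebrate mitochondria. Defaults are sized to
the real system: 13 genes named for the canonical mitochondrial PCG
complement, 50–600 codons per gene, table 5, four light-strand genes
(cox3, atp6, atp8, nad3), four genes with incomplete stops (atp6, nad1,
nad3, nad4l), genome-wide `g = 0.35` (matching the ~35% GC typical of
these genomes) and `s = 0` as the neutral baseline. All randomness
flows from a single seed through per-gene `SeedSequence` spawn keys, so
draws are order-independent and GenBank emission is byte-stable.

Because codons are independent, the expected composition under any
(g, s) is an exact enumeration over the 62 sense codons
(`expected_composition`), giving analytic oracles: with `s = 0` and `g`
spread across genes the expected neutrality slope is ~0.97 and genes
sit near the ENC null curve (the mutation-dominated regime); with large
`s` at fixed `g` the third position pins to the A/T-ending preferred
set, ENC falls below the curve and the fitted slope collapses toward 0
(the selection-dominated regime). Parameter-recovery experiments use
13 genes of 600 codons — the upper half of the real per-gene spread —
so that binomial sampling noise in per-gene GC3, which attenuates an
OLS slope on a noisy predictor, stays negligible against the
gene-resampling bootstrap interval; regime comparisons average 20
replicate genomes. A 95% percentile bootstrap legitimately misses ~1
genome in 20, so the slope-recovery check requires coverage in 2 of 3
independent genomes.

What the generator does **not** emulate: amino-acid composition of real
proteins (codons are drawn over all families at once), site-to-site and
gene-to-gene dependence, strand-asymmetric mutational spectra, tRNA
genes with real structure, and overlapping genes. Passing tests
therefore validate the statistics and the annotation plumbing, not any
claim about real selective regimes; on real data the diagnostics carry
their usual interpretive caveats.

## Pipeline conventions

Species are labelled by input file stem (accessions can repeat across
synthetic runs). All tables are TSV (UTF-8, '.' decimal); reruns with
identical settings are byte-identical, figures excluded. Inputs whose
CDS declare a `transl_table` different from the configured code raise a
configuration error unless explicitly overridden. Exit codes separate
usage (2), format (3), configuration (4) and computation (5) failures.
Figure styling is plain and deliberately not matched to any published
figure.
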