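"""Diagnostic analyses that separate mutation pressure from selection.

Three standard plots drive the inference:

* **ENC plot** — per-gene ENC against GC3s, compared with the null
  curve ``enc_expected``; genes far below the curve are candidates for
  translational selection.
* **PR2-bias plot** — G3/(G3+C3) against A3/(A3+T3); under parity rule 2
  (no strand-specific mutation or selection at the third position) genes
  sit at (0.5, 0.5).
* **Neutrality plot** — per-gene GC12 (mean of first- and
  second-position GC) regressed on GC3. A slope near 1 means the three
  codon positions respond to the same compositional (mutational) drive;
  a flat slope means selection decouples them.

A Pearson correlation matrix over {GC1, GC2, GC3, GCall, ENC} with
per-test two-sided p-values (df = n - 2) completes the panel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codon_bias import enc, enc_expected
from .composition import positional_gc
from .errors import ComputationError
from .genetic_code import GeneticCode
from .seq_io import CodingSequence, count_codons

logger = logging.getLogger(__name__)

PROFILE_VARIABLES = ("GC1", "GC2", "GC3", "GCall", "ENC")


@dataclass(frozen=True)
class GeneBiasProfile:
    """Per-gene composition/bias vector feeding all three plots."""

    gene: str
    species: str
    GC1: float
    GC2: float
    GC3: float
    GCall: float
    GC12: float
    GC3s: float
    A3: float
    T3: float
    G3: float
    C3: float
    ENC: float
    pr2_x: float | None
    pr2_y: float | None
    enc_deviation: float  # ENC - enc_expected(GC3s)


def pr2_coordinates(a3: float, t3: float, g3: float, c3: float) -> tuple[float, float]:
    """PR2-bias plot coordinates (x = G3/(G3+C3), y = A3/(A3+T3))."""
    if g3 + c3 <= 0 or a3 + t3 <= 0:
        raise ComputationError("PR2 coordinates undefined: zero G3+C3 or A3+T3")
    return g3 / (g3 + c3), a3 / (a3 + t3)


def build_profile(
    cds: CodingSequence,
    code: GeneticCode,
    species: str = "",
    include_start: bool = True,
    synonymous_only: bool = False,
    codonw_compat: bool = False,
) -> GeneBiasProfile:
    """Compute the full per-gene bias vector for one coding sequence."""
    comp = positional_gc(cds, code, synonymous_only=synonymous_only)
    counts = count_codons(cds, code, include_start=include_start)
    enc_val = enc(counts, code, codonw_compat=codonw_compat).enc
    try:
        x, y = pr2_coordinates(comp.A3, comp.T3, comp.G3, comp.C3)
    except ComputationError:
        logger.warning("%s: PR2 coordinates undefined, gene dropped from PR2 plot", cds.gene)
        x = y = None
    return GeneBiasProfile(
        gene=cds.gene,
        species=species,
        GC1=comp.GC1,
        GC2=comp.GC2,
        GC3=comp.GC3,
        GCall=comp.GCall,
        GC12=comp.GC12,
        GC3s=comp.GC3s,
        A3=comp.A3,
        T3=comp.T3,
        G3=comp.G3,
        C3=comp.C3,
        ENC=enc_val,
        pr2_x=x,
        pr2_y=y,
        enc_deviation=enc_val - enc_expected(comp.GC3s),
    )


def build_profiles(
    cds_list: Iterable[CodingSequence], code: GeneticCode, species: str = "", **kwargs
) -> list[GeneBiasProfile]:
    return [build_profile(cds, code, species=species, **kwargs) for cds in cds_list]


def profiles_frame(profiles: Iterable[GeneBiasProfile]) -> pd.DataFrame:
    return pd.DataFrame([asdict(p) for p in profiles])


@dataclass(frozen=True)
class RegressionResult:
    """Simple-OLS summary for the neutrality plot."""

    slope: float
    intercept: float
    r_squared: float
    adj_r_squared: float
    p_value: float
    n: int


def neutrality_regression(profiles: Sequence[GeneBiasProfile]) -> RegressionResult:
    """OLS of GC12 on GC3 across genes (GC3 is the predictor).

    Adjusted R² uses the one-predictor Wherry formula
    ``1 - (1 - R²)(n - 1)/(n - 2)`` and may be negative.
    """
    if len(profiles) < 3:
        raise ComputationError("neutrality regression needs at least 3 genes")
    x = np.array([p.GC3 for p in profiles], dtype=float)
    y = np.array([p.GC12 for p in profiles], dtype=float)
    if np.ptp(x) == 0:
        raise ComputationError("neutrality regression undefined: zero variance in GC3")
    fit = stats.linregress(x, y)
    n = len(x)
    r2 = fit.rvalue**2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(r2),
        adj_r_squared=float(adj),
        p_value=float(fit.pvalue),
        n=n,
    )


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson r with per-test (uncorrected) p-values and stars."""

    variables: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, v1 in enumerate(self.variables):
            for v2 in self.variables[:i]:
                rows.append(
                    {
                        "var1": v1,
                        "var2": v2,
                        "r": self.r.loc[v1, v2],
                        "p": self.p.loc[v1, v2],
                        "stars": self.stars.loc[v1, v2],
                    }
                )
        return pd.DataFrame(rows)


def correlation_matrix(
    profiles: Sequence[GeneBiasProfile], variables: Sequence[str] = PROFILE_VARIABLES
) -> CorrelationMatrix:
    """Pearson correlations among codon parameters across genes.

    Zero-variance variables yield NaN r/p for their pairs (reported as
    missing). p-values are two-sided from the t distribution with n - 2
    degrees of freedom, uncorrected for multiple testing.
    """
    if len(profiles) < 3:
        raise ComputationError("correlation matrix needs at least 3 genes")
    data = {v: np.array([getattr(p, v) for p in profiles], dtype=float) for v in variables}
    k = len(variables)
    r = np.full((k, k), np.nan)
    pv = np.full((k, k), np.nan)
    for i, v1 in enumerate(variables):
        for j, v2 in enumerate(variables):
            if i == j:
                r[i, j], pv[i, j] = 1.0, 0.0
                continue
            x, y = data[v1], data[v2]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            res = stats.pearsonr(x, y)
            r[i, j], pv[i, j] = res.statistic, res.pvalue
    r_df = pd.DataFrame(r, index=variables, columns=variables)
    p_df = pd.DataFrame(pv, index=variables, columns=variables)
    stars = p_df.map(lambda p: "" if math.isnan(p) else significance_stars(p))
    for v in variables:
        stars.loc[v, v] = ""
    return CorrelationMatrix(
        variables=tuple(variables), r=r_df, p=p_df, stars=stars
    )
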