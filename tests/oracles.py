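"""Independent brute-force transcriptions of the statistics, kept free of
any import from the package so they can serve as oracles.

Each function is a direct, unoptimized rendering of the published
formula: codon homozygosity and the effective number of codons (Wright),
RSCU, simple-OLS normal equations, and the Pearson product-moment sum
formula with its t-test.
"""

from __future__ import annotations

import math

from scipy.stats import t as t_dist


def oracle_rscu(counts: dict[str, int], families: list[set[str]]) -> dict[str, float]:
    """RSCU_c = n_a * x_c / sum over the family; NaN for unobserved families."""
    out: dict[str, float] = {}
    for family in families:
        total = sum(counts.get(c, 0) for c in family)
        for c in family:
            out[c] = math.nan if total == 0 else len(family) * counts.get(c, 0) / total
    return out


def oracle_enc(counts: dict[str, int], families: list[set[str]]) -> float:
    """Wright's ENC summed over degeneracy classes; assumes every family
    with size > 1 has at least 2 counted codons (no imputation needed)."""
    by_size: dict[int, list[float]] = {}
    n_families: dict[int, int] = {}
    for family in families:
        k = len(family)
        n_families[k] = n_families.get(k, 0) + 1
        if k == 1:
            continue
        n = sum(counts.get(c, 0) for c in family)
        if n < 2:
            continue
        s = 0.0
        for c in family:
            p = counts.get(c, 0) / n
            s += p * p
        f = (n * s - 1.0) / (n - 1.0)
        by_size.setdefault(k, []).append(f)
    enc = float(n_families.get(1, 0))
    for k, n_k in n_families.items():
        if k == 1:
            continue
        fbar = sum(by_size[k]) / len(by_size[k])
        enc += n_k / fbar
    return enc


def oracle_ols(x: list[float], y: list[float]) -> dict[str, float]:
    """Simple linear regression by the normal equations, with the
    two-sided slope t-test (df = n - 2)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((xi - mx) ** 2 for xi in x)
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    syy = sum((yi - my) ** 2 for yi in y)
    slope = sxy / sxx
    intercept = my - slope * mx
    sse = sum((yi - (intercept + slope * xi)) ** 2 for xi, yi in zip(x, y))
    r2 = 1.0 - sse / syy if syy > 0 else float("nan")
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    se_slope = math.sqrt(sse / (n - 2) / sxx)
    t_stat = slope / se_slope if se_slope > 0 else float("inf")
    p = 2.0 * t_dist.sf(abs(t_stat), n - 2)
    return {
        "slope": slope,
        "intercept": intercept,
        "r_squared": r2,
        "adj_r_squared": adj,
        "p_value": p,
        "n": n,
    }


def oracle_pearson(x: list[float], y: list[float]) -> tuple[float, float]:
    """Pearson r by explicit sums, with the two-sided t-test p-value."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    den = math.sqrt(sum((xi - mx) ** 2 for xi in x) * sum((yi - my) ** 2 for yi in y))
    r = num / den
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t_stat = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * t_dist.sf(abs(t_stat), n - 2)
    return r, p
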