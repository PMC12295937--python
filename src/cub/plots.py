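"""Figure rendering: RSCU stacked bars, ENC plot, PR2-bias plot,
neutrality plot. Styling is config-driven and deliberately plain."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .analysis import GeneBiasProfile, RegressionResult
from .codon_bias import RSCUTable, enc_expected

logger = logging.getLogger(__name__)

_FORMATS = ("svg", "png")


def _save(fig, outdir: Path, stem: str, formats: Sequence[str]) -> list[Path]:
    paths = []
    for fmt in formats:
        path = outdir / f"{stem}.{fmt}"
        fig.savefig(path, dpi=150, bbox_inches="tight")
        paths.append(path)
    plt.close(fig)
    return paths


def rscu_figure(
    tables: dict[str, RSCUTable], outdir: Path, formats: Sequence[str] = _FORMATS
) -> list[Path]:
    """Stacked per-amino-acid RSCU bars, one panel per species."""
    n = len(tables)
    fig, axes = plt.subplots(n, 1, figsize=(10, 3.2 * n), squeeze=False)
    for ax, (species, table) in zip(axes.ravel(), tables.items()):
        df = table.to_frame().dropna(subset=["rscu"])
        bottoms: dict[str, float] = {}
        aas = sorted(df["aa"].unique())
        for _, row in df.sort_values(["aa", "codon"]).iterrows():
            b = bottoms.get(row["aa"], 0.0)
            ax.bar(row["aa"], row["rscu"], bottom=b, edgecolor="white", linewidth=0.4)
            bottoms[row["aa"]] = b + row["rscu"]
        ax.set_xticks(range(len(aas)))
        ax.set_xticklabels(aas)
        ax.set_ylabel("RSCU")
        ax.set_title(species)
    fig.tight_layout()
    return _save(fig, outdir, "rscu", formats)


def enc_plot(
    profiles: Sequence[GeneBiasProfile], outdir: Path, formats: Sequence[str] = _FORMATS
) -> list[Path]:
    """ENC vs GC3s scatter with the null expected curve overlaid."""
    fig, ax = plt.subplots(figsize=(5, 4))
    grid = np.linspace(0.0, 1.0, 201)
    ax.plot(grid, [enc_expected(g) for g in grid], "k-", lw=1, label="expected")
    for species in sorted({p.species for p in profiles}):
        pts = [p for p in profiles if p.species == species]
        ax.scatter([p.GC3s for p in pts], [p.ENC for p in pts], s=18, label=species)
    ax.set_xlabel("GC3s")
    ax.set_ylabel("ENC")
    ax.set_xlim(0, 1)
    ax.legend(fontsize=7)
    return _save(fig, outdir, "enc_plot", formats)


def pr2_plot(
    profiles: Sequence[GeneBiasProfile], outdir: Path, formats: Sequence[str] = _FORMATS
) -> list[Path]:
    """PR2-bias unit square with reference lines at 0.5."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for species in sorted({p.species for p in profiles}):
        pts = [p for p in profiles if p.species == species and p.pr2_x is not None]
        ax.scatter([p.pr2_x for p in pts], [p.pr2_y for p in pts], s=18, label=species)
    ax.axhline(0.5, color="grey", lw=0.8)
    ax.axvline(0.5, color="grey", lw=0.8)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("G3 / (G3 + C3)")
    ax.set_ylabel("A3 / (A3 + T3)")
    ax.legend(fontsize=7)
    return _save(fig, outdir, "pr2_plot", formats)


def neutrality_plot(
    profiles: Sequence[GeneBiasProfile],
    regressions: dict[str, RegressionResult],
    outdir: Path,
    formats: Sequence[str] = _FORMATS,
) -> list[Path]:
    """GC12 vs GC3 scatter with per-species fitted lines and slope/adj-R²."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for species in sorted({p.species for p in profiles}):
        pts = [p for p in profiles if p.species == species]
        sc = ax.scatter([p.GC3 for p in pts], [p.GC12 for p in pts], s=18, label=species)
        reg = regressions.get(species)
        if reg is not None:
            xs = np.array([min(p.GC3 for p in pts), max(p.GC3 for p in pts)])
            ax.plot(
                xs,
                reg.intercept + reg.slope * xs,
                lw=1,
                color=sc.get_facecolor()[0],
                label=f"{species}: slope={reg.slope:.3f}, adj R²={reg.adj_r_squared:.3f}",
            )
    ax.set_xlabel("GC3")
    ax.set_ylabel("GC12")
    ax.legend(fontsize=6)
    return _save(fig, outdir, "neutrality_plot", formats)


def render_figures(
    profiles: Sequence[GeneBiasProfile],
    rscu_tables: dict[str, RSCUTable],
    regressions: dict[str, RegressionResult],
    outdir: str | Path,
    formats: Sequence[str] = _FORMATS,
) -> list[Path]:
    """Render all four figures; no-op with a warning on empty input."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not profiles:
        logger.warning("no profiles: skipping figure rendering")
        return []
    paths = []
    paths += rscu_figure(rscu_tables, outdir, formats)
    paths += enc_plot(profiles, outdir, formats)
    paths += pr2_plot(profiles, outdir, formats)
    paths += neutrality_plot(profiles, regressions, outdir, formats)
    return paths
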