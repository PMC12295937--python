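"""End-to-end orchestration: extract -> composition -> bias -> diagnostics.

One call runs the whole analysis over one or more annotated genomes and
writes every table (TSV, tab-separated, '.' decimal), the four figures,
and a machine-readable run manifest. Reruns with identical settings
produce byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .analysis import (
    build_profiles,
    correlation_matrix,
    neutrality_regression,
    profiles_frame,
)
from .codon_bias import enc, high_frequency_codons, rscu
from .composition import base_composition
from .errors import ComputationError, ConfigurationError
from .genetic_code import get_code
from .plots import render_figures
from .seq_io import extract_all_cds, read_genbank, sum_counts, count_codons

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "code": 5,
    "codonw_compat": False,
    "synonymous_only": False,
    "include_start": True,
    "force_code": False,
    "figure_formats": ("svg", "png"),
}


@dataclass
class RunManifest:
    """Everything needed to reproduce one run."""

    version: str
    inputs: dict[str, str]  # path -> sha256
    code: int
    settings: dict
    outputs: list[str] = field(default_factory=list)
    timestamp: str = ""
    seed: int | None = None

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    inputs: Sequence[str | Path], outdir: str | Path, config: dict | None = None
) -> Path:
    """Run the full codon-usage-bias analysis over GenBank inputs.

    Writes per-gene and per-species tables, the shared/unique
    high-frequency codon report, regression and correlation tables, four
    figures, and ``manifest.json`` into ``outdir``.
    """
    if not inputs:
        raise ConfigurationError("no input files given")
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    code = get_code(cfg["code"])

    # species label = file stem (accessions may repeat across synthetic runs)
    labeled = [(Path(p).stem, read_genbank(p)) for p in inputs]
    genomes = [g for _, g in labeled]
    declared = frozenset().union(*(g.declared_tables for g in genomes))
    if declared and declared != {cfg["code"]} and not cfg["force_code"]:
        raise ConfigurationError(
            f"inputs declare transl_table {sorted(declared)} but --code is "
            f"{cfg['code']}; pass force_code to override"
        )

    comp_rows = []
    all_profiles = []
    rscu_tables = {}
    enc_rows = []
    for species, genome in labeled:
        cds_list = extract_all_cds(genome, code)
        logger.info("%s: %d CDS extracted", species, len(cds_list))
        gcomp = base_composition(genome.sequence)
        comp_rows.append({"species": species, "scope": "genome", **asdict(gcomp)})
        for cds in cds_list:
            comp_rows.append(
                {"species": species, "scope": cds.gene, **asdict(base_composition(cds.nt))}
            )
        profiles = build_profiles(
            cds_list,
            code,
            species=species,
            include_start=cfg["include_start"],
            synonymous_only=cfg["synonymous_only"],
            codonw_compat=cfg["codonw_compat"],
        )
        all_profiles.extend(profiles)
        counts = sum_counts(
            [count_codons(c, code, include_start=cfg["include_start"]) for c in cds_list],
            scope=species,
        )
        rscu_tables[species] = rscu(counts, code)
        genome_enc = enc(counts, code, codonw_compat=cfg["codonw_compat"])
        encs = [p.ENC for p in profiles]
        mean_enc = sum(encs) / len(encs)
        se = (
            math.sqrt(sum((e - mean_enc) ** 2 for e in encs) / (len(encs) - 1) / len(encs))
            if len(encs) > 1
            else float("nan")
        )
        enc_rows.append(
            {
                "species": species,
                "n_genes": len(encs),
                "mean_enc": round(mean_enc, 1),
                "se_enc": round(se, 1),
                "concatenated_enc": round(genome_enc.enc, 1),
                "imputed_classes": ",".join(map(str, sorted(genome_enc.imputed_classes))),
            }
        )
        if genome_enc.imputed_classes:
            logger.warning(
                "%s: ENC class F imputed for sizes %s", species, sorted(genome_enc.imputed_classes)
            )

    # tables -------------------------------------------------------------
    outputs: list[Path] = []

    comp_df = pd.DataFrame(comp_rows)
    outputs.append(_write_tsv(comp_df, outdir / "composition.tsv", float_format="%.3f"))

    prof_df = profiles_frame(all_profiles)
    outputs.append(_write_tsv(prof_df, outdir / "gene_profiles.tsv", float_format="%.6f"))

    rscu_long = []
    for species, table in rscu_tables.items():
        df = table.to_frame()
        df.insert(0, "species", species)
        rscu_long.append(df)
    matrix = (
        pd.concat(rscu_long)
        .pivot(index=["codon", "aa"], columns="species", values="rscu")
        .reset_index()
    )
    outputs.append(_write_tsv(matrix, outdir / "rscu_matrix.tsv", float_format="%.4f"))

    hf = high_frequency_codons(rscu_tables)
    hf_rows = [
        {"codon": c, "third_base": c[2], "status": "shared"} for c in sorted(hf.shared)
    ]
    for species in sorted(hf.unique):
        hf_rows += [
            {"codon": c, "third_base": c[2], "status": f"unique:{species}"}
            for c in sorted(hf.unique[species])
        ]
    outputs.append(_write_tsv(pd.DataFrame(hf_rows), outdir / "high_frequency_codons.tsv"))

    outputs.append(_write_tsv(pd.DataFrame(enc_rows), outdir / "enc_summary.tsv"))

    regressions = {}
    reg_rows = []
    corr_rows = []
    for species in rscu_tables:
        sp_profiles = [p for p in all_profiles if p.species == species]
        try:
            reg = neutrality_regression(sp_profiles)
            regressions[species] = reg
            reg_rows.append({"species": species, **asdict(reg)})
        except ComputationError as exc:
            logger.warning("%s: %s", species, exc)
        corr = correlation_matrix(sp_profiles)
        long = corr.to_long()
        long.insert(0, "species", species)
        corr_rows.append(long)
    outputs.append(_write_tsv(pd.DataFrame(reg_rows), outdir / "neutrality_regression.tsv", float_format="%.6f"))
    outputs.append(_write_tsv(pd.concat(corr_rows), outdir / "correlations.tsv", float_format="%.4f"))

    figs = render_figures(
        all_profiles, rscu_tables, regressions, outdir, formats=cfg["figure_formats"]
    )
    outputs.extend(figs)

    manifest = RunManifest(
        version=__version__,
        inputs={str(p): _sha256(Path(p)) for p in inputs},
        code=cfg["code"],
        settings={k: v for k, v in cfg.items() if k != "code"},
        outputs=[str(p.relative_to(outdir)) for p in outputs],
        timestamp=datetime.now(timezone.utc).isoformat(),
        seed=cfg.get("seed"),
    )
    manifest.write(outdir / "manifest.json")
    return outdir


def _write_tsv(df: pd.DataFrame, path: Path, float_format: str | None = None) -> Path:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)
    return path
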