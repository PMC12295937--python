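#!/usr/bin/env python
"""Mutation-pressure vs selection diagnostics on synthetic genomes with
known parameters: compare the fitted neutrality-plot slope against the
analytic slope from the generator's closed-form expected composition,
and the ENC drop under strong selection.

Writes results/regime_comparison.tsv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from cub import SyntheticSpec, build_profiles, get_code, neutrality_regression, sample_genome
from cub.synthetic import expected_composition

REPO = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--replicates", type=int, default=20)
    args = parser.parse_args()

    code = get_code(5)
    g_spread = tuple(np.linspace(0.2, 0.8, 13))

    exp = [expected_composition(code, g) for g in g_spread]
    analytic = np.polyfit([e["GC3"] for e in exp], [e["GC12"] for e in exp], 1)[0]
    print(f"analytic mutation-regime neutrality slope: {analytic:.4f}")

    rows = []
    for label, kwargs in (
        ("mutation (s=0, g spread 0.2-0.8)", dict(gc_pressure_per_gene=g_spread)),
        ("selection (s=10, g=0.35)", dict(gc_pressure=0.35, selection_strength=10.0)),
    ):
        slopes, encs = [], []
        for rep in range(args.replicates):
            spec = SyntheticSpec(seed=args.seed + rep, codons_per_gene=(600, 600), **kwargs)
            profs = build_profiles(sample_genome(spec)[0], code)
            slopes.append(neutrality_regression(profs).slope)
            encs.append(float(np.mean([p.ENC for p in profs])))
        rows.append(
            {
                "regime": label,
                "mean_slope": np.mean(slopes),
                "sd_slope": np.std(slopes),
                "mean_abs_slope": np.mean(np.abs(slopes)),
                "mean_enc": np.mean(encs),
                "replicates": args.replicates,
            }
        )
        print(
            f"{label}: slope {np.mean(slopes):+.3f} +/- {np.std(slopes):.3f}, "
            f"mean ENC {np.mean(encs):.1f}"
        )
    df = pd.DataFrame(rows)
    df.to_csv(REPO / "results" / "regime_comparison.tsv", sep="\t", index=False, float_format="%.4f")
    flatter = df["mean_abs_slope"].iloc[1] < df["mean_abs_slope"].iloc[0]
    lower = df["mean_enc"].iloc[1] < df["mean_enc"].iloc[0]
    print(
        "selection regime shows "
        + ("a flatter slope " if flatter else "NO slope flattening ")
        + ("and lower ENC " if lower else "and NO ENC drop ")
        + "relative to the mutation regime"
    )


if __name__ == "__main__":
    main()
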