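#!/usr/bin/env python
"""Extract sense-strand CDS from the simulated genomes and tabulate the
genome-description features: strand assignment, start/stop codon usage,
and stops completed by 3' polyadenylation.

Reads scratch/genomes/*.gb (run 01 first); writes results/cds_summary.tsv.
"""

from collections import Counter
from pathlib import Path

import pandas as pd

from cub import extract_all_cds, get_code, read_genbank

REPO = Path(__file__).resolve().parents[1]


def main() -> None:
    code = get_code(5)
    rows = []
    for path in sorted((REPO / "scratch" / "genomes").glob("*.gb")):
        genome = read_genbank(path)
        cds_list = extract_all_cds(genome, code)
        print(
            f"{path.stem}: {genome.length} bp, {len(cds_list)} CDS "
            f"({sum(1 for c in cds_list if c.strand == '-')} light-strand), "
            f"coding fraction {genome.coding_fraction:.1f}%"
        )
        for c in cds_list:
            rows.append(
                {
                    "species": path.stem,
                    "gene": c.gene,
                    "strand": c.strand,
                    "length_nt": len(c.nt),
                    "start_codon": c.start_codon,
                    "stop_codon": c.stop_codon,
                    "stop_completed": c.stop_completed,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(REPO / "results" / "cds_summary.tsv", sep="\t", index=False)
    starts = Counter(df["start_codon"])
    stops = Counter(df["stop_codon"])
    print(f"start codon usage: {dict(starts)}")
    print(f"stop codon usage: {dict(stops)}")
    print(f"stops completed by 3' A addition: {int(df['stop_completed'].sum())}")


if __name__ == "__main__":
    main()
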