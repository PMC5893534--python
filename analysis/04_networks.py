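#!/usr/bin/env python
"""Coordination networks of the GABA pathway across conditions.

For each sex and condition, classifies every GABA-pathway gene pair as
synergistic, antagonistic or independent from the Pearson correlation of
log2 expression across the four replicas, and summarizes how many
coordinated pairs survive in each state. Edge lists go to scratch/networks/,
the per-condition summary to results/network_summary.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from pathfabric import build_network, normalize_median, read_cohort, read_gmt

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "scratch" / "cohort")
    ap.add_argument("--pathway", default="GABA")
    ap.add_argument("--out", type=Path, default=ROOT / "scratch" / "networks")
    args = ap.parse_args()

    cohort = normalize_median(
        read_cohort(args.cohort / "expression.tsv", args.cohort / "samples.tsv")
    )
    genes = read_gmt(args.cohort / "pathways.gmt")[args.pathway]
    args.out.mkdir(parents=True, exist_ok=True)
    rows = []
    for sex in ("male", "female"):
        for cond in ("BNS", "BYS", "BYA", "BYP"):
            edges = build_network(cohort, sex, cond, genes)
            edges.to_csv(args.out / f"network_{sex}_{cond}_{args.pathway}.tsv",
                         sep="\t", index=False, float_format="%.10g")
            rows.append({
                "sex": sex, "condition": cond, "pairs": len(edges),
                "synergistic": int((edges["class"] == "synergistic").sum()),
                "antagonistic": int((edges["class"] == "antagonistic").sum()),
            })
    summary = pd.DataFrame(rows)
    (ROOT / "results").mkdir(exist_ok=True)
    summary.to_csv(ROOT / "results" / "network_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
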