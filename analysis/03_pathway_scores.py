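#!/usr/bin/env python
"""Pathway alteration (WPR) and recovery (GER, PRE) score tables.

Consumes the per-contrast call tables, assembles the full pathway score
table per sex (percent up/down, WPR for each condition; GER and PRE for
each treatment), compares the two treatments across the five pathway
scores with a heteroscedastic t-test, and reports the male:female WPR
ratios. Writes results/pathway_scores.tsv and
results/treatment_comparison.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from pathfabric import compare_treatments, read_gmt, score_table

ROOT = Path(__file__).resolve().parent.parent


def load_calls(calls_dir: Path, sex: str) -> dict:
    return {
        cond: pd.read_csv(calls_dir / f"calls_{sex}_{cond}.tsv", sep="\t",
                          index_col="gene")
        for cond in ("BYS", "BYA", "BYP")
    }


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "scratch" / "cohort")
    ap.add_argument("--calls", type=Path, default=ROOT / "scratch" / "calls")
    args = ap.parse_args()

    pathways = read_gmt(args.cohort / "pathways.gmt")
    frames, comparisons = [], []
    wpr_all = {}
    for sex in ("male", "female"):
        table = score_table(load_calls(args.calls, sex), pathways)
        table.insert(0, "sex", sex)
        frames.append(table)
        wpr_all[sex] = table[(table["pathway"] == "ALL")
                             & (table["condition"] == "BYS")]["wpr"].iloc[0]
        named = table[table["pathway"] != "ALL"]
        for metric in ("pre", "ger"):
            a = named.loc[named["condition"] == "BYA", metric].dropna()
            b = named.loc[named["condition"] == "BYP", metric].dropna()
            comparisons.append({
                "sex": sex, "metric": metric.upper(),
                "mean_BYA": round(a.mean(), 2), "mean_BYP": round(b.mean(), 2),
                "welch_p": compare_treatments(a, b),
            })

    scores = pd.concat(frames, ignore_index=True)
    (ROOT / "results").mkdir(exist_ok=True)
    scores.to_csv(ROOT / "results" / "pathway_scores.tsv", sep="\t",
                  index=False, float_format="%.4g")
    comp = pd.DataFrame(comparisons)
    comp.to_csv(ROOT / "results" / "treatment_comparison.tsv", sep="\t",
                index=False, float_format="%.4g")

    print(scores.round(2).to_string(index=False))
    print()
    print(comp.to_string(index=False))
    ratio = wpr_all["male"] / wpr_all["female"]
    print(f"\nwhole-transcriptome WPR male/female ratio: {ratio:.2f}")


if __name__ == "__main__":
    main()
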