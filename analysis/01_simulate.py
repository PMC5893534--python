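#!/usr/bin/env python
"""Generate the synthetic study cohort.

Simulates the full study design — two sexes, five conditions (SNS, BNS,
BYS, BYA, BYP), four biological replicas each, 17,000 genes with ~3.5%
unquantified in females — with 30% of genes regulated in the disease
condition (BYS), partial recovery plus side effects under the two
treatments (BYA stronger side of ACTH-like recovery 0.65, BYP PMX53-like
0.75), and five overlapping synapse-sized pathway gene sets.

Writes the cohort, the ground-truth ledger and the pathway sets under
scratch/cohort/ (large intermediates) and prints a design summary.
"""

import argparse
from pathlib import Path

from pathfabric import CohortConfig, generate_cohort, write_cohort, write_truth
from pathfabric.scores import write_gmt

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-genes", type=int, default=17_000)
    ap.add_argument("--out", type=Path, default=ROOT / "scratch" / "cohort")
    args = ap.parse_args()

    cfg = CohortConfig(n_genes=args.n_genes, seed=args.seed, make_probes=False)
    cohort, truth = generate_cohort(cfg)
    write_cohort(cohort, args.out)
    write_truth(truth, args.out / "truth.tsv")
    write_gmt(truth.pathways, args.out / "pathways.gmt")

    female_cols = cohort.samples.loc[cohort.samples["sex"] == "female", "sample_id"]
    n_female = int((~cohort.values[female_cols].isna().all(axis=1)).sum())
    print(f"cohort: {cfg.n_genes} genes x {len(cohort.samples)} arrays "
          f"({n_female} genes quantified in females)")
    print(f"planted regulated fraction (BYS vs BNS): "
          f"{truth.planted_fraction('male', 'BYS'):.3f}")
    for name, genes in truth.pathways.items():
        print(f"  pathway {name}: {len(genes)} genes")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
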