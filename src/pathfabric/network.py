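"""Coordination networks from replica-wise expression correlations.

Within one sex and one condition, the Pearson product-moment correlation of
the log2 expression levels of two genes across the biological replicas
(four in the study design) classifies the pair as:

* **synergistic** — significantly positive correlation (r > 0, p < 0.05);
* **antagonistic** — significantly negative correlation (r < 0, p < 0.05);
* **independent** — otherwise.

Significance uses the exact small-sample t relation
``t = r * sqrt((n - 2) / (1 - r^2))`` on ``n - 2`` degrees of freedom. With
n = 4 replicas this makes the rule equivalent to |r| >= 0.950 (3 d.p.) —
only near-perfect coordination is detectable, and with per-pair alpha 0.05
and no multiplicity correction about 5% of truly independent pairs will
still be called coordinated; :func:`build_network` is calibrated against
that rate in the test suite.

Correlations are never pooled across conditions: coordination is a
property of one biological state.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ExpressionCohort

SYNERGISTIC = "synergistic"
ANTAGONISTIC = "antagonistic"
INDEPENDENT = "independent"


def pearson_r(values_a, values_b) -> float:
    """Pearson product-moment correlation of two equal-length vectors.

    Raises on fewer than 3 paired values or a constant vector (undefined
    correlation); callers building networks skip such pairs instead.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two equal-length 1-D vectors")
    if a.size < 3:
        raise ValueError("need at least 3 paired values")
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    if denom == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def correlation_p(r: float, n: int) -> float:
    """Two-tailed p-value for a Pearson r from n paired observations.

    ``t = r * sqrt((n-2)/(1-r^2))`` referred to a t distribution with n-2
    degrees of freedom; |r| = 1 maps to p = 0 by convention.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def r_threshold(n: int, alpha: float = 0.05) -> float:
    """Smallest |r| significant at ``alpha`` for n paired observations.

    Inverts the t relation at the two-tailed critical value; with n = 4
    (t_crit(2 df) = 4.303) this is 0.950 to 3 decimals.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    return float(tcrit / math.sqrt(tcrit**2 + (n - 2)))


def classify_pair(r: float, p: float, alpha: float = 0.05) -> str:
    if p < alpha:
        return SYNERGISTIC if r > 0 else ANTAGONISTIC
    return INDEPENDENT


def build_network(
    cohort: ExpressionCohort,
    sex: str,
    condition: str,
    genes,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify all unordered pathway gene pairs in one (sex, condition).

    Returns an edge list DataFrame (gene_a, gene_b, r, p, class) over the
    pathway genes quantified in every replica of the cell; genes with
    missing or constant values are skipped. Symmetric in the pair and
    invariant under gene reordering (pairs are emitted in sorted order).
    """
    genes = pd.Index(genes).unique()
    present = genes.intersection(cohort.genes)
    if len(present) < 2:
        raise ValueError("need at least 2 quantified pathway genes")
    sub = cohort.submatrix(sex, condition).loc[present]
    arr = np.log2(sub.to_numpy(dtype=float))
    complete = ~np.isnan(arr).any(axis=1)
    usable = complete.copy()
    usable[complete] = arr[complete].std(axis=1) > 0
    arr = arr[usable]
    names = sorted(present[usable])
    order = [list(present[usable]).index(g) for g in names]
    arr = arr[order]
    if arr.shape[0] < 2:
        raise ValueError("fewer than 2 usable pathway genes (missing/constant)")
    n = arr.shape[1]
    corr = np.corrcoef(arr)
    rows = []
    for i, j in itertools.combinations(range(len(names)), 2):
        r = float(np.clip(corr[i, j], -1.0, 1.0))
        p = correlation_p(r, n)
        rows.append(
            {
                "gene_a": names[i],
                "gene_b": names[j],
                "r": r,
                "p": p,
                "class": classify_pair(r, p, alpha),
            }
        )
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "p", "class"])


def degree_summary(edges: pd.DataFrame) -> pd.DataFrame:
    """Per-gene counts of synergistic and antagonistic partners."""
    coordinated = edges[edges["class"] != INDEPENDENT]
    long = pd.concat(
        [
            coordinated[["gene_a", "class"]].rename(columns={"gene_a": "gene"}),
            coordinated[["gene_b", "class"]].rename(columns={"gene_b": "gene"}),
        ]
    )
    if long.empty:
        return pd.DataFrame(columns=[SYNERGISTIC, ANTAGONISTIC]).rename_axis("gene")
    table = long.pivot_table(
        index="gene", columns="class", aggfunc="size", fill_value=0
    )
    for col in (SYNERGISTIC, ANTAGONISTIC):
        if col not in table.columns:
            table[col] = 0
    return table[[SYNERGISTIC, ANTAGONISTIC]]
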