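"""Pathway-level alteration and recovery scores.

Three complementary scores quantify what a disease condition does to a
pathway's transcriptome and how much a treatment undoes:

``WPR`` (Weighted Pathway Regulation) averages, over *all* quantified
pathway genes,

    mu_ref * (|x| - 1) * (1 - p)

where ``mu_ref`` is the gene's mean reference (BNS) expression in
array-median units, ``x`` its signed fold-change and ``p`` its Welch
p-value. No significance filter is applied: ``(1 - p)`` is a confidence
weight, not a cut. WPR is non-negative, zero only when every gene has
|x| = 1 or p = 1, and scales linearly with the expression units — hence the
array-median normalization upstream.

``GER`` (Gene Expression Recovery) summarizes the nine (disease, treated)
transition classes:

    GER = ({DX}+{UX}-{XD}-{XU}) / ({DX}+{UX}+{XD}+{XU}+{DD}+{DU}+{UD}+{UU}) * 100%

crediting disease-regulated genes restored by treatment ({DX}, {UX}) and
debiting treatment side effects ({XD}, {XU}); genes never regulated ({XX})
are excluded from both numerator and denominator.

``PRE`` (Pathway Restoration Efficiency) is the percent reduction of WPR
under treatment, ``(1 - WPR_treated/WPR_disease) * 100%``, with outcomes:
100% full recovery (treated WPR 0), in (0, 100) positive effect, 0 null
effect, negative when the treatment worsens the pathway.

The module also provides the cross-pathway treatment comparison
(heteroscedastic t-test over the per-pathway scores of two treatments) and
the fixed-effects one-way ANOVA sample-size computation from the
noncentral-F distribution, as used to size the behavioural experiment.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .calls import TransitionTable, transition_table, welch_p
from .cohort import TREATMENTS

#: canonical labels of the five synapse pathways (KEGG map ids in fixtures)
SYNAPSE_LABELS = ("ACH", "GLU", "GABA", "DA", "5HT")
#: pseudo-pathway holding every quantified gene
ALL_GENES = "ALL"


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    pathways: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (need >= 3 fields): {line!r}")
        name, _desc, *genes = fields
        pathways[name] = [g for g in genes if g]
    if not pathways:
        raise ValueError(f"no gene sets in {path}")
    return pathways


def write_gmt(pathways: dict[str, list[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, name] + list(genes)) for name, genes in pathways.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def _pathway_subset(contrasts: pd.DataFrame, genes) -> pd.DataFrame:
    sub = contrasts.loc[contrasts.index.intersection(pd.Index(genes).unique())]
    if sub.empty:
        raise ValueError("no pathway gene was quantified in this contrast")
    return sub


def pathway_percentages(calls: pd.Series, genes) -> tuple[float, float]:
    """Percent of quantified pathway genes called U and called D.

    The denominator is the number of pathway genes present in ``calls``
    (quantified genes only), never the nominal pathway size.
    """
    sub = calls.loc[calls.index.intersection(pd.Index(genes).unique())]
    if sub.empty:
        raise ValueError("no pathway gene was quantified")
    n = len(sub)
    return (
        100.0 * float((sub == "U").sum()) / n,
        100.0 * float((sub == "D").sum()) / n,
    )


def wpr(contrasts: pd.DataFrame, genes) -> float:
    """Weighted Pathway Regulation for one pathway and one contrast.

    ``contrasts`` is the per-gene table from :func:`~pathfabric.calls.contrast_genes`
    (needs columns ``mu_ref, x, p``); ``genes`` the pathway's gene ids.
    Averages mu_ref*(|x|-1)*(1-p) over all quantified pathway genes.
    """
    sub = _pathway_subset(contrasts, genes)
    terms = sub["mu_ref"] * (sub["x"].abs() - 1.0) * (1.0 - sub["p"])
    return float(terms.mean())


def ger(transitions: TransitionTable) -> float:
    """Gene Expression Recovery (%) from a transition table.

    Returns NaN (not applicable, never 0) when no gene was regulated in
    either comparison — the all-XX table leaves recovery undefined.
    """
    t = transitions
    denom = sum(t[c] for c in ("DX", "UX", "XD", "XU", "DD", "DU", "UD", "UU"))
    if denom == 0:
        return float("nan")
    num = t["DX"] + t["UX"] - t["XD"] - t["XU"]
    return 100.0 * num / denom


def pre(wpr_treated: float, wpr_untreated: float) -> float:
    """Pathway Restoration Efficiency (%): percent WPR reduction by treatment.

    NaN (not applicable) when the untreated WPR is zero — there is nothing
    to restore.
    """
    if wpr_untreated < 0 or wpr_treated < 0:
        raise ValueError("WPR values must be non-negative")
    if wpr_untreated == 0:
        return float("nan")
    return 100.0 * (1.0 - wpr_treated / wpr_untreated)


def compare_treatments(scores_a, scores_b, paired: bool = False) -> float:
    """Two-tailed p-value comparing two treatments' per-pathway scores.

    Heteroscedastic (Welch) t-test across the pathway-level score vectors
    (typically the five synapse pathways); set ``paired=True`` for a paired
    t-test on the per-pathway differences instead.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 pathway scores per treatment")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison needs equal-length score vectors")
        return float(stats.ttest_rel(a, b).pvalue)
    return welch_p(a, b)


def score_table(
    contrasts: dict[str, pd.DataFrame],
    pathways: dict[str, list[str]],
    include_all: bool = True,
) -> pd.DataFrame:
    """Full per-pathway score table for one sex.

    ``contrasts`` maps each non-reference condition (e.g. BYS, BYA, BYP) to
    its per-gene contrast table against BNS. Produces one row per
    (pathway, condition) with pct_up, pct_down, wpr, and — for treatment
    conditions — ger and pre relative to the untreated disease condition
    (BYS). A synthetic ``ALL`` pathway covering every quantified gene is
    appended unless ``include_all`` is false.
    """
    pw = dict(pathways)
    if include_all:
        universe = set()
        for df in contrasts.values():
            universe.update(df.index)
        pw[ALL_GENES] = sorted(universe)

    disease = "BYS"
    rows = []
    for name, genes in pw.items():
        wpr_by_cond: dict[str, float] = {}
        for cond, df in contrasts.items():
            up, down = pathway_percentages(df["call"], genes)
            w = wpr(df, genes)
            wpr_by_cond[cond] = w
            rows.append(
                {
                    "pathway": name,
                    "condition": cond,
                    "n_genes": len(df.index.intersection(pd.Index(genes).unique())),
                    "pct_up": up,
                    "pct_down": down,
                    "wpr": w,
                    "ger": np.nan,
                    "pre": np.nan,
                }
            )
        if disease in contrasts:
            for treat in TREATMENTS:
                if treat not in contrasts:
                    continue
                pathway_genes = pd.Index(genes).unique()
                calls_d = contrasts[disease]["call"]
                calls_t = contrasts[treat]["call"]
                calls_d = calls_d.loc[calls_d.index.intersection(pathway_genes)]
                calls_t = calls_t.loc[calls_t.index.intersection(pathway_genes)]
                tt = transition_table(calls_d, calls_t)
                for row in rows:
                    if row["pathway"] == name and row["condition"] == treat:
                        row["ger"] = ger(tt)
                        row["pre"] = pre(wpr_by_cond[treat], wpr_by_cond[disease])
    return pd.DataFrame(rows)


def anova_power(f: float, k: int, n: int, alpha: float = 0.05) -> float:
    """Power of a fixed-effects one-way ANOVA with k groups of n each.

    Uses the noncentral-F distribution: noncentrality ``lambda = f^2 * k * n``
    (f is Cohen's effect size), numerator df ``k - 1``, denominator df
    ``k*n - k``; power is the noncentral-F upper tail above the central-F
    critical value at ``alpha``.
    """
    if f <= 0:
        raise ValueError("effect size f must be > 0")
    if k < 2 or n < 2:
        raise ValueError("need k >= 2 groups of n >= 2")
    df1 = k - 1
    df2 = k * n - k
    lam = f * f * k * n
    fcrit = stats.f.ppf(1.0 - alpha, df1, df2)
    return float(stats.ncf.sf(fcrit, df1, df2, lam))


def anova_sample_size(
    f: float,
    k: int,
    alpha: float = 0.05,
    power: float = 0.80,
    max_n: int = 10_000,
) -> int:
    """Smallest per-group n at which the one-way ANOVA reaches target power.

    Linear search from n = 2 (power is non-decreasing in n); raises if the
    target is unreachable within ``max_n`` (e.g. f too small).
    """
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    for n in range(2, max_n + 1):
        if anova_power(f, k, n, alpha) >= power:
            return n
    raise ValueError(
        f"power {power} not reachable with f={f}, k={k} within n <= {max_n}"
    )
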