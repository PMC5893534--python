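"""Per-gene differential regulation calls.

A gene is called up- (U) or down- (D) regulated between a test condition
and the BNS reference only when two criteria hold jointly:

1. its absolute expression ratio exceeds an adaptive cut-off pooling the
   biological and technical variabilities of the two conditions,
   ``cut = 1 + sqrt(cv_test^2 + cv_ref^2 + tech_test^2 + tech_ref^2)``; and
2. the two-tailed p-value of a heteroscedastic (Welch, unequal-variance)
   t-test of the means' equality is below alpha (default 0.05).

Everything else is X (not regulated). The fold-change is signed: negative
for down-regulation, with ``|x| >= 1`` always and equal means mapping to +1.
The t-test runs on log2-transformed values, since fold-changes are
multiplicative; means and CVs for the cut-off stay on the linear scale.

No multiple-testing correction is applied: the combined ratio-plus-p
criterion is deliberately used with a raw per-gene alpha, which the null
calibration tests show keeps the family of non-X calls at or below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ExpressionCohort, REFERENCE, condition_stats

CALLS = ("U", "D", "X")
#: the nine (disease-call, treated-call) classes, first letter = disease
TRANSITION_CLASSES = ("DX", "UX", "XD", "XU", "DD", "DU", "UD", "UU", "XX")

ALPHA_DEFAULT = 0.05


def signed_fold_change(mu_test, mu_ref):
    """Signed fold-change: ``mu_test/mu_ref`` if test >= ref, else
    ``-mu_ref/mu_test`` (negative for down-regulation); equal means -> +1.

    Accepts scalars or arrays; |x| >= 1 always.
    """
    mu_test = np.asarray(mu_test, dtype=float)
    mu_ref = np.asarray(mu_ref, dtype=float)
    if np.any((mu_test <= 0) | (mu_ref <= 0)):
        raise ValueError("means must be strictly positive")
    up = mu_test >= mu_ref
    with np.errstate(divide="ignore"):
        x = np.where(up, mu_test / mu_ref, -mu_ref / mu_test)
    return float(x) if x.ndim == 0 else x


def adaptive_cutoff(cv_test, cv_ref, tech_cv_test=0.0, tech_cv_ref=0.0):
    """Fold-change cut-off from pooled biological and technical CVs.

    ``1 + sqrt(cv_t^2 + cv_r^2 + tech_t^2 + tech_r^2)``; equals 1 when all
    variabilities vanish and is monotone non-decreasing in each argument.
    Technical CVs default to 0 when only gene-level data exist.
    """
    arrs = [np.asarray(a, dtype=float) for a in (cv_test, cv_ref, tech_cv_test, tech_cv_ref)]
    for a in arrs:
        if np.any(a < 0):
            raise ValueError("CVs must be non-negative")
    cut = 1.0 + np.sqrt(sum(a**2 for a in arrs))
    return float(cut) if cut.ndim == 0 else cut


def _welch_arrays(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise two-tailed Welch p for 2-D arrays with NaN handling."""
    na = np.sum(~np.isnan(a), axis=1).astype(float)
    nb = np.sum(~np.isnan(b), axis=1).astype(float)
    if np.any(na < 2) or np.any(nb < 2):
        raise ValueError("need at least 2 values per side")
    with np.errstate(invalid="ignore", divide="ignore"):
        ma = np.nansum(a, axis=1) / na
        mb = np.nansum(b, axis=1) / nb
        va = np.nansum((a - ma[:, None]) ** 2, axis=1) / (na - 1)
        vb = np.nansum((b - mb[:, None]) ** 2, axis=1) / (nb - 1)
        se2 = va / na + vb / nb
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = np.empty(a.shape[0])
    degenerate = se2 == 0
    p[degenerate] = np.where(np.isclose(ma[degenerate], mb[degenerate]), 1.0, 0.0)
    ok = ~degenerate
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    return np.minimum(p, 1.0)


def welch_p(replicas_test, replicas_ref) -> float:
    """Two-tailed Welch (heteroscedastic) t-test p-value for two samples.

    Uses the Welch-Satterthwaite degrees of freedom. Identical samples (or
    zero variance on both sides with equal means) give p = 1. The caller
    chooses the scale; contrasts in this package test log2 values.
    """
    a = np.asarray(replicas_test, dtype=float)[None, :]
    b = np.asarray(replicas_ref, dtype=float)[None, :]
    return float(_welch_arrays(a, b)[0])


def call_regulation(x, cut, p, alpha: float = ALPHA_DEFAULT):
    """Combine fold-change, cut-off and p-value into a U/D/X call.

    U if ``x >= cut`` and ``p < alpha``; D if ``x <= -cut`` and ``p < alpha``;
    X otherwise. A fold-change exactly at the cut-off counts as regulated
    (the >= / <= convention mirrors the fold-change's own boundary branch).
    """
    x = np.asarray(x, dtype=float)
    cut = np.asarray(cut, dtype=float)
    p = np.asarray(p, dtype=float)
    sig = p < alpha
    call = np.where(
        (x >= cut) & sig, "U", np.where((x <= -cut) & sig, "D", "X")
    )
    return str(call) if call.ndim == 0 else call


def classify_transition(call_disease: str, call_treated: str) -> str:
    """Two-letter transition class, disease call first (e.g. ``DX``)."""
    for c in (call_disease, call_treated):
        if c not in CALLS:
            raise ValueError(f"invalid call symbol {c!r}; expected one of {CALLS}")
    return call_disease + call_treated


@dataclass(frozen=True)
class TransitionTable:
    """Counts of the nine (disease-call, treated-call) classes."""

    counts: dict

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(TRANSITION_CLASSES)
        if unknown:
            raise ValueError(f"unknown transition class(es): {sorted(unknown)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("transition counts must be non-negative")
        full = {c: int(self.counts.get(c, 0)) for c in TRANSITION_CLASSES}
        object.__setattr__(self, "counts", full)

    def __getitem__(self, cls: str) -> int:
        return self.counts[cls]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def transition_table(calls_disease: pd.Series, calls_treated: pd.Series) -> TransitionTable:
    """Count transition classes over the genes contrasted in both comparisons.

    Genes present in only one of the two call series are excluded; the nine
    counts sum to the size of the intersection.
    """
    common = calls_disease.index.intersection(calls_treated.index)
    pairs = calls_disease.loc[common] + calls_treated.loc[common]
    counts = pairs.value_counts().to_dict()
    return TransitionTable(counts=counts)


def contrast_genes(
    cohort: ExpressionCohort,
    sex: str,
    test_condition: str,
    ref_condition: str = REFERENCE,
    alpha: float = ALPHA_DEFAULT,
    use_technical_cv: bool = True,
) -> pd.DataFrame:
    """Per-gene contrast of one condition against the reference.

    Returns a DataFrame indexed by gene with columns ``mu_ref, mu_test, x,
    cut, p, call`` plus the CVs and replica counts that produced the
    cut-off. Genes with fewer than two quantified replicas on either side
    are dropped (their variance, hence the criterion, is undefined).
    """
    st = condition_stats(cohort, sex, test_condition)
    sr = condition_stats(cohort, sex, ref_condition)
    ok = (st["n"] >= 2) & (sr["n"] >= 2)
    genes = cohort.genes[ok.to_numpy()]
    st = st.loc[genes]
    sr = sr.loc[genes]

    x = signed_fold_change(st["mean"].to_numpy(), sr["mean"].to_numpy())
    tech = (
        cohort.tech_cv.reindex(genes).fillna(0.0).to_numpy()
        if use_technical_cv
        else np.zeros(len(genes))
    )
    cut = adaptive_cutoff(st["cv"].to_numpy(), sr["cv"].to_numpy(), tech, tech)

    log_t = np.log2(cohort.submatrix(sex, test_condition).loc[genes].to_numpy(dtype=float))
    log_r = np.log2(cohort.submatrix(sex, ref_condition).loc[genes].to_numpy(dtype=float))
    p = _welch_arrays(log_t, log_r)

    call = call_regulation(x, cut, p, alpha=alpha)
    return pd.DataFrame(
        {
            "mu_ref": sr["mean"],
            "mu_test": st["mean"],
            "x": x,
            "cut": cut,
            "p": p,
            "call": call,
            "cv_ref": sr["cv"],
            "cv_test": st["cv"],
            "n_ref": sr["n"],
            "n_test": st["n"],
        },
        index=genes,
    )
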