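"""Expression cohort data model and I/O.

A cohort is a strictly positive, linear-scale gene-by-sample expression
matrix plus a sample sheet assigning each array to a sex, a condition and a
biological replica. The five condition codes follow the three-letter scheme
prenatal priming (Betamethasone/Saline) - spasms (Yes/No) - postnatal
treatment (ACTH/PMX53/Saline): SNS, BNS, BYS, BYA, BYP. BNS (primed, no
spasms, saline) is the reference for every contrast downstream.

Probe-level tables are optional: arrays measure probes, the analysis runs on
genes, so :func:`summarize_probes` collapses probes to their per-sample
median and retains the across-probe technical CV per gene, which feeds the
adaptive regulation cut-off.

Missing values (``NaN``) are permitted and handled pairwise-complete with
recorded ``n``; genes quantified in only one sex are analysed within that
sex only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CONDITIONS = ("SNS", "BNS", "BYS", "BYA", "BYP")
REFERENCE = "BNS"
TREATMENTS = ("BYA", "BYP")
SEXES = ("male", "female")

SHEET_COLUMNS = ["sample_id", "sex", "condition", "replica"]


class CohortError(ValueError):
    """Raised when a cohort violates its structural invariants."""


@dataclass
class ExpressionCohort:
    """Gene-by-sample expression with its sample sheet.

    Parameters
    ----------
    values
        Linear-scale expression, genes as rows (index = gene ids), one
        column per ``sample_id``. Strictly positive; NaN marks a gene not
        quantified on that array.
    samples
        Sample sheet with columns ``sample_id, sex, condition, replica``.
    probe_values
        Optional probe-by-sample table (same columns as ``values``).
    probe_map
        Optional Series mapping probe id -> gene id.
    tech_cv
        Optional per-gene technical CV (across-probe sd/mean), produced by
        :func:`summarize_probes`.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    probe_values: pd.DataFrame | None = None
    probe_map: pd.Series | None = None
    tech_cv: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)[SHEET_COLUMNS]
        self.values.index.name = "gene"
        self._validate()
        if self.tech_cv is None:
            self.tech_cv = pd.Series(0.0, index=self.values.index, name="tech_cv")

    def _validate(self) -> None:
        sheet = self.samples
        if sheet["sample_id"].duplicated().any():
            dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise CohortError(f"duplicate sample id: {dup!r}")
        unknown = set(sheet["condition"]) - set(CONDITIONS)
        if unknown:
            raise CohortError(
                f"unknown condition labels {sorted(unknown)}; expected one of {CONDITIONS}"
            )
        unknown_sex = set(sheet["sex"]) - set(SEXES)
        if unknown_sex:
            raise CohortError(f"unknown sex labels {sorted(unknown_sex)}")
        missing = set(self.values.columns) - set(sheet["sample_id"])
        if missing:
            raise CohortError(
                f"sample sheet does not cover expression column(s): {sorted(missing)}"
            )
        extra = set(sheet["sample_id"]) - set(self.values.columns)
        if extra:
            raise CohortError(f"sample sheet rows without expression column: {sorted(extra)}")
        if sheet.duplicated(subset=["sex", "condition", "replica"]).any():
            row = sheet[sheet.duplicated(subset=["sex", "condition", "replica"])].iloc[0]
            raise CohortError(
                f"duplicate (sex, condition, replica) = "
                f"({row.sex}, {row.condition}, {row.replica})"
            )
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise CohortError(f"duplicated gene identifier: {dup!r}")
        vals = self.values.to_numpy(dtype=float)
        bad = (vals <= 0) & ~np.isnan(vals)
        if bad.any():
            gi, si = np.argwhere(bad)[0]
            raise CohortError(
                f"non-positive expression value {vals[gi, si]!r} at gene "
                f"{self.values.index[gi]!r}, sample {self.values.columns[si]!r}"
            )

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def sample_ids(self, sex: str, condition: str) -> list[str]:
        """Sample ids of one (sex, condition) cell, ordered by replica."""
        sheet = self.samples
        sel = sheet[(sheet["sex"] == sex) & (sheet["condition"] == condition)]
        return list(sel.sort_values("replica")["sample_id"])

    def submatrix(self, sex: str, condition: str) -> pd.DataFrame:
        ids = self.sample_ids(sex, condition)
        if not ids:
            raise CohortError(f"no samples for sex={sex!r}, condition={condition!r}")
        return self.values[ids]


def read_cohort(expr_path: str | Path, sample_sheet_path: str | Path) -> ExpressionCohort:
    """Read a cohort from tab-delimited expression and sample-sheet files.

    The expression file has gene ids in the first column and one column per
    sample; the sheet has columns ``sample_id, sex, condition, replica``.
    """
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    sheet = pd.read_csv(sample_sheet_path, sep="\t", dtype={"replica": int})
    missing_cols = set(SHEET_COLUMNS) - set(sheet.columns)
    if missing_cols:
        raise CohortError(f"sample sheet missing column(s): {sorted(missing_cols)}")
    return ExpressionCohort(values=values, samples=sheet)


def write_cohort(cohort: ExpressionCohort, outdir: str | Path) -> dict[str, Path]:
    """Write a cohort as tab-delimited text; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "samples": outdir / "samples.tsv",
    }
    cohort.values.to_csv(paths["expression"], sep="\t", index_label="gene")
    cohort.samples.to_csv(paths["samples"], sep="\t", index=False)
    if cohort.probe_values is not None and cohort.probe_map is not None:
        paths["probes"] = outdir / "probes.tsv"
        paths["probe_map"] = outdir / "probe_map.tsv"
        cohort.probe_values.to_csv(paths["probes"], sep="\t", index_label="probe")
        cohort.probe_map.rename("gene").to_csv(
            paths["probe_map"], sep="\t", index_label="probe"
        )
    return paths


def summarize_probes(
    probe_table: pd.DataFrame, probe_map: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """Collapse a probe-by-sample table to gene level.

    Gene value = median of its probes per sample. The per-gene technical CV
    (sd/mean across the gene's probes, averaged over samples) is returned
    alongside for use in the adaptive regulation cut-off. Probes absent from
    the map are dropped; single-probe genes pass through with technical CV 0.
    """
    if probe_map.empty:
        raise CohortError("empty probe->gene map")
    mapped = probe_table.index.intersection(probe_map.index)
    table = probe_table.loc[mapped]
    genes = probe_map.loc[mapped]
    grouped = table.groupby(genes.to_numpy())
    gene_values = grouped.median()
    mean = grouped.mean()
    sd = grouped.std(ddof=1)
    counts = grouped.size()
    # sd is NaN for single-probe genes; their technical CV is 0 by definition
    cv = (sd / mean).mean(axis=1).fillna(0.0)
    cv[counts == 1] = 0.0
    gene_values.index.name = "gene"
    return gene_values, cv.rename("tech_cv")


def normalize_median(cohort: ExpressionCohort) -> ExpressionCohort:
    """Scale each array so its median gene equals 1 (array-median units).

    Division by the per-array median makes downstream WPR values
    dimensionless and O(1-10) instead of inheriting arbitrary fluorescence
    units; it is idempotent and removes any common per-array scale factor.
    """
    medians = cohort.values.median(axis=0, skipna=True)
    values = cohort.values.div(medians, axis=1)
    return ExpressionCohort(
        values=values,
        samples=cohort.samples,
        probe_values=cohort.probe_values,
        probe_map=cohort.probe_map,
        tech_cv=cohort.tech_cv,
    )


def condition_stats(cohort: ExpressionCohort, sex: str, condition: str) -> pd.DataFrame:
    """Per-gene mean, sd, CV and replica count for one (sex, condition).

    Statistics are pairwise-complete on the linear scale: NaN replicas are
    dropped per gene and the effective ``n`` recorded. Refuses cells with
    fewer than two replicas, since the call criterion needs a variance.
    """
    sub = cohort.submatrix(sex, condition)
    if sub.shape[1] < 2:
        raise CohortError(
            f"condition {condition!r} ({sex}) has {sub.shape[1]} replica(s); need >= 2"
        )
    arr = sub.to_numpy(dtype=float)
    n = np.sum(~np.isnan(arr), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, np.nansum(arr, axis=1) / np.maximum(n, 1), np.nan)
        sd = np.full(arr.shape[0], np.nan)
        ok = n >= 2
        if ok.any():
            sd[ok] = np.nanstd(arr[ok], axis=1, ddof=1)
        cv = sd / mean
    return pd.DataFrame(
        {"mean": mean, "sd": sd, "cv": cv, "n": n}, index=cohort.genes
    )
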