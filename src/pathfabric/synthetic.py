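"""Synthetic expression cohorts with a ground-truth ledger.

The generator reproduces the statistical structure of the study design —
2 sexes x 5 conditions (SNS, BNS, BYS, BYA, BYP) x 4 biological replicas,
~17,000 genes with slightly fewer quantified in females, multi-probe genes,
lognormal expression — so that every downstream stage (calls, scores,
networks) can be validated against known truth without any download.

Model, per sex:

* each gene has a lognormal baseline (normal on log2) and its own
  biological CV drawn from a configured range; replicate noise is
  multiplicative lognormal at that CV, technical (probe) noise likewise at
  the technical CV;
* the disease condition BYS applies a planted fold-change to a
  ``frac_regulated`` subset of genes, magnitudes uniform in
  ``effect_fc_range``, direction up with probability ``frac_up``;
* each treatment (BYA = ACTH, BYP = PMX53) copies the BYS effects, reverts
  a ``recovery_frac`` fraction of them to baseline (restored genes) and
  newly perturbs a ``side_effect_frac`` fraction of the previously
  unaffected genes (side-effect genes, same effect-size distribution);
  every gene is thus exactly one of restored / persistent / side-effect /
  untouched per treatment;
* the female cohort shares the planted gene sets and directions but scales
  every |FC - 1| by ``sex_effect_scale`` (default 1/3), mimicking the
  weaker female response at similar regulated percentages;
* SNS is generated identically to BNS (that contrast is out of analytic
  scope here).

Optionally, blocks of genes share a latent replicate factor so their log2
values correlate within a condition — planted coordination for network
tests. Everything is reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CONDITIONS, ExpressionCohort, REFERENCE, SEXES

DISEASE = "BYS"
_TREATMENTS = ("BYA", "BYP")

TRUTH_COLUMNS = ["sex", "gene", "condition", "baseline", "true_fc", "category"]

#: ground-truth categories per treatment
RESTORED, PERSISTENT, SIDE_EFFECT, UNTOUCHED = (
    "restored",
    "persistent",
    "side_effect",
    "untouched",
)


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


def _check_count(name: str, value) -> None:
    if not isinstance(value, (int, np.integer)) or isinstance(value, bool):
        raise ValueError(f"{name} must be an integer, got {value!r}")
    if value < 0:
        raise ValueError(f"{name} must be non-negative, got {value}")


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the simulated study.

    Defaults mirror the study design: 17,000 genes, five conditions, four
    replicas per (sex, condition), 30% of genes regulated by the induced
    spasms, treatment recoveries sized so the recovery scores land in the
    reported 55-75% range, and a 1/3 female effect scale.
    """

    n_genes: int = 17_000
    n_pathways: int = 5
    pathway_size: tuple[int, int] = (80, 130)
    n_replicas: int = 4
    conditions: tuple[str, ...] = CONDITIONS
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 2.0
    biological_cv: tuple[float, float] = (0.05, 0.40)
    technical_cv: float = 0.05
    probes_per_gene: tuple[int, int] = (1, 4)
    frac_regulated: float = 0.30
    effect_fc_range: tuple[float, float] = (1.5, 4.0)
    frac_up: float = 0.5
    recovery_frac: dict = field(
        default_factory=lambda: {"BYA": 0.65, "BYP": 0.75}
    )
    side_effect_frac: dict = field(
        default_factory=lambda: {"BYA": 0.02, "BYP": 0.02}
    )
    sex_effect_scale: float = 1.0 / 3.0
    female_dropout_frac: float = 0.035
    n_coexpressed_blocks: int = 0
    block_size: int = 10
    block_corr: float = 0.9
    make_probes: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_pathways", "n_replicas", "n_coexpressed_blocks",
                     "block_size", "seed"):
            _check_count(name, getattr(self, name))
        if self.n_replicas < 2:
            raise ValueError("n_replicas must be >= 2")
        if not self.conditions:
            raise ValueError("conditions must be a non-empty set")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown condition(s): {sorted(unknown)}")
        if REFERENCE not in self.conditions:
            raise ValueError(f"conditions must include the reference {REFERENCE}")
        for name in ("frac_regulated", "frac_up", "female_dropout_frac"):
            _check_fraction(name, getattr(self, name))
        for d in (self.recovery_frac, self.side_effect_frac):
            for key, val in d.items():
                _check_fraction(f"fraction for {key}", val)
        if self.effect_fc_range[0] <= 1.0:
            raise ValueError("effect_fc_range lower bound must exceed 1")
        if self.effect_fc_range[0] > self.effect_fc_range[1]:
            raise ValueError("effect_fc_range must be (low, high)")
        if not 0.0 <= self.block_corr < 1.0:
            raise ValueError("block_corr must lie in [0, 1)")
        if self.technical_cv < 0 or self.biological_cv[0] < 0:
            raise ValueError("CVs must be non-negative")
        if self.sex_effect_scale <= 0:
            raise ValueError("sex_effect_scale must be positive")


@dataclass
class GroundTruth:
    """Planted truth behind a generated cohort.

    ``table`` is a long ledger with one row per (sex, gene, non-reference
    condition): the gene's baseline mean, its true signed fold-change vs
    BNS (negative for down, +1 for unaffected) and its category —
    'regulated'/'unaffected' for SNS and BYS rows, restored / persistent /
    side_effect / untouched for treatment rows. ``pathways`` maps pathway
    name to gene ids (sets may overlap); ``blocks`` lists planted
    co-expressed gene blocks.
    """

    table: pd.DataFrame
    pathways: dict[str, list[str]]
    blocks: dict[str, list[str]] = field(default_factory=dict)

    def subset(self, sex: str, condition: str) -> pd.DataFrame:
        t = self.table
        return t[(t["sex"] == sex) & (t["condition"] == condition)].set_index("gene")

    def regulated_genes(self, sex: str, condition: str) -> set[str]:
        sub = self.subset(sex, condition)
        return set(sub.index[sub["true_fc"].abs() > 1.0])

    def planted_fraction(self, sex: str, condition: str) -> float:
        sub = self.subset(sex, condition)
        return float((sub["true_fc"].abs() > 1.0).mean())

    def category_sets(self, sex: str, treatment: str) -> dict[str, set[str]]:
        sub = self.subset(sex, treatment)
        return {
            cat: set(sub.index[sub["category"] == cat])
            for cat in (RESTORED, PERSISTENT, SIDE_EFFECT, UNTOUCHED)
        }


def _signed(ratio: np.ndarray) -> np.ndarray:
    """Linear multiplier -> signed fold-change (negative for down)."""
    return np.where(ratio >= 1.0, ratio, -1.0 / ratio)


def _scale_effect(ratio: np.ndarray, scale: float) -> np.ndarray:
    """Shrink |FC - 1| by ``scale`` while preserving direction."""
    mag = np.where(ratio >= 1.0, ratio, 1.0 / ratio)
    mag = 1.0 + scale * (mag - 1.0)
    return np.where(ratio >= 1.0, mag, 1.0 / mag)


def generate_cohort(config: CohortConfig) -> tuple[ExpressionCohort, GroundTruth]:
    """Simulate both sexes' expression matrices and the truth behind them.

    Returns the cohort (gene table, sample sheet, and a probe-level table
    with technical noise when ``make_probes``) and the :class:`GroundTruth`
    ledger. Bit-identical for equal (config, seed).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    genes = pd.Index([f"G{i:05d}" for i in range(n)], name="gene")

    baseline = 2.0 ** rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, n)
    bio_cv = rng.uniform(cfg.biological_cv[0], cfg.biological_cv[1], n)

    # planted disease effects (linear multipliers), shared across sexes
    n_reg = int(round(cfg.frac_regulated * n))
    reg_idx = rng.choice(n, size=n_reg, replace=False)
    up = rng.random(n_reg) < cfg.frac_up
    mag = rng.uniform(cfg.effect_fc_range[0], cfg.effect_fc_range[1], n_reg)
    bys_ratio = np.ones(n)
    bys_ratio[reg_idx] = np.where(up, mag, 1.0 / mag)

    ratios: dict[str, np.ndarray] = {c: np.ones(n) for c in cfg.conditions}
    categories: dict[str, np.ndarray] = {}
    if DISEASE in cfg.conditions:
        ratios[DISEASE] = bys_ratio
    for treat in _TREATMENTS:
        if treat not in cfg.conditions:
            continue
        rho = cfg.recovery_frac.get(treat, 0.0)
        sigma = cfg.side_effect_frac.get(treat, 0.0)
        ratio = bys_ratio.copy()
        n_restore = int(round(rho * n_reg))
        restored = rng.choice(reg_idx, size=n_restore, replace=False)
        ratio[restored] = 1.0
        unaffected = np.setdiff1d(np.arange(n), reg_idx)
        n_side = int(round(sigma * unaffected.size))
        side = rng.choice(unaffected, size=n_side, replace=False)
        side_up = rng.random(n_side) < cfg.frac_up
        side_mag = rng.uniform(cfg.effect_fc_range[0], cfg.effect_fc_range[1], n_side)
        ratio[side] = np.where(side_up, side_mag, 1.0 / side_mag)
        ratios[treat] = ratio
        cat = np.full(n, UNTOUCHED, dtype=object)
        cat[reg_idx] = PERSISTENT
        cat[restored] = RESTORED
        cat[side] = SIDE_EFFECT
        categories[treat] = cat

    bys_cat = np.full(n, "unaffected", dtype=object)
    bys_cat[reg_idx] = "regulated"

    # co-expressed blocks share a latent replicate factor on the log scale
    block_members: dict[str, list[str]] = {}
    block_of = np.full(n, -1)
    if cfg.n_coexpressed_blocks > 0:
        chosen = rng.choice(
            n, size=cfg.n_coexpressed_blocks * cfg.block_size, replace=False
        )
        for b in range(cfg.n_coexpressed_blocks):
            members = chosen[b * cfg.block_size : (b + 1) * cfg.block_size]
            block_of[members] = b
            block_members[f"block{b}"] = [genes[i] for i in sorted(members)]

    cond_order = [c for c in CONDITIONS if c in cfg.conditions]
    sample_rows = []
    per_sex_values = {}
    sigma_ln = np.sqrt(np.log1p(bio_cv**2))
    female_scale = cfg.sex_effect_scale
    n_drop = int(round(cfg.female_dropout_frac * n))
    drop_idx = rng.choice(n, size=n_drop, replace=False) if n_drop else np.array([], int)

    for sex in SEXES:
        cols = []
        mats = []
        for cond in cond_order:
            ratio = ratios[cond]
            if sex == "female":
                ratio = _scale_effect(ratio, female_scale)
            expected = baseline * ratio
            z = rng.standard_normal((n, cfg.n_replicas))
            if cfg.n_coexpressed_blocks > 0:
                z_common = rng.standard_normal(
                    (cfg.n_coexpressed_blocks, cfg.n_replicas)
                )
                in_block = block_of >= 0
                rho_c = cfg.block_corr
                z[in_block] = (
                    np.sqrt(rho_c) * z_common[block_of[in_block]]
                    + np.sqrt(1.0 - rho_c) * z[in_block]
                )
            noise = np.exp(
                z * sigma_ln[:, None] - 0.5 * sigma_ln[:, None] ** 2
            )
            mats.append(expected[:, None] * noise)
            for rep in range(1, cfg.n_replicas + 1):
                sid = f"{sex[0].upper()}_{cond}_{rep}"
                cols.append(sid)
                sample_rows.append(
                    {"sample_id": sid, "sex": sex, "condition": cond, "replica": rep}
                )
        mat = np.concatenate(mats, axis=1)
        if sex == "female" and n_drop:
            mat[drop_idx, :] = np.nan
        per_sex_values[sex] = pd.DataFrame(mat, index=genes, columns=cols)

    values = pd.concat([per_sex_values["male"], per_sex_values["female"]], axis=1)
    samples = pd.DataFrame(sample_rows)

    probe_values = probe_map = None
    if cfg.make_probes:
        k = rng.integers(cfg.probes_per_gene[0], cfg.probes_per_gene[1] + 1, n)
        probe_gene_idx = np.repeat(np.arange(n), k)
        offsets = np.concatenate([np.arange(ki) for ki in k])
        probe_ids = pd.Index(
            [f"{genes[g]}_p{o + 1}" for g, o in zip(probe_gene_idx, offsets)],
            name="probe",
        )
        sig_t = np.sqrt(np.log1p(cfg.technical_cv**2))
        base_mat = values.to_numpy()[probe_gene_idx]
        tnoise = np.exp(
            rng.standard_normal(base_mat.shape) * sig_t - 0.5 * sig_t**2
        )
        probe_values = pd.DataFrame(
            base_mat * tnoise, index=probe_ids, columns=values.columns
        )
        probe_map = pd.Series(
            [genes[g] for g in probe_gene_idx], index=probe_ids, name="gene"
        )

    # pathway gene sets; overlap allowed (each pathway sampled independently)
    labels = ["ACH", "GLU", "GABA", "DA", "5HT"]
    pathways: dict[str, list[str]] = {}
    for i in range(cfg.n_pathways):
        name = labels[i] if i < len(labels) else f"P{i + 1:02d}"
        size = int(rng.integers(cfg.pathway_size[0], cfg.pathway_size[1] + 1))
        size = min(size, n)
        members = rng.choice(n, size=size, replace=False)
        pathways[name] = [genes[j] for j in sorted(members)]

    # truth ledger: one row per (sex, gene, non-reference condition)
    frames = []
    for sex in SEXES:
        for cond in cond_order:
            if cond == REFERENCE:
                continue
            ratio = ratios[cond]
            if sex == "female":
                ratio = _scale_effect(ratio, female_scale)
            if cond in categories:
                cat = categories[cond]
            elif cond == DISEASE:
                cat = bys_cat
            else:
                cat = np.full(n, "unaffected", dtype=object)
            frames.append(
                pd.DataFrame(
                    {
                        "sex": sex,
                        "gene": genes,
                        "condition": cond,
                        "baseline": baseline,
                        "true_fc": _signed(ratio),
                        "category": cat,
                    }
                )
            )
    table = pd.concat(frames, ignore_index=True)[TRUTH_COLUMNS]

    cohort = ExpressionCohort(
        values=values,
        samples=samples,
        probe_values=probe_values,
        probe_map=probe_map,
    )
    truth = GroundTruth(table=table, pathways=pathways, blocks=block_members)
    return cohort, truth


def write_truth(truth: GroundTruth, path: str | Path) -> Path:
    """Write the truth ledger as tab-delimited text (lossless round-trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    truth.table.to_csv(path, sep="\t", index=False)
    return path


def read_truth(path: str | Path) -> pd.DataFrame:
    """Read a truth ledger written by :func:`write_truth`."""
    df = pd.read_csv(path, sep="\t")
    missing = set(TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"truth ledger missing column(s): {sorted(missing)}")
    return df[TRUTH_COLUMNS]
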