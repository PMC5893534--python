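"""End-to-end pipeline: simulate/read -> normalize -> calls -> scores -> networks.

One deterministic run per seed. Each sex is processed as an independent
cohort throughout (sexes are never pooled; cross-sex comparisons are ratios
of scores only), every treatment is contrasted against the fixed BNS
reference, and all arbitrary constants (alpha, cut-off variant,
normalization) are echoed into a JSON manifest with per-file checksums for
auditability.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .calls import contrast_genes
from .cohort import (
    REFERENCE,
    SEXES,
    normalize_median,
    read_cohort,
    write_cohort,
)
from .network import build_network
from .scores import compare_treatments, read_gmt, score_table, write_gmt
from .synthetic import CohortConfig, generate_cohort, write_truth

CONTRAST_CONDITIONS = ("BYS", "BYA", "BYP")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending entity."""


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Either ``input_dir`` (a cohort previously written by
    :func:`~pathfabric.cohort.write_cohort`) or ``sim`` (a
    :class:`~pathfabric.synthetic.CohortConfig`, seeded from ``seed``) must
    be given. ``pathway_file`` (GMT) overrides simulated pathway sets.
    """

    outdir: str | Path
    seed: int = 0
    sim: CohortConfig | None = None
    input_dir: str | Path | None = None
    pathway_file: str | Path | None = None
    sexes: tuple[str, ...] = SEXES
    contrasts: tuple[str, ...] = CONTRAST_CONDITIONS
    alpha: float = 0.05
    use_technical_cv: bool = True
    network_pathways: tuple[str, ...] = ()
    write_inputs: bool = False

    def __post_init__(self) -> None:
        if self.sim is None and self.input_dir is None:
            self.sim = CohortConfig(seed=self.seed)
        if self.sim is not None and self.input_dir is not None:
            raise ValueError("give either a simulation config or an input dir, not both")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the manifest dict (also written to disk).

    Outputs under ``config.outdir``: per-(sex, contrast) call tables,
    a consolidated score table (pct_up/pct_down/WPR per pathway and
    condition, GER/PRE per treatment), treatment-comparison p-values,
    per-pathway coordination edge lists, and ``manifest.json``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    # --- stage: input -----------------------------------------------------
    if config.sim is not None:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        cohort, truth = generate_cohort(sim)
        pathways = truth.pathways
        written["truth"] = write_truth(truth, out / "truth.tsv")
        if config.write_inputs:
            written.update(write_cohort(cohort, out / "cohort"))
            write_gmt(pathways, out / "pathways.gmt")
            written["pathways"] = out / "pathways.gmt"
    else:
        indir = Path(config.input_dir)
        try:
            cohort = read_cohort(indir / "expression.tsv", indir / "samples.tsv")
        except Exception as exc:
            raise PipelineError(f"stage 'input': cannot read cohort from {indir}: {exc}")
        pathways = {}
    if config.pathway_file is not None:
        pathways = read_gmt(config.pathway_file)
    if not pathways:
        raise PipelineError("stage 'input': no pathway gene sets provided")

    cohort = normalize_median(cohort)

    # --- stage: calls and scores, per sex ---------------------------------
    manifest: dict = {
        "seed": config.seed,
        "alpha": config.alpha,
        "reference": REFERENCE,
        "normalization": "per-array median division",
        "cutoff": "1 + sqrt(cv_test^2 + cv_ref^2 + tech_test^2 + tech_ref^2)",
        "test": "Welch t on log2 values",
        "use_technical_cv": config.use_technical_cv,
        "sim": None if config.sim is None else dataclasses.asdict(sim),
        "comparisons": {},
    }
    score_frames = []
    for sex in config.sexes:
        contrasts: dict[str, pd.DataFrame] = {}
        for cond in config.contrasts:
            try:
                df = contrast_genes(
                    cohort,
                    sex,
                    cond,
                    alpha=config.alpha,
                    use_technical_cv=config.use_technical_cv,
                )
            except Exception as exc:
                raise PipelineError(f"stage 'calls' ({sex}, {cond} vs {REFERENCE}): {exc}")
            contrasts[cond] = df
            path = out / f"calls_{sex}_{cond}.tsv"
            df.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")
            written[f"calls_{sex}_{cond}"] = path
        try:
            scores = score_table(contrasts, pathways)
        except Exception as exc:
            raise PipelineError(f"stage 'scores' ({sex}): {exc}")
        scores.insert(0, "sex", sex)
        score_frames.append(scores)

        # treatment-vs-treatment comparison over the per-pathway scores
        named = scores[scores["pathway"] != "ALL"]
        for metric in ("pre", "ger"):
            a = named.loc[named["condition"] == "BYA", metric].dropna()
            b = named.loc[named["condition"] == "BYP", metric].dropna()
            if len(a) >= 2 and len(b) >= 2:
                manifest["comparisons"][f"{metric}_BYA_vs_BYP_{sex}"] = (
                    compare_treatments(a, b)
                )

        for pw in config.network_pathways:
            if pw not in pathways:
                raise PipelineError(f"stage 'network' ({sex}): unknown pathway {pw!r}")
            for cond in config.contrasts:
                try:
                    edges = build_network(
                        cohort, sex, cond, pathways[pw], alpha=config.alpha
                    )
                except Exception as exc:
                    raise PipelineError(f"stage 'network' ({sex}, {cond}, {pw}): {exc}")
                path = out / f"network_{sex}_{cond}_{pw}.tsv"
                edges.to_csv(path, sep="\t", index=False, float_format="%.10g")
                written[f"network_{sex}_{cond}_{pw}"] = path

    all_scores = pd.concat(score_frames, ignore_index=True)
    path = out / "scores.tsv"
    all_scores.to_csv(path, sep="\t", index=False, float_format="%.10g")
    written["scores"] = path

    manifest["files"] = {
        name: {"path": str(p), "sha256": _sha256(Path(p))}
        for name, p in sorted(written.items())
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
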