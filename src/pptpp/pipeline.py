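"""End-to-end orchestration: simulate/ingest -> scores -> tests -> rates -> classes.

One :func:`run_pipeline` call reproduces the whole analysis into a run
directory, deterministically for a fixed configuration and seed, and
records a run log with the configuration hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, inference, preprocess, quant_io, scoring, simulate, turnover

log = logging.getLogger(__name__)

ARTIFACTS = (
    "normalized.tsv",
    "scores.tsv",
    "tests.tsv",
    "rates.tsv",
    "classes.tsv",
    "filter_report.tsv",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs.

    ``input_dir`` of ``None`` simulates data with ``sim`` overrides;
    otherwise per-run protein tables plus metadata.tsv are ingested
    from that directory.
    """

    out_dir: str = "pptpp_run"
    input_dir: str | None = None
    sim: dict = field(default_factory=dict)
    filter_rules: dict = field(default_factory=dict)
    normalization_method: str = "vst"
    normalization_grouping: tuple[str, ...] = ("temperature", "label")
    batch_factors: tuple[str, ...] = preprocess.DEFAULT_BATCH_FACTORS
    moderation: bool = True
    quantile_q: float = 0.2
    stability_cutoff: float = 0.5
    tier_stab: float = 0.5
    tier_high: float = 2.9
    iqr_fence: float = 1.5
    annotations_dir: str | None = None
    seed: int = 0

    def config_hash(self) -> str:
        payload = yaml.safe_dump(_jsonable(asdict(self)), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for key in ("normalization_grouping", "batch_factors"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def build_classes(
    summary: pd.DataFrame,
    rates: pd.DataFrame,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Assemble the per-(protein, time) classification table."""
    wide = summary.pivot_table(
        index=["protein_id", "time_min"],
        columns="label",
        values="stability_score",
        aggfunc="first",
    ).reset_index()
    for pool in ("light", "heavy"):
        if pool not in wide.columns:
            wide[pool] = np.nan
        wide[f"stability_class_{pool}"] = classify.stability_classes(
            wide[pool], cutoff=config.stability_cutoff
        ).to_numpy()
    wide["tier"] = classify.stabilization_tiers(
        wide["light"], wide["heavy"], t_stab=config.tier_stab, t_high=config.tier_high
    ).to_numpy()
    wide = wide.rename(
        columns={"light": "stability_score_light", "heavy": "stability_score_heavy"}
    )

    outlier_long, _ = classify.outliers_by_condition(
        summary, value_col="stability_score", fence=config.iqr_fence
    )
    flagged = set(zip(outlier_long["protein_id"], outlier_long["time_min"]))
    wide["is_outlier"] = [
        key in flagged for key in zip(wide["protein_id"], wide["time_min"])
    ]

    try:
        abclasses = classify.abundance_classes(rates, q=config.quantile_q)
        wide = wide.merge(
            abclasses[["protein_id", "abundance_class"]], on="protein_id", how="left"
        )
    except classify.ClassificationError as err:
        log.warning("abundance classes skipped: %s", err)
        wide["abundance_class"] = np.nan
    return wide


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis, writing all artifacts into the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    stage = "setup"
    try:
        stage = "ingest"
        ground_truth = None
        if config.input_dir is None:
            sim_cfg = simulate.SimConfig(**{"seed": config.seed, **config.sim})
            quant, ground_truth = simulate.simulate_experiment(sim_cfg)
            quant_io.write_tidy(ground_truth, out / "ground_truth.tsv")
        else:
            quant = quant_io.load_experiment_dir(config.input_dir)
        quant_io.write_tidy(quant, out / "quant_long.tsv")

        stage = "filter"
        rules = preprocess.FilterRules(**config.filter_rules)
        filtered, report = preprocess.filter_proteins(quant, rules)
        quant_io.write_tidy(report.per_protein, out / "filter_report.tsv")

        stage = "batch_correction"
        corrected = preprocess.correct_batch_effects(
            filtered, factors=tuple(config.batch_factors)
        )

        stage = "normalize"
        normalized, coeffs = preprocess.normalize(
            corrected,
            method=config.normalization_method,
            grouping=tuple(config.normalization_grouping),
        )
        quant_io.write_tidy(normalized, out / "normalized.tsv")
        if len(coeffs):
            quant_io.write_tidy(coeffs, out / "normalization_coefficients.tsv")

        stage = "score"
        fc = scoring.compute_fold_changes(normalized)
        per_rep = scoring.replicate_scores(fc)
        quant_io.write_tidy(per_rep, out / "scores.tsv")
        summary = scoring.summarize_scores(per_rep)
        summary = scoring.z_scale_scores(summary)
        quant_io.write_tidy(summary, out / "scores_summary.tsv")

        stage = "test"
        tests = inference.test_scores(per_rep, moderate=config.moderation)
        quant_io.write_tidy(tests, out / "tests.tsv")

        stage = "turnover"
        rates = turnover.estimate_rates(corrected)
        quant_io.write_tidy(rates, out / "rates.tsv")

        stage = "classify"
        classes = build_classes(summary, rates, config)
        quant_io.write_tidy(classes, out / "classes.tsv")
        if config.annotations_dir:
            annotations = classify.read_annotations(config.annotations_dir)
            groups = classify.annotate_and_summarize(summary, annotations)
            quant_io.write_tidy(groups, out / "group_summaries.tsv")

        stage = "report"
        import pptpp

        run_log = {
            "config": _jsonable(asdict(config)),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "pptpp_version": pptpp.__version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "n_proteins_input": int(quant["protein_id"].nunique()),
            "n_entries_kept": report.n_kept,
            "removed_by_rule": report.removed_by_rule,
            "artifacts": list(ARTIFACTS),
        }
        (out / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))
    except Exception as err:  # pragma: no cover - error path
        failed_marker.write_text(f"stage: {stage}\nerror: {err}\n")
        if isinstance(err, PipelineError):
            raise
        raise PipelineError(stage, err) from err
    return out
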