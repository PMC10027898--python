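"""Abundance and thermal-stability scores from clogger/control ratios.

For each protein, SILAC label, timepoint and replicate, the log2
clogger/control fold change is formed at every temperature of the
gradient. The abundance score is the mean fold change of the two
coolest temperatures (a proxy for protein amount, where essentially no
denaturation has occurred); the stability score is the sum, over the
remaining temperatures, of the abundance-corrected fold changes (a
proxy for a thermal stability shift). Scores are finally z-scaled
within each SILAC label.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

FC_KEY = ["protein_id", "label", "time_min", "replicate"]


class ScoringError(ValueError):
    pass


def compute_fold_changes(normalized: pd.DataFrame) -> pd.DataFrame:
    """Log2 clogger/control fold change per aligned measurement.

    Expects a table with a log2-like ``value`` column (see
    :func:`pptpp.preprocess.normalize`) containing both strains.
    Returns one row per (protein, label, time, replicate, temperature)
    with column ``log2fc``; pairs with either strain missing are
    dropped (masked). Proteins with no aligned pair at all are dropped
    with a logged reason.
    """
    value_col = "value" if "value" in normalized.columns else "signal_sum"
    wide = normalized.pivot_table(
        index=FC_KEY + ["temperature"],
        columns="strain",
        values=value_col,
        aggfunc="first",
    )
    for strain in ("clogger", "control"):
        if strain not in wide.columns:
            raise ScoringError(f"no {strain} measurements in table")
    fc = (wide["clogger"] - wide["control"]).rename("log2fc").reset_index()
    aligned = fc.dropna(subset=["log2fc"])
    lost = set(fc["protein_id"].unique()) - set(aligned["protein_id"].unique())
    if lost:
        log.info("dropping %d proteins with no aligned clogger/control pair", len(lost))
    return aligned.reset_index(drop=True)


def abundance_score(log2fc: np.ndarray, temperatures: np.ndarray, low_temps) -> float:
    """Mean log2 fold change over the available low temperatures.

    NaN if neither low-temperature fold change is present.
    """
    mask = np.isin(temperatures, low_temps) & np.isfinite(log2fc)
    if not mask.any():
        return float("nan")
    return float(np.mean(log2fc[mask]))


def stability_score(
    log2fc: np.ndarray, temperatures: np.ndarray, low_temps, abundance: float
) -> float:
    """Sum of abundance-corrected fold changes over non-low temperatures.

    Division by the abundance ratio in intensity space is subtraction
    in log2 space; missing entries contribute 0 to the sum.
    """
    if not np.isfinite(abundance):
        return float("nan")
    mask = ~np.isin(temperatures, low_temps) & np.isfinite(log2fc)
    return float(np.sum(log2fc[mask] - abundance))


def replicate_scores(
    fold_changes: pd.DataFrame, low_temps=None
) -> pd.DataFrame:
    """Per-(protein, label, time, replicate) abundance and stability scores.

    ``n_temps_used`` counts the fold-change entries present in the
    replicate's gradient vector. Replicates whose both low-temperature
    entries are missing get NaN scores (excluded downstream).
    """
    if low_temps is None:
        gradient = np.sort(fold_changes["temperature"].unique())
        low_temps = tuple(gradient[:2])
    low_temps = np.asarray(low_temps, dtype=float)

    def _one(sub: pd.DataFrame) -> pd.Series:
        temps = sub["temperature"].to_numpy(float)
        fc = sub["log2fc"].to_numpy(float)
        ab = abundance_score(fc, temps, low_temps)
        st = stability_score(fc, temps, low_temps, ab)
        return pd.Series(
            {
                "abundance_score": ab,
                "stability_score": st,
                "n_temps_used": int(np.isfinite(fc).sum()),
            }
        )

    scores = (
        fold_changes.groupby(FC_KEY, sort=True)[["temperature", "log2fc"]]
        .apply(_one)
        .reset_index()
    )
    scores["n_temps_used"] = scores["n_temps_used"].astype(int)
    return scores


def summarize_scores(per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Average replicate scores per (protein, label, time)."""
    key = ["protein_id", "label", "time_min"]
    summary = (
        per_replicate.dropna(subset=["abundance_score"])
        .groupby(key)
        .agg(
            abundance_score=("abundance_score", "mean"),
            stability_score=("stability_score", "mean"),
            n_replicates=("replicate", "nunique"),
            n_temps_used=("n_temps_used", "mean"),
        )
        .reset_index()
    )
    return summary


def z_scale_scores(summary: pd.DataFrame, grouping=("label",)) -> pd.DataFrame:
    """Z-scale abundance and stability scores within each group.

    The default grouping scales each SILAC label separately; raw scores
    are retained alongside ``z_abundance`` / ``z_stability``.
    """
    out = summary.copy()
    for col, zcol in (
        ("abundance_score", "z_abundance"),
        ("stability_score", "z_stability"),
    ):
        def _z(s: pd.Series) -> pd.Series:
            vals = s.dropna()
            if len(vals) < 2:
                raise ScoringError(f"group too small to z-scale {col}")
            sd = vals.std(ddof=1)
            if sd == 0:
                raise ScoringError(f"zero variance in {col} group")
            return (s - vals.mean()) / sd

        out[zcol] = out.groupby(list(grouping), group_keys=False)[col].transform(_z)
    return out
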