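"""Categorical classification of proteins from scores and rate ratios.

Implements the rule set used for the figure-level summaries: abundance
classes from dK quantiles (top/bottom 20% = considerable change),
stability classes from a +/-0.5 score cutoff, two-tier stabilization
calls combining light and heavy pools, Tukey IQR outliers per
(timepoint, pool), and annotation-group summary statistics.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import inference


def _astuple(key) -> tuple:
    """Groupby key as a tuple without dtype coercion."""
    return key if isinstance(key, tuple) else (key,)

log = logging.getLogger(__name__)


class ClassificationError(ValueError):
    pass


def quantile_classes(values, q: float = 0.2) -> pd.Series:
    """Classify dK values as up / down / unchanged by empirical quantiles.

    Values at or above the (1-q) quantile are "up", at or below the q
    quantile "down" (ties at a cutoff fall in the extreme class).
    Quantiles use the finite values only, with linear interpolation.
    If every value sits in both extremes (all equal), the degenerate
    case resolves to "unchanged".
    """
    s = pd.Series(values, dtype=float)
    finite = s[np.isfinite(s)]
    if len(finite) < 5:
        raise ClassificationError("need >= 5 finite values for quantile classes")
    if not (0 <= q <= 0.5):
        raise ClassificationError("q must be in [0, 0.5]")
    out = pd.Series("unchanged", index=s.index, dtype=object)
    out[~np.isfinite(s)] = np.nan
    if q == 0:
        return out
    lo = float(np.quantile(finite, q))
    hi = float(np.quantile(finite, 1.0 - q))
    up = s >= hi
    down = s <= lo
    both = up & down  # degenerate ties spanning both cutoffs
    out[up & ~both] = "up"
    out[down & ~both] = "down"
    out[~np.isfinite(s)] = np.nan
    return out


def stability_classes(scores, cutoff: float = 0.5) -> pd.Series:
    """Stabilized / destabilized / unchanged by a strict score cutoff.

    A stability score above +cutoff is "stabilized", below -cutoff
    "destabilized"; exactly +/-cutoff counts as unchanged (the rule is
    strictly "below -0.5 or above 0.5").
    """
    s = pd.Series(scores, dtype=float)
    out = pd.Series("unchanged", index=s.index, dtype=object)
    out[s > cutoff] = "stabilized"
    out[s < -cutoff] = "destabilized"
    out[~np.isfinite(s)] = np.nan
    return out


def stabilization_tiers(
    light_score, heavy_score, t_stab: float = 0.5, t_high: float = 2.9
):
    """Two-tier stabilization call from the light/heavy pool scores.

    highly_stabilized: light > t_high and heavy > t_stab;
    stabilized: light > t_stab and heavy > t_stab; otherwise none.
    Missing pool scores leave the tier undefined (NaN).
    """
    light = pd.Series(np.atleast_1d(np.asarray(light_score, dtype=float)))
    heavy = pd.Series(np.atleast_1d(np.asarray(heavy_score, dtype=float)))
    out = pd.Series("none", index=light.index, dtype=object)
    out[(light > t_stab) & (heavy > t_stab)] = "stabilized"
    out[(light > t_high) & (heavy > t_stab)] = "highly_stabilized"
    out[~np.isfinite(light) | ~np.isfinite(heavy)] = np.nan
    if np.isscalar(light_score) and np.isscalar(heavy_score):
        return out.iloc[0]
    return out


def iqr_outliers(
    values, fence: float = 1.5, side: str = "both"
) -> pd.Index:
    """Tukey IQR outliers of one (timepoint, pool) score collection.

    Low outliers fall below Q1 - fence*IQR, high outliers above
    Q3 + fence*IQR; quartiles by linear interpolation. A zero IQR
    (most of the mass on a single value) is degenerate: no spread is
    measurable, so no outliers are called.
    """
    if side not in ("low", "high", "both"):
        raise ClassificationError(f"invalid side {side!r}")
    s = pd.Series(values, dtype=float)
    finite = s[np.isfinite(s)]
    if len(finite) < 4:
        raise ClassificationError("need >= 4 values for IQR outliers")
    q1, q3 = np.quantile(finite, [0.25, 0.75])
    iqr = q3 - q1
    if iqr == 0:
        return s.index[:0]
    mask = pd.Series(False, index=s.index)
    if side in ("low", "both"):
        mask |= s < q1 - fence * iqr
    if side in ("high", "both"):
        mask |= s > q3 + fence * iqr
    return s.index[mask.fillna(False)]


def outliers_by_condition(
    scores: pd.DataFrame,
    value_col: str = "stability_score",
    by: tuple[str, ...] = ("time_min", "label"),
    fence: float = 1.5,
    side: str = "both",
) -> tuple[pd.DataFrame, pd.Index]:
    """IQR outliers per (timepoint, pool) plus their deduplicated union.

    Returns a long table with one row per outlier occurrence (keeping
    the condition it was flagged in, i.e. union-with-provenance) and
    the unique protein index.
    """
    frames = []
    for gkey, sub in scores.groupby(list(by)):
        sub = sub.set_index("protein_id")
        try:
            idx = iqr_outliers(sub[value_col], fence=fence, side=side)
        except ClassificationError:
            continue
        hit = sub.loc[idx, [value_col]].reset_index()
        for col, val in zip(by, _astuple(gkey)):
            hit[col] = val
        frames.append(hit)
    if frames:
        long = pd.concat(frames, ignore_index=True)
    else:
        long = pd.DataFrame(columns=["protein_id", value_col, *by])
    unique = pd.Index(long["protein_id"].unique(), name="protein_id")
    return long, unique


def abundance_classes(
    rates: pd.DataFrame, q: float = 0.2
) -> pd.DataFrame:
    """Joint synthesis/degradation abundance classes from dKS and dKD."""
    out = rates[["protein_id", "delta_ks", "delta_kd"]].dropna().copy()
    if len(out) < 5:
        raise ClassificationError("too few proteins with both delta rates")
    out["class_delta_ks"] = quantile_classes(out["delta_ks"], q=q).to_numpy()
    out["class_delta_kd"] = quantile_classes(out["delta_kd"], q=q).to_numpy()
    out["abundance_class"] = (
        "synthesis-" + out["class_delta_ks"] + "/degradation-" + out["class_delta_kd"]
    )
    return out


def read_annotations(directory) -> dict[str, set[str]]:
    """Read one-ID-per-line annotation lists named ``<group>.txt``."""
    directory = Path(directory)
    annotations = {}
    for path in sorted(directory.glob("*.txt")):
        ids = {line.strip() for line in path.read_text().splitlines() if line.strip()}
        annotations[path.stem] = ids
    return annotations


def annotate_and_summarize(
    scores: pd.DataFrame,
    annotations: dict[str, set[str]],
    by: tuple[str, ...] = ("label", "time_min"),
) -> pd.DataFrame:
    """Group-level score summaries with a KS test against the complement.

    For each annotation group and (label, time) condition: member
    count, median and IQR of the abundance and stability scores, and
    the two-sample Kolmogorov-Smirnov test of the group's stability
    scores against all other proteins. Empty groups yield a warning
    row with count 0.
    """
    rows = []
    for name, members in annotations.items():
        in_group = scores["protein_id"].isin(members)
        if not in_group.any():
            log.warning("annotation group %s matches no protein", name)
        for gkey, sub in scores.groupby(list(by)):
            g = sub[sub["protein_id"].isin(members)]
            bg = sub[~sub["protein_id"].isin(members)]
            rec = dict(zip(by, _astuple(gkey))) | {"group": name, "n": len(g)}
            for col in ("abundance_score", "stability_score"):
                vals = g[col].dropna()
                rec[f"median_{col}"] = float(vals.median()) if len(vals) else np.nan
                rec[f"iqr_{col}"] = (
                    float(np.subtract(*np.quantile(vals, [0.75, 0.25])))
                    if len(vals)
                    else np.nan
                )
            g_vals = g["stability_score"].dropna()
            bg_vals = bg["stability_score"].dropna()
            if len(g_vals) and len(bg_vals):
                d, p = inference.ks_two_sample(g_vals, bg_vals)
                rec["ks_d"], rec["ks_p"] = d, p
            else:
                rec["ks_d"] = rec["ks_p"] = np.nan
            rows.append(rec)
    return pd.DataFrame(rows)
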