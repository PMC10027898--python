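"""Identification filtering, batch-effect cleaning and normalization.

Proteins enter the analysis only if identified with at least two unique
peptides, seen in two of three runs at one of the two coolest gradient
points, in a minimum number of temperatures, and in a minimum number of
MS runs overall. Log2 intensities are then cleaned for per-run (batch)
offsets with an additive per-protein linear model, and
variance-stabilized within each (temperature, SILAC label) group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quant_io import QUANT_COLUMNS


def _astuple(key) -> tuple:
    """Groupby key as a tuple without dtype coercion."""
    return key if isinstance(key, tuple) else (key,)

log = logging.getLogger(__name__)

RULE_ORDER = (
    "min_unique_peptides",
    "min_runs_at_low_temp",
    "min_temperatures",
    "min_total_runs",
)


class DesignError(ValueError):
    """Invalid filter rules or confounded experimental design."""


@dataclass
class FilterRules:
    """Identification-quality filter thresholds.

    Defaults follow the source workflow: >= 2 unique peptides; observed
    in >= 2 of 3 replicate runs at one of the two coolest temperatures;
    observed at >= 5 of 11 temperatures; observed in >= 8 MS runs.
    """

    min_unique_peptides: int = 2
    low_temps: tuple[float, float] | None = None  # default: two coolest in table
    min_runs_at_low_temp: int = 2
    min_temperatures: int = 5
    min_total_runs: int = 8

    def __post_init__(self) -> None:
        counts = (
            self.min_unique_peptides,
            self.min_runs_at_low_temp,
            self.min_temperatures,
            self.min_total_runs,
        )
        if any(c < 1 for c in counts):
            raise DesignError("all filter counts must be >= 1")


@dataclass
class FilterReport:
    """Outcome of protein filtering with first-failing-rule attribution."""

    n_input: int
    n_kept: int
    removed_by_rule: dict[str, int] = field(default_factory=dict)
    per_protein: pd.DataFrame | None = None  # protein_id, label, status


def filter_proteins(
    table: pd.DataFrame, rules: FilterRules | None = None
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the identification filters per (protein, SILAC label).

    Rules are evaluated in a fixed order (unique peptides, low-temperature
    runs, temperatures, total runs) and each removed entry is attributed
    to the first rule it fails.
    """
    rules = rules or FilterRules()
    gradient = np.sort(table["temperature"].unique())
    low_temps = rules.low_temps
    if low_temps is None:
        low_temps = tuple(gradient[:2])
    if not set(low_temps) <= set(gradient):
        raise DesignError(
            f"low_temps {low_temps} not part of the gradient {list(gradient)}"
        )

    obs = table.dropna(subset=["signal_sum"])
    groups = obs.groupby(["protein_id", "label"])
    stats = pd.DataFrame(
        {
            "qupm": groups["qupm"].max(),
            "n_temperatures": groups["temperature"].nunique(),
        }
    )
    run_pairs = obs[["protein_id", "label", "temperature", "replicate"]].drop_duplicates()
    stats["n_total_runs"] = run_pairs.groupby(["protein_id", "label"]).size()
    low = run_pairs[run_pairs["temperature"].isin(low_temps)]
    low_counts = (
        low.groupby(["protein_id", "label", "temperature"]).size()
        .groupby(["protein_id", "label"]).max()
    )
    stats["max_low_temp_runs"] = low_counts.reindex(stats.index).fillna(0).astype(int)

    fails = {
        "min_unique_peptides": stats["qupm"] < rules.min_unique_peptides,
        "min_runs_at_low_temp": stats["max_low_temp_runs"] < rules.min_runs_at_low_temp,
        "min_temperatures": stats["n_temperatures"] < rules.min_temperatures,
        "min_total_runs": stats["n_total_runs"] < rules.min_total_runs,
    }
    status = pd.Series("kept", index=stats.index, name="status")
    for rule in reversed(RULE_ORDER):  # earlier rules overwrite later ones
        status[fails[rule]] = rule
    per_protein = status.reset_index()

    kept_keys = per_protein.loc[per_protein["status"] == "kept", ["protein_id", "label"]]
    filtered = table.merge(kept_keys, on=["protein_id", "label"], how="inner")
    filtered = filtered.reset_index(drop=True)
    report = FilterReport(
        n_input=len(stats),
        n_kept=len(kept_keys),
        removed_by_rule={
            rule: int((per_protein["status"] == rule).sum()) for rule in RULE_ORDER
        },
        per_protein=per_protein,
    )
    return filtered, report


DEFAULT_BATCH_FACTORS = ("strain", "time_min", "label", "temperature")


def _design_matrices(
    table: pd.DataFrame, factors: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray]:
    """Condition (intercept + treatment-coded) and sum-coded batch matrices."""
    n = len(table)
    cond_cols = [np.ones(n)]
    for f in factors:
        levels = np.sort(table[f].unique())
        for lev in levels[1:]:
            cond_cols.append((table[f] == lev).to_numpy(float))
    x_cond = np.column_stack(cond_cols)

    batches = np.sort(table["batch"].unique())
    codes = table["batch"].map({b: i for i, b in enumerate(batches)}).to_numpy()
    k = len(batches)
    x_batch = np.zeros((n, k - 1))
    for j in range(k - 1):
        x_batch[codes == j, j] = 1.0
    x_batch[codes == k - 1, :] = -1.0
    return x_cond, x_batch


def correct_batch_effects(
    table: pd.DataFrame,
    factors: tuple[str, ...] = DEFAULT_BATCH_FACTORS,
) -> pd.DataFrame:
    """Remove per-batch log2 offsets, protein by protein.

    Fits, for each protein, an additive least-squares model of log2
    intensity on the declared condition factors plus sum-coded batch
    offsets, and subtracts the estimated batch component. Intensities
    are returned back-transformed (strictly positive). A single batch
    is a no-op; a batch aliased with a condition factor raises
    :class:`DesignError`.
    """
    factors = tuple(f for f in factors if table[f].nunique() > 1)
    if table["batch"].nunique() < 2:
        return table.copy()

    obs_mask = table["signal_sum"].notna().to_numpy()
    x_cond, x_batch = _design_matrices(table, factors)

    # aliasing check on observed rows: batch contrasts must not lie in
    # the span of the condition design
    xo_c, xo_b = x_cond[obs_mask], x_batch[obs_mask]
    q, _ = np.linalg.qr(xo_c)
    resid = xo_b - q @ (q.T @ xo_b)
    col_norms = np.linalg.norm(resid, axis=0)
    if np.any(col_norms < 1e-8 * max(1.0, np.linalg.norm(xo_b))):
        raise DesignError("batch is aliased with the condition design")

    y = np.log2(table["signal_sum"].to_numpy(float))

    out = table.copy()
    corrected = np.full(len(table), np.nan)
    idx_by_protein = table.groupby("protein_id", sort=False).indices
    for _, idx in idx_by_protein.items():
        rows = idx[obs_mask[idx]]
        if len(rows) == 0:
            continue
        # batch contrasts orthogonal to the condition design: the
        # removed component then cannot absorb condition effects, and
        # nesting of batches within a condition factor stays harmless
        qc, _ = np.linalg.qr(x_cond[rows])
        b = x_batch[rows]
        b_perp = b - qc @ (qc.T @ b)
        keep = np.linalg.norm(b_perp, axis=0) > 1e-10 * max(1.0, np.linalg.norm(b))
        if not keep.any():
            corrected[rows] = y[rows]
            continue
        beta_b, *_ = np.linalg.lstsq(b_perp[:, keep], y[rows], rcond=None)
        corrected[rows] = y[rows] - b_perp[:, keep] @ beta_b
    out["signal_sum"] = 2.0 ** corrected
    return out


GLOG_QUANTILE = 0.05


class NormalizationError(ValueError):
    pass


def normalize(
    table: pd.DataFrame,
    method: str = "vst",
    grouping: tuple[str, ...] = ("temperature", "label"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize and variance-stabilize intensities within groups.

    Within each group (by default each temperature x SILAC label, the
    unit in which normalization coefficients are estimated), one
    "sample" is a (strain, time, replicate) channel.

    Methods
    -------
    ``vst``
        Per-sample scale factor from the median ratio to a
        geometric-mean reference profile, followed by a generalized-log
        transform ``glog2(x, c) = log2((x + sqrt(x^2 + c^2)) / 2)``
        with softening constant ``c`` set to a low quantile of the
        rescaled intensities. Asymptotically log2 for large x, monotone
        throughout.
    ``median_log2``
        Equalize per-sample medians on log2 scale (group grand median
        preserved).
    ``log2``
        Plain log2 transform; no coefficients estimated. Useful when
        global composition shifts must not be absorbed.

    Returns the table with a ``value`` column (log2-like transformed
    intensity) and a coefficient table for reporting.
    """
    if method not in ("vst", "median_log2", "log2"):
        raise NormalizationError(f"unknown method {method!r}")
    out = table.copy()
    out["value"] = np.nan
    sample_cols = [c for c in ("strain", "time_min", "replicate") if c in out.columns]
    coeff_rows = []

    for gkey, sub in out.groupby(list(grouping)):
        present = sub.dropna(subset=["signal_sum"])
        if present.empty:
            continue
        if method == "log2":
            out.loc[present.index, "value"] = np.log2(present["signal_sum"])
            continue
        n_samples = present.groupby(sample_cols).ngroups
        if n_samples < 2:
            raise NormalizationError(
                f"group {gkey}: fewer than 2 samples, no coefficients estimable"
            )
        if method == "median_log2":
            v = np.log2(present["signal_sum"])
            med = v.groupby([present[c] for c in sample_cols]).transform("median")
            grand = v.groupby([present[c] for c in sample_cols]).median().median()
            out.loc[present.index, "value"] = v - med + grand
            for skey, m in v.groupby([present[c] for c in sample_cols]).median().items():
                coeff_rows.append(
                    dict(zip(grouping, _astuple(gkey)))
                    | dict(zip(sample_cols, _astuple(skey)))
                    | {"offset_log2": m - grand}
                )
        else:  # vst
            wide = present.pivot_table(
                index="protein_id",
                columns=sample_cols,
                values="signal_sum",
                aggfunc="first",
            )
            ref = np.exp(np.nanmean(np.log(wide.to_numpy(float)), axis=1))
            scale = (wide.to_numpy(float) / ref[:, None])
            s_j = np.nanmedian(scale, axis=0)
            s_j = s_j / np.exp(np.mean(np.log(s_j)))  # preserve group location
            rescaled = wide.to_numpy(float) / s_j[None, :]
            c = np.nanquantile(rescaled, GLOG_QUANTILE)
            c = max(c, 1e-12)
            glog = np.log2((rescaled + np.sqrt(rescaled**2 + c**2)) / 2.0)
            glog_df = pd.DataFrame(glog, index=wide.index, columns=wide.columns)
            stacked = glog_df.stack(sample_cols, future_stack=True).rename("value")
            sub_keys = pd.MultiIndex.from_frame(present[["protein_id"] + sample_cols])
            out.loc[present.index, "value"] = stacked.reindex(sub_keys).to_numpy()
            for skey, s in zip(wide.columns, s_j):
                coeff_rows.append(
                    dict(zip(grouping, _astuple(gkey)))
                    | dict(zip(sample_cols, _astuple(skey)))
                    | {"scale": s, "glog_c": c}
                )
    coeffs = pd.DataFrame(coeff_rows)
    return out, coeffs
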