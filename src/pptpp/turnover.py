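"""Synthesis (KS) and degradation (KD) rate constants from 37 degC trajectories.

Pulsed-SILAC kinetics are assumed exponential: the heavy (newly
synthesized) pool accumulates and the light (pre-existing) pool decays
exponentially along the time course, so ordinary least squares on
natural-log intensity versus time identifies the rate constant from
the 3-4 available timepoints. Inputs are batch-corrected intensities
on the natural scale (variance-stabilized values would distort the
exponential slopes). dKS / dKD are clogger/control slope ratios.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SYNTHESIS_TIMES = (30.0, 90.0, 270.0)
DEGRADATION_TIMES = (0.0, 30.0, 90.0, 270.0)
REFERENCE_TEMPERATURE = 37.0


class TurnoverError(ValueError):
    pass


def _log_linear_fit(times: np.ndarray, intensities: np.ndarray) -> tuple[float, float, int]:
    """OLS slope of ln(intensity) on time; returns (slope, r2, n_used).

    Non-positive or missing intensities are excluded. Fewer than 2
    usable points yields (nan, nan, n); r2 is nan below 3 points.
    """
    times = np.asarray(times, dtype=float)
    y = np.asarray(intensities, dtype=float)
    ok = np.isfinite(y) & (y > 0) & np.isfinite(times)
    n_excluded = int(np.isfinite(y).sum() - ok.sum())
    if n_excluded:
        log.debug("excluded %d non-positive intensities from rate fit", n_excluded)
    t, ly = times[ok], np.log(y[ok])
    n = len(t)
    if n < 2 or len(np.unique(t)) < 2:
        return float("nan"), float("nan"), n
    slope, intercept = np.polyfit(t, ly, 1)
    if n < 3:
        return float(slope), float("nan"), n
    resid = ly - (slope * t + intercept)
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(r2), n


def fit_synthesis_rate(times, heavy) -> tuple[float, float, int]:
    """KS (1/min) from heavy-pool accumulation: the ln-intensity slope."""
    slope, r2, n = _log_linear_fit(times, heavy)
    return slope, r2, n


def fit_degradation_rate(times, light) -> tuple[float, float, int]:
    """KD (1/min) from light-pool decay: minus the ln-intensity slope.

    An increasing light pool yields KD < 0, reported as-is (flag via r2
    and sign), never clipped.
    """
    slope, r2, n = _log_linear_fit(times, light)
    return -slope if np.isfinite(slope) else slope, r2, n


def delta_rate(k_clogger: float, k_control: float) -> float:
    """Clogger/control rate ratio; NaN (logged) when the control rate is 0."""
    if not np.isfinite(k_clogger) or not np.isfinite(k_control):
        return float("nan")
    if k_control == 0:
        log.info("control rate is zero; delta ratio undefined")
        return float("nan")
    return k_clogger / k_control


def estimate_rates(
    table: pd.DataFrame,
    reference_temperature: float = REFERENCE_TEMPERATURE,
    min_points_for_delta: int = 3,
) -> pd.DataFrame:
    """Fit KS/KD per (protein, strain) and form dKS/dKD ratios.

    Parameters
    ----------
    table : long quantification table (batch-corrected, natural scale)
    reference_temperature : gradient point used for the kinetics
        (lowest temperature: essentially no thermal denaturation)
    min_points_for_delta : minimum usable points in both strains' fits
        for a delta ratio to be reported

    Returns one row per protein with ks/kd, fit r2 and point counts per
    strain, plus delta_ks / delta_kd.
    """
    at_ref = table[np.isclose(table["temperature"], reference_temperature)]
    if at_ref.empty:
        raise TurnoverError(
            f"no measurements at reference temperature {reference_temperature}"
        )
    rows = []
    for (pid, strain), sub in at_ref.groupby(["protein_id", "strain"]):
        heavy = sub[(sub["label"] == "heavy") & (sub["time_min"] > 0)]
        light = sub[sub["label"] == "light"]
        ks, r2_ks, n_ks = fit_synthesis_rate(
            heavy["time_min"].to_numpy(), heavy["signal_sum"].to_numpy()
        )
        kd, r2_kd, n_kd = fit_degradation_rate(
            light["time_min"].to_numpy(), light["signal_sum"].to_numpy()
        )
        rows.append(
            {
                "protein_id": pid,
                "strain": strain,
                "ks": ks,
                "r2_ks": r2_ks,
                "n_ks": n_ks,
                "kd": kd,
                "r2_kd": r2_kd,
                "n_kd": n_kd,
            }
        )
    rates = pd.DataFrame(rows)
    wide = rates.pivot(index="protein_id", columns="strain")
    out = rates.copy()
    deltas = []
    for pid in wide.index:
        rec = {"protein_id": pid}
        for rate, npts in (("ks", "n_ks"), ("kd", "n_kd")):
            try:
                k_clg = wide.loc[pid, (rate, "clogger")]
                k_ctl = wide.loc[pid, (rate, "control")]
                n_clg = wide.loc[pid, (npts, "clogger")]
                n_ctl = wide.loc[pid, (npts, "control")]
            except KeyError:
                rec[f"delta_{rate}"] = float("nan")
                continue
            if (
                np.isfinite(k_ctl)
                and k_ctl != 0
                and n_clg >= min_points_for_delta
                and n_ctl >= min_points_for_delta
            ):
                rec[f"delta_{rate}"] = delta_rate(k_clg, k_ctl)
            else:
                rec[f"delta_{rate}"] = float("nan")
        deltas.append(rec)
    out = out.merge(pd.DataFrame(deltas), on="protein_id", how="left")
    return out
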