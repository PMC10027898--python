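"""Significance machinery for the score tables.

Per-replicate scores are tested for a nonzero mean with a weighted,
empirical-Bayes moderated one-sample t-statistic: per-protein weighted
variances are shrunk toward a common prior estimated from the whole
ensemble by moment matching on log variances. The resulting t-values
are then decomposed against an empirical null — a central half-normal
fitted to |t| by truncated maximum likelihood — from which two-sided
p-values, local false discovery rates and tail-area q-values are
extracted. Identification counts serve as per-replicate precision
weights.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import minimize_scalar


def _astuple(key) -> tuple:
    """Groupby key as a tuple without dtype coercion."""
    return key if isinstance(key, tuple) else (key,)

log = logging.getLogger(__name__)


class InferenceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x by Newton iteration."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x  # good starting value for the inverse
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) / np.maximum(y, 1e-12) < 1e-10):
            break
    return y


def fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Estimate prior df d0 and prior variance s0^2 from sample variances.

    Moment matching on log variances: if s2 ~ s0^2 * F(df, d0), then
    log s2 has known mean/variance expressible through digamma and
    trigamma functions.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s2) & (df > 0)
    s2, df = s2[ok], df[ok]
    if len(s2) < 2:
        return np.inf, float(np.mean(s2)) if len(s2) else 1.0
    z = np.log(np.maximum(s2, 1e-300))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, df / 2.0)))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = float(2.0 * _trigamma_inverse(np.array(e_var)))
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_score_test(
    scores: pd.DataFrame,
    score_col: str,
    weight_col: str | None = "n_temps_used",
    group_cols: tuple[str, ...] = ("label", "time_min"),
    moderate: bool = True,
) -> pd.DataFrame:
    """Weighted moderated one-sample test of mean score != 0.

    Parameters
    ----------
    scores : per-replicate score table (one row per protein x replicate)
    score_col : column holding the per-replicate score
    weight_col : per-replicate precision weights (identification counts);
        weights are rescaled to mean 1 within each protein so uniform
        weights reproduce the ordinary t-statistic
    group_cols : the moderation ensembles — the variance prior is
        estimated separately within each (label, time) stratum
    moderate : disable to obtain the ordinary weighted t (prior df 0)

    Returns one row per (protein, *group_cols*) with columns t,
    df_total, mean, n_replicates, tested.
    """
    rows = []
    for gkey, sub in scores.groupby(list(group_cols)):
        per_protein = []
        for pid, ps in sub.groupby("protein_id"):
            x = ps[score_col].to_numpy(float)
            w = (
                ps[weight_col].to_numpy(float)
                if weight_col is not None
                else np.ones_like(x)
            )
            ok = np.isfinite(x) & np.isfinite(w)
            x, w = x[ok], w[ok]
            if len(x) and np.any(w <= 0):
                raise InferenceError(f"non-positive weights for {pid}")
            if len(x) < 2:
                per_protein.append((pid, np.nan, np.nan, np.nan, len(x), False))
                continue
            w = w / w.mean()
            wmean = float(np.sum(w * x) / np.sum(w))
            d = len(x) - 1
            s2 = float(np.sum(w * (x - wmean) ** 2) / d)
            per_protein.append((pid, wmean, s2, np.sum(w), d, True))

        tested = [r for r in per_protein if r[5]]
        if tested and moderate:
            d0, s0_sq = fit_variance_prior(
                np.array([r[2] for r in tested]), np.array([r[4] for r in tested])
            )
        else:
            d0, s0_sq = 0.0, 0.0
        for pid, wmean, s2, wsum, d, was_tested in per_protein:
            if not was_tested:
                rows.append(
                    dict(zip(group_cols, _astuple(gkey)))
                    | {
                        "protein_id": pid,
                        "mean": np.nan,
                        "t": np.nan,
                        "df_total": np.nan,
                        "n_replicates": d,
                        "tested": False,
                    }
                )
                continue
            if np.isfinite(d0):
                s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
                df_total = d + d0
            else:
                s2_post = s0_sq
                df_total = np.inf
            if s2_post <= 0:
                t = 0.0 if wmean == 0 else np.inf * np.sign(wmean)
            else:
                t = wmean / np.sqrt(s2_post / wsum)
            rows.append(
                dict(zip(group_cols, _astuple(gkey)))
                | {
                    "protein_id": pid,
                    "mean": wmean,
                    "t": float(t),
                    "df_total": float(df_total),
                    "n_replicates": d + 1,
                    "tested": True,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# empirical null and fdr extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmpiricalNull:
    """Central null component fitted to an ensemble of t-values."""

    eta0: float  # estimated null proportion, in (0, 1]
    null_scale: float  # sd of the central (null) distribution
    truncation: float  # |t| cutoff used for the truncated fit

    def __post_init__(self) -> None:
        if not (self.null_scale > 0):
            raise InferenceError("null_scale must be > 0")


_HN_90 = stats.halfnorm.ppf(0.9)  # 90% quantile of the standard half-normal


def fit_empirical_null(
    t_values, truncation: float | None = None, n_iter: int = 4
) -> EmpiricalNull:
    """Fit a central half-normal to |t| by truncated maximum likelihood.

    The truncation point is chosen adaptively (false-nondiscovery
    heuristic): starting from a robust scale estimate, the cutoff is
    placed at the 90% mass point of the current null fit and the
    truncated MLE re-solved, so that values dominated by the
    alternative do not enter the null fit. eta0 is the fraction of
    values below the cutoff divided by the null mass below it.
    """
    t = np.asarray(t_values, dtype=float)
    t = np.abs(t[np.isfinite(t)])
    n = len(t)
    if n < 2 or np.ptp(t) == 0:
        raise InferenceError("degenerate t-value ensemble")
    if n < 200:
        warnings.warn(f"only {n} t-values; empirical-null fit may be unstable")

    sigma = float(np.median(t) / stats.halfnorm.ppf(0.5))
    fixed_cutoff = truncation is not None
    x0 = truncation if fixed_cutoff else sigma * _HN_90
    for _ in range(n_iter):
        inside = t[t <= x0]
        if len(inside) < 2:
            raise InferenceError("truncation point leaves < 2 values")

        def nll(s: float) -> float:
            mass = 2.0 * stats.norm.cdf(x0 / s) - 1.0
            return float(
                np.sum(inside**2) / (2 * s**2)
                + len(inside) * (np.log(s) + np.log(mass))
            )

        res = minimize_scalar(nll, bounds=(1e-3 * sigma + 1e-12, 10 * sigma + 1.0),
                              method="bounded")
        sigma = float(res.x)
        if fixed_cutoff:
            break
        new_x0 = sigma * _HN_90
        if abs(new_x0 - x0) < 1e-9:
            x0 = new_x0
            break
        x0 = new_x0
    null_mass = 2.0 * stats.norm.cdf(x0 / sigma) - 1.0
    eta0 = min(1.0, (np.sum(t <= x0) / n) / null_mass)
    return EmpiricalNull(eta0=float(eta0), null_scale=sigma, truncation=float(x0))


def _grenander_density(x_sorted: np.ndarray) -> np.ndarray:
    """Decreasing density estimate on [0, inf) at the sorted sample points.

    Slopes of the least concave majorant of the ECDF (Grenander
    estimator), computed with a monotone stack.
    """
    n = len(x_sorted)
    xs = np.concatenate([[0.0], x_sorted])
    ys = np.arange(n + 1) / n
    # upper concave hull of the ECDF points
    hull = [0]
    for i in range(1, n + 1):
        while len(hull) >= 2:
            i0, i1 = hull[-2], hull[-1]
            s1 = (ys[i1] - ys[i0]) / max(xs[i1] - xs[i0], 1e-300)
            s2 = (ys[i] - ys[i1]) / max(xs[i] - xs[i1], 1e-300)
            if s2 >= s1:
                hull.pop()
            else:
                break
        hull.append(i)
    dens = np.empty(n)
    for a, b in zip(hull[:-1], hull[1:]):
        slope = (ys[b] - ys[a]) / max(xs[b] - xs[a], 1e-300)
        dens[a: b] = slope  # indices a..b-1 in the padded array = samples a..b-1
    return dens


def fdr_from_null(t_values, null: EmpiricalNull) -> pd.DataFrame:
    """Two-sided p, local fdr and tail-area q for each t-value.

    p comes from the fitted null scale; lfdr = eta0 * f0 / f with the
    mixture density f estimated by a monotone (Grenander) estimate on
    |t|; q is the tail-area false discovery rate. Both lfdr and q are
    clipped to [0, 1] and enforced non-increasing in |t|.
    """
    t = np.asarray(t_values, dtype=float)
    out = pd.DataFrame({"t": t})
    at = np.abs(t)
    ok = np.isfinite(at)
    sigma, eta0 = null.null_scale, null.eta0

    p = np.full_like(t, np.nan)
    p[ok] = 2.0 * stats.norm.sf(at[ok] / sigma)
    out["p"] = p

    a = at[ok]
    order = np.argsort(a, kind="mergesort")
    a_sorted = a[order]
    n = len(a_sorted)

    f_mix = _grenander_density(a_sorted)
    f0 = 2.0 * stats.norm.pdf(a_sorted / sigma) / sigma
    lfdr_sorted = np.clip(eta0 * f0 / np.maximum(f_mix, 1e-300), 0.0, 1.0)
    lfdr_sorted = np.maximum.accumulate(lfdr_sorted[::-1])[::-1]  # non-increasing in |t|

    tail_frac = (n - np.arange(n)) / n  # fraction of |t| >= a_sorted[i] (ties: lower bound)
    surv0 = 2.0 * stats.norm.sf(a_sorted / sigma)
    q_sorted = np.clip(eta0 * surv0 / tail_frac, 0.0, 1.0)
    q_sorted = np.maximum.accumulate(q_sorted[::-1])[::-1]

    lfdr = np.full_like(t, np.nan)
    q = np.full_like(t, np.nan)
    idx_ok = np.flatnonzero(ok)
    lfdr[idx_ok[order]] = lfdr_sorted
    q[idx_ok[order]] = q_sorted
    out["lfdr"] = lfdr
    out["q"] = q
    return out


def test_scores(
    per_replicate: pd.DataFrame,
    weight_col: str | None = "n_temps_used",
    moderate: bool = True,
    truncation: float | None = None,
) -> pd.DataFrame:
    """Full significance pass over a per-replicate score table.

    For each score type (abundance, stability) and each (label, time)
    stratum: moderated weighted t, then empirical-null p / lfdr / q
    from the stratum's t ensemble. Returns a long table with one row
    per (protein, label, time, score_type).
    """
    frames = []
    for score_type, col in (("abundance", "abundance_score"), ("stability", "stability_score")):
        res = moderated_score_test(
            per_replicate, col, weight_col=weight_col, moderate=moderate
        )
        res["score_type"] = score_type
        for _, sub in res.groupby(["label", "time_min"]):
            tested = sub["tested"] & np.isfinite(sub["t"])
            tvals = sub.loc[tested, "t"].to_numpy()
            block = sub.copy()
            block[["p", "lfdr", "q"]] = np.nan
            if tested.sum() >= 2 and np.ptp(tvals) > 0:
                null = fit_empirical_null(tvals, truncation=truncation)
                fdr = fdr_from_null(tvals, null)
                block.loc[tested, ["p", "lfdr", "q"]] = fdr[["p", "lfdr", "q"]].to_numpy()
                block["eta0"] = null.eta0
                block["null_scale"] = null.null_scale
            frames.append(block)
    out = pd.concat(frames, ignore_index=True)
    cols = ["protein_id", "label", "time_min", "score_type", "mean", "t",
            "df_total", "n_replicates", "tested", "p", "lfdr", "q"]
    extra = [c for c in ("eta0", "null_scale") if c in out.columns]
    return out[cols + extra]


# ---------------------------------------------------------------------------
# classical tests
# ---------------------------------------------------------------------------

def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    Exact p-value when n*m <= 10,000, asymptotic otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if len(x) == 0 or len(y) == 0:
        raise InferenceError("empty sample")
    method = "exact" if len(x) * len(y) <= 10_000 else "asymp"
    res = stats.ks_2samp(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation, pairwise-complete."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise InferenceError("need >= 3 paired finite values")
    if np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
        raise InferenceError("zero variance")
    res = stats.pearsonr(x[ok], y[ok])
    return float(res.statistic), float(res.pvalue)
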