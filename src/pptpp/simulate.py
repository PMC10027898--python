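"""Synthetic ppTPP experiment generator.

Emulates the full pulsed-SILAC 2D thermal proteome profiling design:
two strains (a mitochondrial import "clogger" and a cytosolic control)
sampled at 0/30/90/270 min after induction, each protein split into a
pre-existing (light) and newly synthesized (heavy) SILAC pool, heated
over an 11-point temperature gradient in 3 replicates. Soluble signal
follows a 3-parameter logistic melting curve times exponential label
pool kinetics, with multiplicative log-normal noise, per-run (batch)
log2 offsets and deterministic detection-limit censoring.

Ground-truth parameters per protein are returned alongside the
quantification table so downstream stages can be tested for recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

#: Temperature gradient of the 2D-TPP protocol (degrees Celsius).
DEFAULT_TEMPERATURES: tuple[float, ...] = (
    37.0, 37.8, 40.4, 44.0, 46.9, 49.8, 52.9, 55.5, 58.6, 62.0, 66.3,
)

#: Sampling times after induction / SILAC medium switch (minutes).
DEFAULT_TIMES_MIN: tuple[int, ...] = (0, 30, 90, 270)

STRAINS = ("clogger", "control")
LABELS = ("light", "heavy")

#: TMT reporter channel names used when writing per-run protein tables
#: (8 channels: 2 strains x 4 timepoints share one temperature plex).
TMT_CHANNELS = ("126", "127N", "127C", "128N", "128C", "129N", "129C", "130N")


class ParameterError(ValueError):
    """Invalid model or configuration parameter."""


@dataclass(frozen=True)
class MeltingParams:
    """3-parameter logistic melting curve.

    tm : temperature (degC) of half-denaturation of the non-plateau fraction
    slope : steepness (1/degC), > 0
    plateau : residual soluble fraction at high temperature, in [0, 1)
    """

    tm: float
    slope: float
    plateau: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.tm, self.slope, self.plateau)
        if not all(math.isfinite(v) for v in vals):
            raise ParameterError(f"non-finite melting parameters: {vals}")
        if self.slope <= 0:
            raise ParameterError(f"slope must be > 0, got {self.slope}")
        if not (0.0 <= self.plateau < 1.0):
            raise ParameterError(f"plateau must be in [0, 1), got {self.plateau}")


@dataclass(frozen=True)
class KineticParams:
    """Exponential label-pool kinetics.

    ks : synthesis rate constant (1/min), >= 0
    kd : degradation rate constant (1/min), >= 0
    baseline : pre-shift protein signal (arbitrary intensity units), > 0
    """

    ks: float
    kd: float
    baseline: float

    def __post_init__(self) -> None:
        vals = (self.ks, self.kd, self.baseline)
        if not all(math.isfinite(v) for v in vals):
            raise ParameterError(f"non-finite kinetic parameters: {vals}")
        if self.ks < 0 or self.kd < 0:
            raise ParameterError("rates must be non-negative")
        if self.baseline <= 0:
            raise ParameterError("baseline must be > 0")


@dataclass(frozen=True)
class EffectProfile:
    """Clogger-vs-control ground-truth effect for one protein class.

    Abundance deltas are log2 shifts of the clogger pools relative to
    control; Tm deltas are melting-point shifts in degC; ks_ratio and
    kd_ratio multiply the clogger strain's rate constants.
    """

    group: str
    d_log2_abundance_post: float = 0.0
    d_log2_abundance_pre: float = 0.0
    d_tm_pre: float = 0.0
    d_tm_post: float = 0.0
    ks_ratio: float = 1.0
    kd_ratio: float = 1.0


#: Illustrative ground-truth classes mirroring the biology the assay probes:
#: blocked mitochondrial import depletes and destabilizes newly made
#: (heavy) mitochondrial proteins, proteasome induction raises abundance
#: and synthesis, ribosomes are thermally stabilized in both pools.
DEFAULT_EFFECTS: dict[str, EffectProfile] = {
    "null": EffectProfile("null"),
    "mito_import_blocked": EffectProfile(
        "mito_import_blocked",
        d_log2_abundance_post=-1.0,
        d_tm_post=-3.0,
        kd_ratio=1.5,
    ),
    "ups_induced": EffectProfile(
        "ups_induced",
        d_log2_abundance_post=0.8,
        d_log2_abundance_pre=0.3,
        ks_ratio=1.5,
    ),
    "ribosome_stabilized": EffectProfile(
        "ribosome_stabilized",
        d_tm_pre=2.0,
        d_tm_post=3.0,
    ),
}


@dataclass
class SimConfig:
    """Configuration of one simulated ppTPP experiment."""

    n_proteins: int = 100
    group_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "null": 0.70,
            "mito_import_blocked": 0.10,
            "ups_induced": 0.10,
            "ribosome_stabilized": 0.10,
        }
    )
    effects: dict[str, EffectProfile] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    times_min: tuple[int, ...] = DEFAULT_TIMES_MIN
    n_replicates: int = 3
    noise_cv: float = 0.1
    batch_sd: float = 0.2
    detection_limit: float = 100.0
    heavy_seed_fraction: float = 0.01
    synthesis_mode: str = "exponential"  # or "saturating"
    # parameter sampling ranges (uniform unless noted)
    tm_range: tuple[float, float] = (44.0, 56.0)
    slope_range: tuple[float, float] = (0.35, 0.75)
    plateau_range: tuple[float, float] = (0.0, 0.15)
    log10_baseline_mean: float = 5.3
    log10_baseline_sd: float = 0.45
    ks_range: tuple[float, float] = (0.002, 0.012)  # log-uniform
    kd_range: tuple[float, float] = (0.001, 0.010)  # log-uniform
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ParameterError("n_proteins must be >= 1")
        temps = np.asarray(self.temperatures, dtype=float)
        if temps.ndim != 1 or len(temps) < 2 or not np.all(np.diff(temps) > 0):
            raise ParameterError("temperatures must be strictly increasing")
        times = np.asarray(self.times_min, dtype=float)
        if times[0] != 0 or not np.all(np.diff(times) > 0):
            raise ParameterError("times_min must start at 0 and increase")
        total = sum(self.group_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(
                f"group_fractions must sum to 1, got {total}"
            )
        unknown = set(self.group_fractions) - set(self.effects)
        if unknown:
            raise ParameterError(f"groups without an EffectProfile: {unknown}")
        if self.synthesis_mode not in ("exponential", "saturating"):
            raise ParameterError(f"unknown synthesis_mode {self.synthesis_mode!r}")
        if self.noise_cv < 0 or self.batch_sd < 0 or self.detection_limit < 0:
            raise ParameterError("noise_cv, batch_sd, detection_limit must be >= 0")


def melting_fraction(temperature, params: MeltingParams):
    """Soluble (non-denatured) fraction at a given temperature.

    plateau + (1 - plateau) / (1 + exp(slope * (T - tm))); strictly
    decreasing in T, equal to plateau + (1 - plateau)/2 at T = tm.
    """
    t = np.asarray(temperature, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ParameterError("temperature must be finite")
    z = np.clip(params.slope * (t - params.tm), -700.0, 700.0)
    frac = params.plateau + (1.0 - params.plateau) / (1.0 + np.exp(z))
    return float(frac) if np.isscalar(temperature) else frac


def pool_intensities(
    t,
    params: KineticParams,
    heavy_seed_fraction: float = 0.01,
    mode: str = "exponential",
):
    """Noise-free light/heavy pool intensities at time t (minutes).

    Light decays as baseline * exp(-kd t). Heavy is exactly 0 at t = 0
    (all protein pre-existing at the label switch) and, for t > 0,
    grows as h0 * exp(ks t) with h0 = baseline * heavy_seed_fraction
    in the default exponential mode; the saturating mode uses
    baseline * (ks/kd) * (1 - exp(-kd t)) for realism checks.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ParameterError("time must be >= 0")
    light = params.baseline * np.exp(-params.kd * t_arr)
    if mode == "exponential":
        h0 = params.baseline * heavy_seed_fraction
        heavy = np.where(t_arr > 0, h0 * np.exp(params.ks * t_arr), 0.0)
    elif mode == "saturating":
        kd = max(params.kd, 1e-12)
        amplitude = params.baseline * params.ks / kd
        heavy = np.where(t_arr > 0, amplitude * (1.0 - np.exp(-kd * t_arr)), 0.0)
    else:
        raise ParameterError(f"unknown synthesis mode {mode!r}")
    if np.isscalar(t):
        return float(light), float(heavy)
    return light, heavy


def _sample_ground_truth(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_proteins
    groups = sorted(config.group_fractions)
    # deterministic group assignment by largest-remainder rounding
    counts = {}
    remainders = []
    assigned = 0
    for g in groups:
        exact = config.group_fractions[g] * n
        counts[g] = int(exact)
        assigned += counts[g]
        remainders.append((exact - int(exact), g))
    for _, g in sorted(remainders, reverse=True)[: n - assigned]:
        counts[g] += 1
    group_col = np.repeat(groups, [counts[g] for g in groups])
    rng.shuffle(group_col)

    tm = rng.uniform(*config.tm_range, size=n)
    slope = rng.uniform(*config.slope_range, size=n)
    plateau = rng.uniform(*config.plateau_range, size=n)
    baseline = 10.0 ** rng.normal(config.log10_baseline_mean, config.log10_baseline_sd, size=n)
    ks = np.exp(rng.uniform(np.log(config.ks_range[0]), np.log(config.ks_range[1]), size=n))
    kd = np.exp(rng.uniform(np.log(config.kd_range[0]), np.log(config.kd_range[1]), size=n))
    qupm = 2 + rng.poisson(6.0, size=n)

    eff = pd.DataFrame(
        [asdict(config.effects[g]) for g in group_col]
    ).drop(columns="group")
    gt = pd.DataFrame(
        {
            "protein_id": [f"P{i:05d}" for i in range(n)],
            "gene_name": [f"GENE{i:05d}" for i in range(n)],
            "group": group_col,
            "tm": tm,
            "slope": slope,
            "plateau": plateau,
            "baseline": baseline,
            "ks": ks,
            "kd": kd,
            "qupm": qupm,
        }
    )
    gt = pd.concat([gt, eff], axis=1)
    gt["tm_clogger_pre"] = gt["tm"] + gt["d_tm_pre"]
    gt["tm_clogger_post"] = gt["tm"] + gt["d_tm_post"]
    gt["ks_clogger"] = gt["ks"] * gt["ks_ratio"]
    gt["kd_clogger"] = gt["kd"] * gt["kd_ratio"]
    return gt


def simulate_experiment(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full ppTPP experiment.

    Returns
    -------
    quant : DataFrame
        Long-format quantification table with one row per
        (protein, strain, time, label, temperature, replicate);
        columns protein_id, gene_name, qupm, strain, time_min, label,
        temperature, replicate, batch, signal_sum. Signals below the
        detection limit (and the empty heavy pool at t = 0) are NaN.
    ground_truth : DataFrame
        One row per protein with all simulator parameters.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gt = _sample_ground_truth(config, rng)

    temps = np.asarray(config.temperatures, dtype=float)
    times = np.asarray(config.times_min, dtype=float)
    n_p = config.n_proteins
    n_t, n_temp, n_rep = len(times), len(temps), config.n_replicates

    # per-(temperature, replicate) MS-run batch offsets on log2 scale,
    # shared by both SILAC labels of a run
    batch_offsets = rng.normal(0.0, config.batch_sd, size=(n_temp, n_rep))

    sigma_log = math.sqrt(math.log(1.0 + config.noise_cv**2)) if config.noise_cv > 0 else 0.0

    frames = []
    base = gt["baseline"].to_numpy()
    for strain in STRAINS:
        is_clg = strain == "clogger"
        ks = (gt["ks_clogger"] if is_clg else gt["ks"]).to_numpy()
        kd = (gt["kd_clogger"] if is_clg else gt["kd"]).to_numpy()
        d_pre = gt["d_log2_abundance_pre"].to_numpy() if is_clg else 0.0
        d_post = gt["d_log2_abundance_post"].to_numpy() if is_clg else 0.0
        tm_pre = (gt["tm_clogger_pre"] if is_clg else gt["tm"]).to_numpy()
        tm_post = (gt["tm_clogger_post"] if is_clg else gt["tm"]).to_numpy()
        slope = gt["slope"].to_numpy()
        plateau = gt["plateau"].to_numpy()

        # pool kinetics: (protein, time)
        light = base[:, None] * np.exp(-kd[:, None] * times[None, :]) * 2.0 ** np.atleast_1d(d_pre)[:, None]
        if config.synthesis_mode == "exponential":
            h0 = base * config.heavy_seed_fraction
            heavy = h0[:, None] * np.exp(ks[:, None] * times[None, :])
        else:
            amplitude = base * ks / np.maximum(kd, 1e-12)
            heavy = amplitude[:, None] * (1.0 - np.exp(-np.maximum(kd, 1e-12)[:, None] * times[None, :]))
        heavy = np.where(times[None, :] > 0, heavy, 0.0) * 2.0 ** np.atleast_1d(d_post)[:, None]

        # melting: (protein, label, temperature)
        frac_pre = plateau[:, None] + (1 - plateau[:, None]) / (
            1 + np.exp(slope[:, None] * (temps[None, :] - tm_pre[:, None]))
        )
        frac_post = plateau[:, None] + (1 - plateau[:, None]) / (
            1 + np.exp(slope[:, None] * (temps[None, :] - tm_post[:, None]))
        )
        pools = np.stack([light, heavy], axis=1)          # (p, label, time)
        fracs = np.stack([frac_pre, frac_post], axis=1)   # (p, label, temp)
        clean = pools[:, :, :, None] * fracs[:, :, None, :]  # (p, label, time, temp)
        clean = np.broadcast_to(clean[..., None], clean.shape + (n_rep,)).copy()

        noise = (
            np.exp(rng.normal(0.0, sigma_log, size=clean.shape))
            if sigma_log > 0
            else 1.0
        )
        signal = clean * noise * 2.0 ** batch_offsets[None, None, None, :, :]
        signal[signal < config.detection_limit] = np.nan
        signal[clean == 0.0] = np.nan  # empty heavy pool at t = 0

        idx = pd.MultiIndex.from_product(
            [gt["protein_id"], LABELS, times.astype(int), temps, range(1, n_rep + 1)],
            names=["protein_id", "label", "time_min", "temperature", "replicate"],
        )
        df = pd.DataFrame({"signal_sum": signal.ravel()}, index=idx).reset_index()
        df["strain"] = strain
        frames.append(df)

    quant = pd.concat(frames, ignore_index=True)
    quant["batch"] = (
        "T" + quant["temperature"].map("{:g}".format) + "_r" + quant["replicate"].astype(str)
    )
    quant = quant.merge(gt[["protein_id", "gene_name", "qupm"]], on="protein_id")
    cols = [
        "protein_id", "gene_name", "qupm", "strain", "time_min", "label",
        "temperature", "replicate", "batch", "signal_sum",
    ]
    quant = quant[cols].sort_values(
        ["protein_id", "strain", "time_min", "label", "temperature", "replicate"],
        kind="mergesort",
    ).reset_index(drop=True)
    return quant, gt


def write_experiment(quant: pd.DataFrame, ground_truth: pd.DataFrame, out_dir) -> dict[str, Path]:
    """Write a simulated experiment to disk.

    Emits ``quant_long.tsv``, ``ground_truth.tsv``, ``metadata.tsv`` and
    one IsobarQuant-style ``protein_<run>.txt`` per (temperature,
    replicate, label) table, with 8 TMT channels covering
    strain x timepoint. Missing signals are written as 0 in the per-run
    files (reporter-ion non-detections) and "NA" in the long table.
    """
    from . import quant_io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["quant_long"] = out / "quant_long.tsv"
    quant_io.write_tidy(quant, paths["quant_long"])
    paths["ground_truth"] = out / "ground_truth.tsv"
    quant_io.write_tidy(ground_truth, paths["ground_truth"])

    strains = sorted(quant["strain"].unique())
    times = sorted(quant["time_min"].unique())
    conditions = [(s, t) for s in strains for t in times]
    if len(conditions) > len(TMT_CHANNELS):
        raise ParameterError("more strain x time conditions than TMT channels")
    meta_rows = []
    for (temp, rep, label), sub in quant.groupby(["temperature", "replicate", "label"]):
        run_id = f"T{temp:g}_r{rep}_{label}"
        wide = sub.pivot_table(
            index="protein_id",
            columns=["strain", "time_min"],
            values="signal_sum",
            aggfunc="first",
            dropna=False,
        )
        tbl = (
            sub[["protein_id", "gene_name", "qupm"]]
            .drop_duplicates()
            .sort_values("protein_id")
            .reset_index(drop=True)
        )
        for chan, (s, t) in zip(TMT_CHANNELS, conditions):
            if (s, t) in wide.columns:
                col = wide[(s, t)].reindex(tbl["protein_id"]).to_numpy(float)
            else:
                col = np.full(len(tbl), np.nan)
            tbl[f"signal_sum_{chan}"] = np.nan_to_num(col)
            meta_rows.append(
                {
                    "run_id": run_id,
                    "channel": chan,
                    "strain": s,
                    "time_min": t,
                    "label": label,
                    "temperature": temp,
                    "replicate": rep,
                    "batch": f"T{temp:g}_r{rep}",
                }
            )
        path = out / f"protein_{run_id}.txt"
        tbl.to_csv(path, sep="\t", index=False)
        paths[run_id] = path
    meta = pd.DataFrame(meta_rows).drop_duplicates()
    paths["metadata"] = out / "metadata.tsv"
    meta.to_csv(paths["metadata"], sep="\t", index=False)
    return paths
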