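# Methods

`pptpp` analyzes pre-post thermal proteome profiling (ppTPP) data: a
pulsed-SILAC experiment crossed with two-dimensional thermal proteome
profiling. A galactose-inducible "clogger" fusion stalls in the TOM
import channel and competitively blocks mitochondrial protein import;
a cytosolic DHFR strain is the control. At the moment of induction the
medium switches from light to heavy arginine/lysine, so protein made
before induction (light, "pre") and after induction (heavy, "post")
are mass-distinguishable. Samples taken 0, 30, 90 and 270 min after
induction are heated over an 11-point gradient (37, 37.8, 40.4, 44,
46.9, 49.8, 52.9, 55.5, 58.6, 62, 66.3 degC), and the soluble fraction
is quantified per protein by TMT reporter ions, three biological
replicates, one temperature per TMT plex.

The pipeline starts from protein-level `signal_sum` tables. Everything
below that level (peptide identification, search-engine merging) is
out of scope.

## Scores

For each protein, SILAC label, timepoint and replicate, let
`FC(T) = log2 I_clogger(T) - log2 I_control(T)` over the ordered
gradient, computed from normalized log2-like intensities.

- **Abundance score** `A = mean(FC(37), FC(37.8))` — at the two coolest
  temperatures essentially nothing is denatured, so the ratio reflects
  protein amount. If only one of the two entries is present, it is
  used alone; if both are missing the replicate is excluded from
  score-dependent outputs.
- **Stability score** `S = sum over the 9 remaining temperatures of
  (FC(T) - A)` — division by the abundance ratio in intensity space is
  subtraction in log space. Missing entries contribute 0 to the sum
  (the score stays a pure sum; no curvature is fabricated), and
  `n_temps_used` is reported so users can filter. Adding a constant to
  every FC shifts `A` by that constant and leaves `S` unchanged.

Replicate scores are averaged per (protein, label, time) for
reporting; the per-replicate values feed the significance test. Both
scores are z-scaled within each SILAC label (mean 0, sd 1); raw scores
are retained. An optional per-(label, time) scaling mode exists; the
label-only default matches the reference workflow's description.

## Identification filters

A (protein, label) entry enters the analysis only if all of the
following hold, evaluated in this order for removal attribution:
at least 2 unique peptides; observed in at least 2 of 3 replicate runs
at one of the two coolest temperatures; observed at 5 or more of the
11 temperatures; observed in 8 or more MS runs overall. Filtering is
bookkept per SILAC label because the light and heavy proteomes come
from separate database searches and are scored separately; a protein
may be retained in one pool only. Filtering is idempotent.

## Batch cleaning and normalization

Each (temperature, replicate) MS run is a batch. Per protein, log2
intensities are modelled additively on the declared condition factors
(strain, time, label, temperature by default; configurable) plus batch
contrasts that are first orthogonalized against the condition design.
Orthogonalization guarantees the removed component cannot absorb
condition effects even though batches are nested within temperature
(a per-temperature common offset is unidentifiable from a temperature
effect and is deliberately left to the temperature term). A single
batch is a no-op; a batch aliased with a condition factor is an error.
Clogger and control share each run, so residual per-run offsets cancel
in the fold changes regardless.

Normalization coefficients are estimated separately within each
(temperature, SILAC label) group, where one sample is a
(strain, time, replicate) channel:

- `vst` (default): per-sample scale factors from the median ratio to a
  geometric-mean reference profile, then a generalized log transform
  `glog2(x, c) = log2((x + sqrt(x^2 + c^2))/2)` with `c` set to the
  5% quantile of rescaled intensities — monotone everywhere and
  asymptotically log2 for large intensities. The estimation is robust
  and closed-form rather than an iterative per-sample maximum
  likelihood fit: it is deterministic, exact for samples that differ
  by a pure scale factor, and the downstream scores depend only on
  log-ratio differences, not on the precise stabilization
  coefficients.
- `median_log2`: equalize per-sample log2 medians (group grand median
  preserved) — a simple, audited fallback.
- `log2`: the plain transform with no coefficient estimation. Any
  per-sample equalization assumes most proteins are unchanged; when an
  effect is shared by essentially every protein in a simulation (as in
  the recovery checks below), equalization would absorb it, so those
  checks run on `log2`.

Missing intensities stay missing throughout; zero reporter-ion signals
are treated as non-detections on ingest. There is no imputation.

## Significance

Per-replicate scores are tested for mean different from zero within
each (label, time, score-type) stratum:

1. **Weighted moderated t.** Per protein, weights (the number of
   identified temperatures per replicate) are rescaled to mean 1 — so
   uniform weights reproduce the ordinary one-sample t — and a
   weighted mean and weighted residual variance are formed. Sample
   variances are shrunk toward a prior, `s2_post = (d0 s0^2 + d s2) /
   (d0 + d)`, with `(d0, s0^2)` estimated from the stratum's variance
   ensemble by moment matching on log variances (digamma/trigamma
   moments, trigamma inverted by Newton iteration). The statistic is
   `t = wmean / sqrt(s2_post / sum(w))` with `df = d + d0`. The
   moment matching is cross-checked against an independent reference
   implementation in the test suite.
2. **Empirical null.** A central half-normal is fitted to the
   stratum's |t| ensemble by truncated maximum likelihood. The
   truncation point is chosen adaptively: starting from a robust
   (median-based) scale estimate, the cutoff is placed at the 90% mass
   point of the current null fit and the fit repeated, so values
   dominated by the alternative stay out of the null estimate. The
   null proportion is `eta0 = (fraction below cutoff) / (null mass
   below cutoff)`, capped at 1.
3. **p / lfdr / q.** Two-sided p-values come from the fitted null
   scale. The local fdr is `eta0 * f0(|t|) / f(|t|)` with the mixture
   density estimated by a Grenander (monotone-decreasing) estimator on
   |t|; the tail-area q-value is `eta0 * P0(|T| >= t) / ECDF_tail(t)`.
   Both are clipped to [0, 1] and enforced non-increasing in |t|.

Calibration: on all-null simulations the p-value distribution is close
to uniform (KS distance ~0.02-0.03 at ~7,000 tests) with a fraction
below 0.05 of about 0.06. The slight anti-conservatism is intrinsic to
fitting a single central null to a mildly heteroscedastic t-ensemble —
proteins differ in how many temperatures enter the stability sum — and
is shared by the reference extraction pathway this reproduces. The
classical helpers (two-sample Kolmogorov-Smirnov, exact for
n*m <= 10,000; Pearson correlation, pairwise-complete) delegate to
scipy.

## Turnover rates

Kinetics are read at 37 degC only (no thermal denaturation) from
batch-corrected intensities on the natural scale — the glog transform
would distort exponential slopes. Assuming exponential kinetics, KS is
the OLS slope of ln(heavy) on time over 30/90/270 min and KD is minus
the slope of ln(light) over 0/30/90/270 min, pooling replicates as
points; r2 and the number of usable points are reported. Non-positive
intensities are excluded; fewer than two points flags the fit
untested; a negative fitted KD (increasing light pool) is reported
as-is, never clipped. `dKS`/`dKD` are clogger/control slope ratios,
reported only when the control rate is nonzero and both fits used at
least 3 points — ratio instability near zero is the user's signal to
exclude, not something to cap.

## Classification

- **Abundance classes**: dK at or beyond the top/bottom 20% empirical
  quantile is "up"/"down" (ties inclusive; linear-interpolation
  quantiles; the all-equal degenerate case resolves to unchanged;
  q = 0 means no calls).
- **Stability classes**: score strictly above +0.5 is stabilized,
  strictly below -0.5 destabilized (exactly +/-0.5 is unchanged).
- **Stabilization tiers**: highly stabilized if light > 2.9 and
  heavy > 0.5; stabilized if both pools > 0.5; else none; undefined if
  a pool score is missing.
- **Outliers**: Tukey fences Q1 - 1.5 IQR / Q3 + 1.5 IQR per
  (timepoint, pool), quartiles by linear interpolation, reported per
  condition and as a deduplicated union with provenance. A zero IQR is
  degenerate (no measurable spread): no outliers are called.
- **Annotation summaries**: per group and condition, member count,
  median and IQR of both scores, and a KS test of the group's
  stability scores against the complement.

## Synthetic experiments

The generator emulates the full design with known ground truth so
every stage is testable without the deposited raw data. Per protein:
a 3-parameter logistic melting curve
`f(T) = plateau + (1 - plateau) / (1 + exp(slope (T - tm)))`
(the analysis itself is curve-free; this is the standard minimal TPP
form), exponential pool kinetics (light `baseline * exp(-kd t)`; heavy
exactly 0 at t = 0 and `(baseline/100) * exp(ks t)` after — pure
exponential so the rate fits are well-posed; a saturating mode
`A (1 - exp(-kd t))` exists to quantify misspecification), and an
effect class giving the clogger strain log2 abundance shifts and Tm
shifts per pool plus rate multipliers. Signals are
`pool * melting fraction * lognormal noise * 2^(batch offset)`, with
one N(0, batch_sd) log2 offset per (temperature, replicate) run shared
by both labels, and deterministic censoring below the detection limit
(missingness is MNAR and monotone in temperature for noise-free data,
reflecting loss of soluble signal, not random dropout).

Defaults: Tm uniform on 44-56 degC, slope 0.35-0.75 per degC, plateau
0-0.15, baselines log-normal around 2x10^5, ks and kd log-uniform on
0.002-0.012 and 0.001-0.010 per min (half-lives roughly 1-12 h),
noise_cv 0.1, batch_sd 0.2 log2 units, detection limit 100. The noise
magnitudes are working values chosen to produce realistic-looking
tables, validated only by the generator's own tests — not estimates of
any instrument run. Determinism: identical configuration and seed give
byte-identical outputs.

What the generator does not emulate — and hence what passing recovery
tests do not show about real data: peptide-level effects (co-isolation,
ratio compression), correlated noise across channels, growth dilution,
precursor-pool recycling, saturation of TMT reporters, or proteins
whose melting is non-sigmoidal.

## Problem sizes in the standard checks

The recovery and calibration checks run at 200-1,000 simulated
proteins with the full 2 x 2 x 4 x 11 x 3 design grid — large enough
that Monte-Carlo error is small against every stated bound (e.g. the
median relative error of a fitted kd = 0.001/min is ~6% against a 10%
bound with 600 fits) while the whole suite stays fast. Sizes are fixed
in the tests and in `scripts/acceptance.py`.

## Known limitations

- The per-temperature mean of batch offsets is unidentifiable and
  deliberately not removed (harmless for ratios and slopes, visible in
  absolute intensities).
- Rate ratios for proteins with near-zero control rates are missing by
  design.
- The empirical-null family is the half-normal on t; with the
  moderated degrees of freedom typically estimated as effectively
  infinite, a Student-t family would coincide with it, so no second
  family is implemented.
- z-scaling is per label only by default; per-(label, time) scaling is
  available but changes cross-time comparability.
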