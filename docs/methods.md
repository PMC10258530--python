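# Methods

This note documents the models, defaults and numerical choices behind
`dyadsync`, and what the synthetic test bed does and does not establish
about real recordings.

## Behavioral synchrony

Velocities are first differences of 3D hand position scaled by the sampling
rate (units/s), smoothed per axis with a Gaussian kernel of 100 ms full
width (σ = 25 ms, truncated at ±2σ, edge-renormalized so constants pass
unchanged).

The synchrony statistic is the cosine of the angle between the two
participants' velocity vectors (CVV). When either speed falls below
ε = 1e−9 units/s the cosine is defined as 0: a still hand has no direction,
so stillness contributes no alignment evidence rather than inflating
synchrony.

**Windowing order.** The lag-resolved map applies, per lag: signed CVV per
sample → centered 2 s (100-sample) moving average → absolute value. The
order matters. The instantaneous |cos| of two independent, isotropically
distributed 3D directions has mean 0.5, so averaging |CVV| first would put
*every* window above the 0.35 detection threshold and make the statistic
useless as a filter against chance alignment. Averaging the signed cosine
first lets unaligned movement cancel toward 0 while sustained same-direction
(≈ +1) or mirror (≈ −1) episodes survive; the final absolute value treats
both polarities as synchrony. A window mixing both polarities in equal
measure would cancel, but sustained episodes do not mix polarities on the
2 s scale. Windowed values are reported only for time points where the
window and every lag shift are fully inside the data (valid mode; no
partially-windowed estimates).

**Lag grid.** ±750 ms in 10 ms steps. At 50 Hz a 10 ms step is half a
sample; the lagged partner's velocity is linearly interpolated onto the
shifted time grid. Positive lag means participant j trails participant i
(j at t+τ is compared with i at t); the convention is stated in output
headers.

**Summaries.** lag0_sync is the fraction of time points with the mask true
at lag 0; lagged_sync uses any lag with |lag| > 30 ms; total_sync combines
the two regimes with a per-time-point OR. Both total_sync (a time
proportion) and the Fisher z of the time-lag mean |CVV| are emitted, since
either reading of "how much synchrony" can be wanted downstream. Fisher z
is arctanh with inputs clipped at 1 − 1e−12 so perfect synthetic copies stay
finite.

**Nulls and exclusion.** Pseudo dyads re-pair participants across dyads via
a seeded derangement (no pseudo pair shares a real dyad, condition-matched,
one pseudo dyad per real dyad). Outlier exclusion removes condition-level
summary values beyond mean ± 2.5 SD, computed once on the full set (single
pass, no re-trimming), and reports the removed fraction.

## Synthetic movement

Each participant's velocity is a stationary 3D Ornstein–Uhlenbeck process
(exact discretization), integrated to positions. OU velocities give smooth,
non-repetitive, unpredictable trajectories; rhythmic sinusoids would
trivially inflate CVV. Coupling is applied in velocity space — the
statistic is a velocity statistic — as
v_B(t) = κ · v_A(t − lag) + (1 − κ) · v_indep(t).

Defaults: fs 50 Hz, 120 s blocks, OU time constant τ = 0.25 s (free hand
movement changes direction on a sub-second scale), stationary speed SD
1 unit/s. Under these conditions the chance-level total_sync baseline is
roughly 0.45; κ = 1 drives it to 1.0. The generator does not model arm
biomechanics, intermittent stillness, or deliberate rhythm, so absolute
baseline levels in real data (where rest periods pull CVV toward 0) will
differ; the tests establish ordering and recovery properties, not absolute
rates in humans.

## fNIRS preprocessing

Optical density is −log10(I / mean I) per channel × wavelength, invariant
to detector gain. Continuous-wave NIRS only defines concentration *changes*;
recovered series are therefore meaningful up to each channel's temporal
mean, and round-trip checks compare mean-centered series.

**Wavelet motion correction.** Daubechies-5 DWT, 4 levels. Detail
coefficients whose magnitude exceeds 1.5 × the interquartile range of their
level are zeroed; smooth hemodynamics keep coefficients inside the bulk
while spike/shift transients produce extreme ones. Coefficients within one
filter length of each boundary are exempt: under symmetric extension they
reflect the edge, not motion, and zeroing them distorts the block edges.
On the synthetic fixtures a 10× spike is suppressed by ~95% with ~2% RMS
carrier distortion, and a second pass changes a corrected signal by < 1%.

**Beer–Lambert.** Per channel the 2×2 system ΔOD(λ) = ε(λ,·)·c · d · DPF(λ)
is solved for c = (ΔHbO, ΔHHb); with ε in 1/(mM·cm) from the standard
hemoglobin tabulation (pinned in `constants.py`), d the 3.5 cm nominal
separation, and DPF = 6.0 at both wavelengths (a typical adult-head value;
no study-specific DPF is assumed), outputs are in µM. The simulator inverts
exactly this operator, guaranteeing recoverability.

**Channel QC.** Manual inspection is replaced by automation: a channel
passes if its Welch spectrum (nperseg = 256) shows a peak in 0.8–2.0 Hz
with prominence above 3× the in-band median power — at 10 Hz sampling the
cardiac band is well below Nyquist. An optional variance threshold flags
noisy channels; it is off by default. Excluded channels are dropped from
all coupling computations, never interpolated. Epoch-level exclusion is not
performed.

**PCA scalp filtering.** O2Hb channels are decomposed by SVD; each
component's channel-loading vector is smoothed with a row-normalized
Gaussian kernel over channel-midpoint distances (σ = 3.5 cm, one optode
spacing); the smoothed (spatially global) loadings are subtracted and the
signal rebuilt from the residual loadings with unchanged temporal scores.
Because the kernel preserves constants, a spatially uniform component is
removed exactly, while high-spatial-frequency focal patterns pass nearly
untouched. σ = 0 is defined as the identity filter (no spatial pooling, no
global estimate — a degenerate no-op rather than the kernel→delta limit,
which would annihilate the signal). Only O2Hb is filtered and carried to
coherence; HHb passes through for QC. With every component retained the
operation is linear in the data; the PCA route is kept for fidelity to the
published procedure and for future component truncation.

## Synthetic fNIRS

Per channel: √ρ · shared + √(1−ρ) · independent band-limited (0.015–0.15 Hz)
unit-SD Gaussian processes (frequency-domain synthesis, seeded phases),
plus cardiac (1.2 Hz, 0.3 µM), respiration (0.25 Hz, 0.15 µM) and Mayer
(0.1 Hz, 0.15 µM) sinusoids with per-participant random phases, an optional
participant-global scalp process, and exponential spike artifacts
(0.2 s time constant) at a configurable rate. HHb is generated as −0.3 ×
HbO plus small independent noise (typical anticorrelated hemodynamics);
concentrations are inverted through the Beer–Lambert operator to
two-wavelength intensities. The generator does not model neurovascular
coupling dynamics, optode-skin mechanics, or heart-rate variability;
passing tests show the pipeline recovers what the generator planted, not
that real scalp physiology is this simple.

## Wavelet coherence

Analytic Morlet CWT (ω₀ = 6), FFT implementation with power-of-two zero
padding, scale grid of 12 voices per octave covering 0.01–0.5 Hz so the
analysis band is interior. The scale-frequency map is pinned as
f = ω₀/(2πs). Squared coherence uses the standard estimator

R²(t,s) = |S(W_xy/s)|² / (S(|W_x|²/s) · S(|W_y|²/s)),

with S a Gaussian time-smoother (σ = s, edge-renormalized, FFT
implementation) followed by a 0.6-octave boxcar along scale. Without S,
R² ≡ 1 for any pair — a regression test keeps this degeneracy visible.
Cells beyond the e-folding boundary (√2·s from the nearer edge) are outside
the cone of influence and never enter band averages; with 120 s blocks this
raises the effective band floor to ~0.023 Hz, which is reported per record
rather than silently averaging edge-biased cells at 0.015 Hz (67 s period).

Band averages are unweighted means of R² over COI-valid in-band cells. The
Fisher z convention is arctanh(√R̄²): coherence is a squared quantity, so
its square root is the correlation-scale value the transform expects; both
raw R̄² and z are emitted and the stats stage consumes z.

ROI aggregation: coherence is computed once per channel pair on the full
recording and cells are assigned to condition blocks by time (per-block
recomputation would lose the block edges to the COI; it remains available
by slicing first). Channel-pair z values are averaged in z space per ROI
pair — all cross-ROI channel pairs by default, homologous-only via flag.
Between-brain records span the two participants; within-brain records pair
distinct ROIs of one participant, never a channel with itself. Pseudo
coupling reuses the behavioral derangement on the fNIRS series.

## Mixed models

The ladder fits main effects → +2-way → +3-way interaction models with a
random intercept per dyad (or participant for within-brain analyses). Each
depth is fitted twice: by ML for likelihood-ratio comparison (REML
likelihoods are not comparable across fixed-effect structures) and by REML
for estimation and Wald inference (ML covariance underestimates SEs; the
REML refit keeps the per-cell slope type-I rate at the nominal 5% in the
null simulations). The likelihood-ratio χ², with df equal to the
fixed-parameter difference, stands in for a Type II Wald χ²; the two agree
asymptotically and the choice is recorded in the report metadata, as is the
normal approximation used for fixed-effect p-values. A partial-η²-style
effect size is derived from the deepest comparison's χ² and residual df;
it is reported, never used for selection.

Simple slopes per condition × ROI cell are linear contrasts (moderator 1
vs 0) of the deepest model's REML fit — a cell-specific slope is only
identifiable with the 3-way interaction present, even when selection
favours a shallower model; `model="selected"` overrides. Cells with fewer
than 3 observations are errors. Real-vs-pseudo contrasts come from a single
full-factorial (condition × ROI × group) mixed model with Bonferroni
adjustment over cells. Duplicate rows, single-level factors and unbalanced
cells are flagged in the report warnings; singular fits are reported, not
dropped.

## Problem sizes in tests

Monte-Carlo suites use fixed seeds and sizes chosen for a fast, convergent
suite: null-calibration at 24 dyad simulations of 60 s blocks, coherence
ρ-recovery at 8–10 seeds per level, model-selection and type-I suites at
15–50 replicates of 15–30 dyads. The oracle-equivalence check compares the
vectorized sync map against a literal triple-loop reference at 1e−10 on 5 s
fixtures.

## Known limitations

- The channel→ROI table is configuration, not anatomy: the bundled
  23-channel layout is an illustrative three-cluster geometry, not a
  reconstruction of any headcap.
- No short-separation regression (the modeled hardware has none); the PCA
  scalp filter is the only systemic-physiology control.
- The BB (back-to-back) baseline shares room acoustics and task set in real
  experiments; the generator exposes a baseline ρ for BB but no empirical
  value is assumed (default 0).
- Sub-sample lags rely on linear interpolation of 50 Hz velocities;
  band-limited interpolation would differ at the few-percent level near
  Nyquist.
- Fixed-effect p-values use the normal approximation (no Satterthwaite df);
  with ≤ 10 dyads they are anti-conservative and the report says so.
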