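# Methods

## The measurement problem

Dynamic muscular endurance is operationalized as the retention of peak power
output over repeated isotonic contractions: the subject works against a
constant load (50 % of isometric peak torque, IPT) through a fixed range of
motion at a paced cadence until voluntary exhaustion. Per repetition, the
peak of *P(t) = τ(t)·ω(t)* (ω in rad/s) inside the concentric phase is the
mechanical fatigue observable. The electrophysiological observables are nine
sEMG parameters computed per concentric contraction; the scientific question
the pipeline addresses is how well their percent-normalized trajectories map
the percent loss of peak power, linearly and non-linearly.

## Trial simulation (`iso_sim`)

No public recordings of this protocol exist, so every downstream stage is
validated against a generator with known ground truth.

**Kinematics.** The joint angle of one cycle is a raised cosine between the
range-of-motion endpoints over *T* = 60/pace s; angular velocity is its
analytic derivative (one positive concentric lobe, one negative eccentric
lobe), so the velocity integral over the concentric lobe equals the ROM span
exactly. Torque is constant over the cycle (isotonic load) at the level that
realizes the repetition's scheduled peak power at the velocity peak; for the
first repetition this equals the 50 %-IPT resistance. Default group
constants (ROM, mean IPT, typical repetition count): plantar flexors
80–130°, 154.90 N·m, 52 reps; knee extensors 80–170°, 166.45 N·m, 31 reps;
hip extensors 90–180°, 198.56 N·m, 48 reps.

**Power decay.** The scheduled peak power falls from
`baseline_peak_power_W` by a total fraction `decay_frac` (linear by default,
exponential optional). The group defaults (0.409 / 0.423 / 0.426) are
calibrated analytically so that a linear decay over the group's typical
repetition count reproduces the observed end-of-trial retention,
mean(last 5)/mean(first 5) ≈ 0.60–0.62. Trials run the full schedule — the
endpoint is psychophysiological (voluntary exhaustion) — while the
dynamometer's 75 %-of-first-5-s indicator (two consecutive sub-threshold
cycles) is evaluated on per-cycle mean power and recorded in the ground
truth. The two notions are deliberately distinct: observed end-of-trial
retention is well below 75 %, which is only possible if subjects continue
past the indicator.

**Latent fatigue states.** Each trial draws two per-repetition latent
trajectories around the common ramp *u* ∈ [0, 1]: a *spectral* state shared
by peak power and the EMG centroid (power loss is coupled to spectral
compression) and an independent *recruitment* state driving EMG amplitude.
This makes the frequency features informative about power beyond the common
trend while amplitude features track it only through the trend — the
qualitative pattern seen in fatiguing dynamic contractions, where amplitude
measures correlate with power much more weakly than spectral ones.

**sEMG synthesis.** Within each concentric segment the channel is Gaussian
noise shaped by a 4th-order Butterworth band-pass whose edges scale
proportionally with the repetition's target centroid; the design is
calibrated (one corrective redesign against the measured |H|² centroid,
restricted to the 20–250 Hz analysis band) so the imposed centroid is what
the downstream periodogram MNF reads, within a few percent. The default
centroid trajectory is 110 → 80 Hz; RMS grows by 25 % (defaults). Bursts
carry a Tukey (α = 0.5) envelope — contraction bursts are non-stationary —
and the segment RMS is scaled exactly to the scheduled value. Two
contamination processes, both standard features of dynamic sEMG, complete
the model: per-repetition lognormal amplitude instability (CV 10 %;
electrode contact and crosstalk variability) and motion-artifact transients
(Poisson rate 1.5 per contraction, ~30 ms broadband bursts at 5× the
contraction RMS). Rest intervals carry broadband baseline noise at 5 % of
the first-repetition RMS so segmentation is exercised against a non-silent
floor. All three contamination processes are configurable and can be
disabled; the shaping-fidelity tests do so.

**What the generator does not model:** motor-unit recruitment, conduction
velocity, or any biophysical EMG model (the spectra are phenomenological);
eccentric-phase EMG; powerline interference; inter-muscle crosstalk
structure. Passing tests therefore demonstrate that the pipeline recovers
imposed fatigue structure of this phenomenological kind — not that it would
achieve the same accuracy on physiological recordings.

## Preprocessing (`preprocess`)

The 20–250 Hz analysis band is realized as a 5th-order Butterworth high-pass
cascaded with a 10th-order low-pass, applied with `sosfiltfilt`
(zero-phase; effective attenuation order doubles — documented contract).
The record is always filtered full-length before segmentation; filtering per
segment would bias boundary samples. The hardware 750 Hz anti-alias filter
is assumed applied by the acquisition system and is not reapplied.
Mechanical traces are smoothed by adjacent averaging (centered moving mean,
shrinking windows at the edges; default 11 samples ≈ 7.3 ms at 1.5 kHz — the
protocol's source does not state a window). Concentric phases are contiguous
runs of smoothed velocity above a floor (default 5 % of the 95th-percentile
velocity) lasting ≥ 0.2 s; indices are 0-based, half-open. Per-repetition
peak power is the maximum of τ·ω·π/180 inside each segment.

## Features (`features`)

- **MAV, RMS**: mean |x| and √mean x² per segment; MAV ≤ RMS always.
- **MNF, MDF**: single rectangular-window periodogram of the whole segment
  (segments are ~0.5 s; no averaging is possible without losing resolution),
  restricted to 20–250 Hz; MDF linearly interpolated between the bins
  straddling half the cumulative power.
- **Wavelet denoising**: six-level db1 (Haar) decomposition; the finest
  detail D1 and the approximation A6 are zeroed, retaining D2–D6, i.e.
  11.71875–375 Hz at 1.5 kHz. Retaining A6 instead is available via
  `keep_approximation`. The Haar bank is only 2-tap, so attenuation below
  the nominal edge is gradual (a 5 Hz tone keeps ~37 % RMS; < 15 % is
  reached near 1.5 Hz) — a property of the chosen mother wavelet, verified
  by the tests.
- **IMNF, IMDF**: instantaneous frequency as the central-difference
  derivative of the unwrapped analytic-signal phase (Hilbert transform) of
  the denoised record, clipped to [0, Nyquist]; aggregated per segment as
  the squared-envelope-weighted mean (IMNF) and weighted median (IMDF).
  The weighting is a design decision (no aggregation is prescribed by the
  protocol's source); it reduces to the plain mean/median for constant
  envelope, suppresses the spurious frequency spikes where the envelope
  vanishes, and is what gives IMNF/IMDF — especially the median — their
  robustness to artifact transients.
- **ZC, SSC, WL**: zero crossings and slope-sign changes with an amplitude
  deadband `eps` (default 0; real recordings typically need ~10 µV), and
  waveform length Σ|Δx|.
- **Percent normalization**: 100 × value / mean(first two repetitions), per
  feature and for peak power; scale-invariant by construction.

## Mapping (`mapping`)

**Linear.** Univariate OLS per percent feature (reported r is the signed
feature–power correlation). Stepwise multiple linear regression over
{RMS%, MAV%, MNF%, MDF%, IMNF%, IMDF%}: forward entry of the smallest
partial-t p-value below `p_enter` = 0.05, backward removal above
`p_remove` = 0.10, exact-collinear candidates excluded by a rank check.
Note the procedure's honest null behavior: with six candidates it admits a
spurious predictor in ≈ 1 − 0.95⁶ ≈ 26 % of pure-noise datasets — a property
of any p-based stepwise selection, asserted as such in the tests.

**Non-linear.** A single-hidden-layer perceptron, inputs → 10 tanh units →
1 linear output, trained on z-scored inputs/targets (statistics from the
training folds only) by Levenberg–Marquardt: solve (JᵀJ + λI)δ = −Jᵀr with
the exact analytic Jacobian; λ₀ = 10⁻³, ×10 on a rejected step, ÷10 on an
accepted one, so training MSE is non-increasing. Stopping: 100 epochs, a
training-MSE goal of 4 × 10⁻⁵ (z-scored units), 18 consecutive
validation-MSE increases (the returned weights are the best-validation
ones), or trust-region collapse (λ > 10¹⁰). Weights initialize uniform
[−0.5, 0.5] from the model seed. A plain gradient-descent fallback
(learning rate 0.1) exists behind `use_lm=False`; LM itself has no learning
rate. Evaluation is by five-fold rotation over contiguous blocks (the data
are serial fatigue trajectories; a shuffled mode exists behind a flag), the
held-out block doubling as the early-stopping validation segment, with the
pooled out-of-fold estimates scored against the actual series. The linear
map is fitted and scored on the full data, as is conventional for
regression summaries; this asymmetry slightly favors the linear map, so a
perceptron advantage is conservative.

**Scoring.** SNR = 10·log₁₀(Σ(aᵢ−ā)²/Σ(aᵢ−eᵢ)²) dB, capped at 100 dB for
numerically zero residuals; exactly 0 dB for the constant-mean predictor.
No formula is prescribed by the protocol's source, so SNR values here are
comparable in spirit, not numerically, to other implementations. The
slope/intercept equality of the two actual-versus-estimated lines is tested
with nested extra-sum-of-squares F-tests (`stats.compare_regression_lines`).

**Feature-level cohorts.** `simulate_feature_cohort` generates
percent-feature/power tables with a *known* map for validating the mapping
stage at scale (40 subjects × 25 repetitions by default): the linear
coupling is affine in IMDF% and RMS%; the non-linear coupling adds a
quadratic in IMDF% and an IMDF%×RMS% interaction — emulating the
accelerating power loss near exhaustion — with Gaussian noise (SD 5 percent
points). On the non-linear cohorts the cross-validated perceptron
out-scores stepwise regression in essentially every seed (median gap
≈ +1.7 dB); on the linear control the median gap is ≈ −0.2 dB, i.e. no
spurious advantage.

## Statistics (`stats`)

Repeated-measures one-way ANOVA (statsmodels `AnovaRM`; an independent
one-way option behind `repeated=False`) with Bonferroni-corrected paired-t
post-hocs over the three condition pairs, flagged at 0.05 and 0.01; paired
t and Pearson r from scipy with two-tailed p; CV = 100·SD/mean with the
< 10 % screening convention; regression-line comparison as above. Type-I
calibration of paired t, the ANOVA, and the slope F-test is verified by
1000-run null Monte-Carlo (all within [0.03, 0.07] at nominal 0.05).

## Problem sizes and determinism

Default verification sizes — chosen to make the checks statistically
meaningful at desk scale — are: 10–20 simulated trials (~50 repetitions
each) for pipeline-level checks, 25 seeds × 40 subjects × 25 repetitions
for the mapping comparison, 1000 replicates for null calibrations, 50
sequences for the termination oracle. Every stochastic component draws from
`numpy.random.default_rng` seeded explicitly; per-subject streams derive
from (master seed, subject id) via `SeedSequence`, so cohorts are
reproducible and parallel-safe, and reruns of the pipeline are
bit-identical.

## Known limitations

- Phenomenological EMG: spectral compression is imposed, not derived from
  conduction-velocity physiology; absolute SNR/r values on synthetic data
  should not be read as predictions for human recordings.
- Absolute power magnitudes follow from the paced raised-cosine kinematics
  (~212 W first-rep peak for plantar flexors); ballistic human contractions
  reach higher velocities and powers. Retention ratios, not watts, are the
  comparable quantity.
- The stepwise/MLP comparison pools repetitions across subjects per muscle
  (subject-tagged rows); a strictly within-subject split is available via
  the folds interface but is not the default.
- MDF/IMDF interpolation assumes locally smooth cumulative distributions;
  extremely short segments (< 0.2 s) are rejected rather than estimated.
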