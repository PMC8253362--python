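# Methods

`tmsnet` infers time-varying directed networks from multichannel EEG recorded
around single transcranial magnetic stimulation (TMS) pulses, and carries the
accompanying event-related-potential (ERP) and behavioral analyses of a
dual-feature delayed matching experiment. This note documents the models, the
estimation choices that were genuinely open, the synthetic data the package is
validated on, and what that validation does and does not establish.

## Time-varying MVAR model

The EEG vector X(t) over M channels is modeled as a time-varying
vector-autoregression of order p,

    X(t) = Σ_{i=1..p} A(i,t) X(t−i) + E(t),

with E(t) multivariate white noise. The order is chosen on a *stationary*
pooled least-squares fit by the Akaike information criterion

    AIC(p) = ln det(χ) + 2 M² p / N,

scanned over p ∈ [2, 20] (χ = innovation covariance, N = pooled regression
rows); ties break toward the smaller order. The penalty term makes white
noise select the lower bound, and simulation shows the true order of a stable
VAR(3) is recovered in ≥ 18/20 seeds at 4,000 samples.

### Kalman estimation

The coefficient trajectory is estimated recursively. Because every target
channel regresses on the same lagged-regressor vector φ(t) ∈ R^{Mp}, the
state is the Mp × M coefficient matrix with one shared Mp × Mp covariance P —
the standard adaptive-MVAR formulation, which ignores cross-channel
innovation correlation in the gain but is exact for scalar measurement noise.
Design choices (the source method names the Kalman filter but no
hyperparameters):

- **Random-walk transition** with fixed process noise Q = uc·I per step.
  The *update constant* uc ∈ (0,1) is the single smoothness/adaptivity dial:
  larger uc tracks coefficient changes faster at the price of noisier
  trajectories. The trace-scaled alternative Q = uc·tr(P)/dim·I was rejected
  because it self-quenches (Q shrinks as P converges), making adaptation
  speed nearly independent of uc. Default uc = 10⁻³; with a 50-trial
  ensemble at 32 Hz this locates a planted coupling step within ±5 samples
  in ≳ 85% of runs, and tracking lag is monotone decreasing in uc.
- **Shrinkage initialization** P₀ = 0.01·I (prior coefficient std 0.1), zero
  initial state. A diffuse P₀ = I makes the first informative update jump to
  whatever fits that single time step (coefficient excursions ~0.5 on pure
  noise), which the p-sample warm-up flag does not cover; the shrinkage prior
  suppresses this transient without affecting steady-state behavior.
- **Fixed scalar measurement noise** r = mean per-channel variance of the
  input. Only the ratio of P to r matters for the gain, so this sets the
  scale without a second tuning constant.
- **Ensemble updating** (default): all trials enter each time step as
  simultaneous observations (stacked rows of the observation matrix).
  Single-trial trajectories at 48 samples/epoch are hopelessly noisy;
  per-trial mode exists for diagnostics and averages independent fits.
- The first p time points are warm-up and excluded from all downstream
  statistics.

On stationary data the time-averaged trajectory agrees with the pooled
least-squares fit to RMSE < 0.03 (bound asserted: 0.1) over 20 seeds.

## Adaptive directed transfer function

The fit is moved to the frequency domain as A(f,t) = Σ_{k=0..p} A_k(t)
e^{−j2πfk/fs} with A₀ = +I and A_k = −(lag-k coefficients) — the only sign
assignment consistent with the time-domain regression — and H(f,t) =
A(f,t)⁻¹. The normalized ADTF

    γ²_ij(f,t) = |H_ij(f,t)|² / Σ_m |H_im(f,t)|²

is the share of inflow into node i arriving from node j; rows sum to 1 by
construction (asserted to 10⁻⁸ on every run). Band integration over the
0.5–14.5 Hz band of interest is implemented as the **mean over in-band grid
points**, keeping Q²_ij(t) ∈ [0,1]; the printed sum/(f₂−f₁) convention is not
bin-count normalized and can exceed 1, so it is available only behind
`convention="printed"`. The frequency grid defaults to 0.5–14.5 Hz in 0.5 Hz
steps (spacing is an implementation choice, not a reconstruction). Node
outflow is Q²_j(t) = Σ_{k≠j} Q²_kj(t)/(n−1). Singular A(f,t) cells become
flagged missing values rather than pseudo-inverses, so silent distortion is
impossible. The whole chain is verified against an independent
straight-from-the-equations implementation to 10⁻⁸.

## Preprocessing

Epochs are half-open sample windows, 0-based, t = 0 at the alignment event.
The network branch uses (−0.5, +1.0) s around the pulse (1.5 s segments); the
ERP branch uses (−1.0, +1.0) s with baseline [−0.9, −0.7] s — the 200 ms
before the first visual stimulus, whose onset precedes the pulse by 0.7 s
(this mapping is inferred from the trial geometry and encoded in config).

The pulse window (60 ms post-pulse by default) is excised and bridged by
per-channel linear interpolation, with the bad samples flagged in a mask.
The two consumers intentionally differ: ERP averaging *excludes* masked
samples; the network stage, which needs contiguous series, uses the
interpolated values. Whether the original analysis interpolated or
zero-padded is unstated; interpolation is our documented choice.

Decimation to the 32 Hz network rate derives its factor from the rates (the
stated ×8 is inconsistent with 1,024 Hz acquisition; the target rate is
authoritative). Anti-aliasing is a zero-phase Kaiser FIR cascade (stages of
≤ 4×) with the final cutoff at 0.4 × target rate and ≥ 50 dB stopband from
0.5 × target; odd-symmetric `filtfilt` padding preserves constants and
linear trends at epoch edges. Tones above half the target rate are attenuated
by ≥ 40 dB.

The two-round ICA cleanup used on real recordings is delegated to an external
decomposition behind `apply_component_rejection` (components in, rejected
indices out) and is disabled by default on synthetic data, which contains no
blink or muscle activity. Recordings are assumed referenced on ingest.

## Network statistics

Per-unit Q² tensors are compared edge-wise and timepoint-wise with **Welch's**
two-sample t (safer than pooled under variance heterogeneity, identical in
the limit of equal variances), diagonal excluded. The p-value family is all
off-diagonal edges × all post-warm-up time points, corrected in one
Benjamini–Hochberg pass (statsmodels); the significance set is the BH
step-up rejection set, i.e. adjusted p ≤ α — the step-up rule rejects at the
boundary, as the worked example p = {0.01, 0.02, 0.03, 0.04, 0.9} at α = 0.05
shows. "Units" are subjects in a group study; on a single synthetic session
the pipeline forms disjoint trial sub-ensembles per condition as
pseudo-subjects (config `n_units`). How Q² was aggregated over trials and
time before testing in the source analysis is unstated, so both axes are
explicit configuration here. A window summary reports edges significant with
consistent sign in ≥ 50% of window time points, grouped by 10-20 scalp
region (frontal, central, temporal, parietal, occipital, midline).

Under the null (both groups from one generative model, full
simulate→fit→ADTF chain per unit) the mean FDR-significant fraction is
≪ α = 0.05 over 100 replicates; a 3-pooled-SD planted edge shift is detected
in ≥ 90% of seeds.

## ERP and behavior

Component amplitudes are window means of condition-averaged waveforms,
relative to S2 onset: P1 60–110 ms and N1 112–200 ms at P3/P4/O1/O2; N270
220–320 ms and P3 322–500 ms at C3/C4/P3/P4. (Electrode sets follow the
source's reported selections and are configurable — the original choice was
by visual inspection.) Behavioral trials keep correct responses with
200 ms ≤ RT ≤ 1500 ms; boundary values are retained because the exclusion is
strict (< 200 or > 1500). Correct rate is computed over all attempted trials;
RT statistics over surviving trials only.

The repeated-measures ANOVA engine handles any fully-crossed within-subject
factorial via orthonormal Kronecker contrasts: for effect E, C_E is the
Kronecker product of orthonormal contrast bases (factors in E) and normalized
unit vectors (factors averaged out); with D = YC_E' the F statistic is
(n‖d̄‖²/q)/(Σ‖D−d̄‖²/(q(n−1))) and the Greenhouse–Geisser ε =
tr(Σ_D)²/(q·tr(Σ_D²)) from the contrast-score covariance, clamped to
[1/q, 1]; F is referred to (q·ε, q(n−1)·ε) degrees of freedom. ε = 1 exactly
for two-level factors. Pairwise follow-ups are paired t-tests Bonferroni-
multiplied and capped at 1. The engine matches pingouin (F, p, ε) for one-
and two-way designs and statsmodels AnovaRM (F) for three-way; pingouin's
*interaction* ε uses a different convention its own documentation flags as
unreliable, so interaction ε is compared only against the contrast-based
definition above. Zero-error-variance effects are flagged, not crashed.

## Synthetic sessions

`synthetic.simulate_session` emulates the study conditions: 21 channels
(10-20 montage), 1,024 Hz, S1 500 ms → 500 ms ISI with the pulse 300 ms
before S2 → S2 500 ms, 5 s from S2 offset to the next S1, four equiprobable
stimulus-pair types × 2 tasks × 2 conditions (80 trials at 5/cell, one block
per task-condition pairing). Components:

- **Background**: a stable sparse random VAR(2) (spectral radius 0.7, ~10%
  coupling density), innovation scale 5 µV. `simulate_tvmvar` implements a
  general piecewise (step or linear) coefficient schedule with stability
  checked at every breakpoint and a discarded burn-in of 10·order samples.
- **ERP templates**: Gaussians in time (latency, amplitude, σ, per-channel
  gain, per-cell modulation), because Gaussians make window means analytic —
  the planted N270 (−6 µV, 270 ms, σ 25 ms) has closed-form window mean
  −6·(√(2π)·25/100)·(Φ(2)−Φ(−2)) = −3.59 µV over 220–320 ms. The default set
  plants the study's qualitative pattern: N270 absent for match pairs and
  attenuated ×0.45 under real stimulation; P1 enhanced under real; P3
  condition-insensitive.
- **Pulse artifact**: a signed exponential (default 300 µV, τ = 15 ms) at the
  pulse sample of real-condition trials — no artifact shape is described in
  the source, only its removal, so the model is the simplest one that makes
  excision testable.
- **Behavior**: shifted-lognormal RTs (shift 150 ms, shape 0.175 — matching
  the reported ±70–90 ms cell SDs) with cell means defaulting to the
  reported condition × task × type table; Bernoulli correctness at the
  reported ~98–99% rates.

What the generator does *not* emulate: volume conduction and a biophysical
forward model, blink/EMG artifacts, sham-coil acoustic/somatosensory effects,
inter-subject variability, or 1/f spectra beyond what the AR background
provides. Passing tests therefore establish correctness of the estimation
chain under known ground truth, not performance on real recordings.

## Numerical and bookkeeping conventions

- Time windows half-open; event geometry exact by construction
  ((S2−TMS) = round(0.3·fs), (S2−S1) = round(1.0·fs)).
- All randomness flows from a single integer seed via `numpy` Generators;
  identical seed ⇒ bit-identical sessions, fits, and manifests.
- Recording interchange: `.npy` + JSON sidecar (µV, events, labels) for
  exact round trips; EDF reading via mne when installed. Statistics tables
  are long-format TSV; epochs live in one HDF5 container per run.
- The run manifest records config digest, seeds, stage runtimes, and output
  inventory, written atomically.

## Validation problem sizes

The bundled experiments (also run by `scripts/acceptance.py`) use 3-channel
networks: stationary recovery on 2,000 samples × 20 seeds; step tracking with
50-trial ensembles × 50 seeds; edge ranking over 40 seeds; null-calibration
over 100 replicates of 2 × 6 units (6 trials each); and one full 21-channel,
80-trial session end to end. These sizes give stable pass/fail margins at
interactive runtimes.

## Known limitations

- No forward–backward (smoother) pass; estimates lag changes by the filter's
  adaptation time rather than straddling them symmetrically.
- No sparse or regularized MVAR variants; at 21 channels and order ~3 the
  ensemble fit is well-conditioned, but larger montages would need shrinkage.
- The default two-sample comparison treats units as independent, as the
  source analysis states; the within-subject structure of the original
  design would justify the paired test available behind ``paired=True``.
- AIC order selection is stationary by definition of the criterion; a
  strongly time-varying innovation structure could bias it.
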