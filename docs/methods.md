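# Methods

`nirsnet` measures how resting-state fNIRS connectome features depend on
scanning duration.  This note documents the model behind each stage, the
parameters that matter, what the synthetic cohort does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Synthetic cohort model

A cohort is `n_subjects` × `n_runs` recordings of `n_channels` hemoglobin
concentration series at `sampling_rate_hz` for `duration_s` seconds
(defaults 18 × 2 × 46 at 25 Hz for 600 s, mirroring a whole-head two-run
resting-state acquisition; analyses in the tests and the acceptance script
use a reduced profile of 6 subjects at 5 Hz, which leaves the 0.01–0.1 Hz
signal untouched while cutting compute roughly fivefold).

**Clean signal.**  White Gaussian noise per channel is band-limited to the
analysis band by a zero-phase Butterworth filter and standardized, then mixed
through the Cholesky factor of the run-level correlation matrix, giving a
stationary Gaussian process whose channel covariance equals the target and
whose power lies inside the band.  The synthesis filter is order 6 rather
than the analysis filter's order 3: an order-3 zero-phase response leaves
roughly 4 % of white-noise power outside the strict band edges, while order 6
confines ≈ 98 %, so "the generated signal is in-band" is true in the measured
(Welch) sense and not only nominally.  A two-period burn-in pad is generated
and discarded on each side so no filter edge transients enter the record.

**Ground-truth connectome.**  The population correlation matrix is modular:
`n_modules` blocks (default: modules of ≥ ~4 channels, at most 4 modules)
with within-module correlation 0.6, between-module correlation 0.2, small
seeded jitter, projected to the nearest unit-diagonal PSD matrix.  The
positive between-module floor reflects the predominantly positive coupling
of resting-state cortical hemodynamics; structurally it also guarantees that
even a 60-s window yields enough positive sample correlations to support
the densest sparsity threshold (0.5).

**Test–retest structure.**  Each subject-run matrix is a perturbation of the
population matrix on the Fisher-z scale by a multiplicative gain
exp(sd_b·a_subject + sd_w·e_run), where a_subject is shared across a
subject's runs and e_run is drawn per run.  The implied intraclass
correlation of any quantity driven by this latent scalar is
sd_b²/(sd_b²+sd_w²); defaults sd_b = 0.2, sd_w = 0.1 give ICC = 0.8.
Setting sd_w = 0 makes both runs share one generating matrix exactly (the
degenerate perfect-reliability case used in convergence tests).

**Artifacts.**  Five classes, each stored in the ground-truth bundle so that
`clean + Σ contributions` reproduces the emitted data bit-for-bit:

| class | waveform | spatial profile | default amplitude |
|---|---|---|---|
| spikes / jumps | exponential spike (τ = 2 s) or sustained step | single channel | 6 µM, 1 event/min |
| drift | shared U-shaped quadratic | Gaussian loadings | 1.5 µM |
| cardiac | ~1 Hz sinusoid | near-uniform (±20 %) | 0.8 µM |
| respiratory | ~0.3 Hz sinusoid | near-uniform (±20 %) | 0.8 µM |
| global superficial | in-band, super-Gaussian (cubed band-limited noise) | near-uniform (±10 %) | 1.5 µM |
| sensor noise | white Gaussian | independent per channel | 0.3 µM |

Amplitudes are in units of the unit-variance clean signal; none are estimates
of any particular instrument.  Two design points deserve emphasis.  The
global superficial component is deliberately placed *inside* the analysis
band so that only the spatial criterion can reject it, and its waveform is
made super-Gaussian (cubed band-limited noise — bursty, like systemic skin
blood flow): a Gaussian in-band waveform would be statistically
indistinguishable from the neural signal and no blind source separation
could isolate it.  The white sensor noise sets a realistic noise floor for
the first-difference jump statistic; without it, the z-score denominator of
smooth oversampled sources collapses and jump detection degenerates.

**Randomness.**  One master seed; every (subject, run) stream is a
`SeedSequence` spawn key, so cohorts are bit-reproducible and independent of
generation order.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: photon transport and optode coupling physics,
spatially structured (non-modular) cortical covariance, non-stationary
arousal drifts, eyes-open/closed state effects, subject motion with
channel-correlated geometry, and any deviation of real artifact waveforms
from the four stylized classes above.

## Preprocessing

**Beer-Lambert inversion.**  ΔOD at two wavelengths maps to (ΔHbO, ΔHbR) by
inverting the 2×2 extinction·DPF·separation system per channel and sample.
Default extinction values approximate 690/830 nm, DPF 6.0, separation
3.2 cm; the inverse is exact by construction (round-trip error ≲ 1e−12).

**PCA + ICA.**  Channels-as-features PCA keeps the smallest dimension
reaching `variance_retained` (default 0.99); FastICA (logcosh, symmetric
decorrelation, fixed seed, up to 5 restarts at tol 1e−3 / 1500 iterations)
unmixes the reduced data into temporal sources.

**Rejection criteria.**  A component is noise iff any of:

1. *Temporal*: max robust z of first differences > 15, or quadratic-trend
   R² > 0.8 (U / inverted-U), or > 2 spike events/min at |z| > 5.  The jump
   threshold sits above the empirical null of ICA sources from artifact-free
   records (~12 — FastICA maximizes non-Gaussianity and manufactures spiky
   projections by chance), while genuine discontinuities score 20–110.
2. *Spectral*: Welch power-spectrum peak outside 0.01–0.1 Hz.
3. *Spatial*: spatial kurtosis of the mixing column below −1.75, where
   spatial kurtosis is the *uncentered* excess kurtosis m₄/m₂² − 3 of the
   unit-normalized loadings.  A constant map scores −2 (minimum), a
   near-uniform global map ≈ −1.9, Gaussian-dispersed loadings ≈ 0, module-
   confined or focal maps are positive to large.  Centered kurtosis cannot
   make this separation: a map in which every channel loads equally is a
   tight cluster and looks Gaussian once centered.  All three statistics are
   invariant to component sign and scale.

**Denoising.**  The identified noise subspace (noise mixing columns ×
sources) is *subtracted from the original data* — algebraically the same as
zeroing the mixing columns, but the PCA-truncation residual stays in the
output, so a run with no flagged components passes through exactly.

**Filtering and binning.**  Zero-phase order-3 Butterworth band-pass
0.01–0.1 Hz (forward–backward; ≥ 20 dB one octave outside either edge, no
group delay); records shorter than 3×(1/low) seconds are rejected.  The
filtered record is cut into 19 prefix windows of 60, 90, …, 600 s, all
anchored at sample 0 so each window extends the previous one — the natural
reading of "increasing scanning duration".

## Connectivity

Pearson correlation, and maximum cross-correlation over symmetric lags
d ∈ [−L, +L] with L = 20 s by default (bounded physiological delays; a
symmetric lag set keeps the matrix symmetric, as an undirected graph
analysis requires).  At each lag the means and variances are recomputed on
the overlapping segments, so every value is a genuine correlation in
[−1, 1]; lags with overlap below half the window are skipped.  Ties in the
argmax resolve toward the smallest |d|, negative before positive.  L = 0
reduces exactly to the Pearson estimator.  No Fisher transform is applied
anywhere; raw r is analyzed throughout.

## Graph metrics

Thresholding keeps the strongest round(s·M) positive correlations
(M = n(n−1)/2; round = half away from zero; floor available by config);
negative correlations are never selected and an unsatisfiable threshold is
an error, not a silent denser graph.  Cutoff ties break lexicographically
by (i, j), making every network a deterministic function of its FC matrix.

Distances: hop counts (binary) or Dijkstra with edge length 1/weight
(weighted); path counts by a vectorized fixpoint over the shortest-path
predecessor DAG; neighbour-subgraph distances for local efficiency by a
dense Floyd–Warshall (cheapest at subgraph scale).  Unreachable pairs
contribute zero efficiency and are excluded from betweenness ratios.

Betweenness is normalized by (n−1)(n−2) with summation over *unordered*
node pairs, so the centre of a 3-path scores 0.5 (and a star centre 0.5).
Weighted clustering uses the Onnela geometric-mean triangle intensity with
max-weight normalization and binary degrees.  The AUC over the sparsity
grid is the composite trapezoid (0.33 × mean height over the default grid).

## Evaluation

Stability: per subject, the FC (or nodal-metric AUC) map of each window is
correlated with that subject's 600-s reference map; group mean ± sd is
reported, and the 600-s bin is the self-comparison (r = 1 exactly).  Global
metric AUCs use two-sided paired t-tests against the reference (n ≥ 3
subjects required; smaller cohorts report NaN).  Reproducibility: the same
map correlations between run 1 and run 2 at matched durations; global AUCs
use a single across-subject correlation.  Reliability: one-way
random-effects ICC = (MS_b − MS_w)/(MS_b + (k−1)MS_w); for maps the ICC is
computed element-wise (per edge / per node) and averaged, for global AUCs on
the scalar directly.  Negative ICCs are reported as computed and banded
"low"; bands follow low < 0.4 ≤ fair < 0.6 ≤ good < 0.75 ≤ excellent
(config-overridable).  p-values are reported unadjusted.

On a stationary 6-subject cohort the between-run FC map correlation rises
steadily with duration (sampling noise in each run's FC estimate shrinks
while the shared generating matrix stays fixed) but does not reach 1 at
600 s — a finite record caps the achievable similarity; only the infinite-
duration limit is exactly 1.  Nodal-metric maps on a near-homogeneous
modular network carry little true node-to-node spread, so their between-run
correlations hover near zero at these durations: between-run convergence
claims are therefore evaluated on FC maps.

## Problem sizes

Unit tests run on 8-channel, 1 Hz toy cohorts (600 s, so the full 19-bin
grid applies).  Pipeline-level checks use 6 subjects × 2 runs × 46 channels
at 5 Hz — the full design at a reduced rate, chosen so a complete sweep
(2 FC methods × 2 network modes × 34 sparsities × 19 durations) runs in a
few minutes on one CPU.  ICC recovery uses the n = 200, k = 2 design with
501 replicates; the replicate count only narrows the sampling noise of the
reported median error.

## Known limitations

- FastICA on predominantly Gaussian data is an ill-posed separation; the
  rejection thresholds are calibrated against its empirical null rather
  than any closed-form distribution, and drift that mixes across several
  components is only partially removed.
- The cross-correlation estimator's maximum-over-lags is biased upward for
  short windows (a maximum over correlated noisy values); the duration
  sweep shows this as lower stability at short durations rather than
  correcting for it, matching how the estimator is used in practice.
- Weighted local efficiency uses plain 1/weight path lengths inside the
  neighbour subgraph; other weighted variants exist and would change
  absolute values (not the duration trends).
- The ICC of FC maps is a mean of per-edge one-way ICCs, one defensible
  summary among several; no consensus element-wise definition exists.
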