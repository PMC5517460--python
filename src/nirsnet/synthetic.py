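"""Synthetic resting-state fNIRS cohort generator with known ground truth.

Emulates the acquisition design the pipeline targets — 18 subjects, two runs,
46 channels at 25 Hz, ~10 min of spontaneous hemodynamics — as band-limited
(0.01-0.1 Hz) correlated Gaussian fluctuations with a modular ground-truth
correlation structure, plus the four artifact classes the ICA rejection
criteria are built to detect:

* focal spikes / sudden baseline jumps (motion),
* a slow U-shaped drift component (instrumental),
* out-of-band physiological oscillations (cardiac ~1 Hz, respiratory ~0.3 Hz),
* a globally loaded, spatially dispersive superficial component that lives
  *inside* the analysis band (systemic scalp interference).

Two variance components control test-retest ground truth: a between-subject
perturbation shared by both of a subject's runs and a within-subject (run
level) perturbation, giving true ICC = sd_b^2 / (sd_b^2 + sd_w^2).

Randomness is counter-based: every (subject, run) stream is derived from the
master seed by `numpy.random.SeedSequence` spawn keys, so cohorts are
reproducible bit-for-bit and independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .recording import HemodynamicRecording, default_channel_layout

__all__ = [
    "ArtifactParams",
    "CohortSpec",
    "GroundTruthBundle",
    "Cohort",
    "OpticalProperties",
    "make_modular_covariance",
    "simulate_run",
    "simulate_cohort",
    "simulate_optical_density",
    "derive_hbr",
    "simulate_reliability_scalars",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class ArtifactParams:
    """Amplitudes (µM, relative to unit-variance clean signal) and rates of the
    injected artifact classes.  Setting an amplitude to 0 disables that class.
    """

    spike_amplitude: float = 6.0
    spike_rate_per_min: float = 1.0   # events per minute across the array
    spike_tau_s: float = 2.0
    jump_fraction: float = 0.3        # fraction of events that are baseline jumps
    drift_amplitude: float = 1.5
    cardiac_amplitude: float = 0.8
    cardiac_freq_hz: float = 1.0
    respiratory_amplitude: float = 0.8
    respiratory_freq_hz: float = 0.3
    global_amplitude: float = 1.5
    global_band_hz: tuple = (0.01, 0.1)  # superficial component is in-band
    sensor_noise_sd: float = 0.3         # white instrument noise, µM

    @classmethod
    def none(cls) -> "ArtifactParams":
        """Artifact-free (stationary) configuration."""
        return cls(
            spike_amplitude=0.0,
            drift_amplitude=0.0,
            cardiac_amplitude=0.0,
            respiratory_amplitude=0.0,
            global_amplitude=0.0,
            sensor_noise_sd=0.0,
        )


@dataclass
class CohortSpec:
    """Study design of a synthetic cohort.

    Defaults mirror the target acquisition (18 subjects x 2 runs, 46 channels
    at 25 Hz, 600 s); `sampling_rate_hz` is reducible (e.g. 5 Hz) for speed
    without leaving the analysis band, since the signal lives below 0.1 Hz.
    """

    n_subjects: int = 18
    n_runs: int = 2
    n_channels: int = 46
    duration_s: float = 600.0
    sampling_rate_hz: float = 25.0
    ground_truth_covariance: np.ndarray | None = None
    signal_band: tuple = (0.01, 0.1)
    artifact_params: ArtifactParams = field(default_factory=ArtifactParams)
    between_subject_sd: float = 0.2
    within_subject_sd: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_runs < 1 or self.n_channels < 2:
            raise ValueError("cohort must have >=1 subject, >=1 run, >=2 channels")
        if self.between_subject_sd < 0 or self.within_subject_sd < 0:
            raise ValueError("variance-component sds must be >= 0")
        n = self.duration_s * self.sampling_rate_hz
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration_s x sampling_rate_hz must be an integer sample count")
        if self.sampling_rate_hz <= 2 * self.signal_band[1]:
            raise ValueError("sampling rate must exceed twice the upper band edge")
        if self.ground_truth_covariance is None:
            # modules of at least ~4 channels keep the network community-like;
            # the positive between-module floor mirrors the predominantly
            # positive coupling of resting-state cortical signals and leaves
            # enough positive sample correlations for the densest thresholds
            # even in the shortest (60 s) analysis window
            n_modules = max(1, min(4, self.n_channels // 4))
            self.ground_truth_covariance = make_modular_covariance(
                self.n_channels, n_modules=n_modules, within_r=0.6, between_r=0.2,
                seed=self.rng_seed, jitter=0.02,
            )
        C = np.asarray(self.ground_truth_covariance, dtype=float)
        if C.shape != (self.n_channels, self.n_channels):
            raise ValueError("ground_truth_covariance shape mismatch")
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("ground_truth_covariance must be symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-8):
            raise ValueError("ground_truth_covariance must have unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise ValueError("ground_truth_covariance must be positive semidefinite")
        self.ground_truth_covariance = C

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate_hz))

    @property
    def true_icc(self) -> float:
        """ICC implied by the two variance components (NaN if both are 0)."""
        b2 = self.between_subject_sd ** 2
        w2 = self.within_subject_sd ** 2
        if b2 + w2 == 0:
            return float("nan")
        return b2 / (b2 + w2)


@dataclass
class GroundTruthBundle:
    """Everything the generator knows that the pipeline must recover.

    `injected_artifacts` holds (kind, channel_indices, (t0, t1), waveform)
    tuples, the waveform spanning exactly those channels and samples, so that
    ``clean_signal + artifact_sum(...)`` reproduces the emitted recording
    bit-for-bit (same accumulation order as the generator).
    """

    clean_signal: np.ndarray                    # channels x samples
    injected_artifacts: list                    # (kind, channel_idx, (t0, t1), waveform)
    true_fc: np.ndarray                         # generating correlation matrix (this run)
    true_icc: float
    subject_scalar: float                       # latent subject-run reliability scalar

    def artifact_sum(self, shape) -> np.ndarray:
        total = np.zeros(shape)
        for _, channels, (t0, t1), wave in self.injected_artifacts:
            total[np.ix_(channels, np.arange(t0, t1))] += wave
        return total


@dataclass
class Cohort:
    spec: CohortSpec
    recordings: dict            # (subject_index, run_index) -> HemodynamicRecording
    bundles: dict               # (subject_index, run_index) -> GroundTruthBundle

    def items(self):
        return sorted(self.recordings.keys())


# ---------------------------------------------------------------------------
# ground-truth covariance
# ---------------------------------------------------------------------------


def _project_correlation(C: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    """Nearest-PSD projection (eigenvalue clipping) followed by re-scaling to
    unit diagonal; the congruence D^-1/2 C D^-1/2 preserves PSD-ness."""
    C = (C + C.T) / 2.0
    w, V = np.linalg.eigh(C)
    if w.min() < floor:
        w = np.clip(w, floor, None)
        C = (V * w) @ V.T
    d = np.sqrt(np.diag(C))
    C = C / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return (C + C.T) / 2.0


def module_partition(n_channels: int, n_modules: int) -> list[np.ndarray]:
    """Contiguous near-equal partition of channel indices into modules."""
    sizes = [n_channels // n_modules + (1 if i < n_channels % n_modules else 0)
             for i in range(n_modules)]
    out, start = [], 0
    for s in sizes:
        out.append(np.arange(start, start + s))
        start += s
    return out


def make_modular_covariance(
    n_channels: int,
    n_modules: int,
    within_r: float,
    between_r: float = 0.0,
    seed: int = 0,
    jitter: float = 0.0,
) -> np.ndarray:
    """Connectome-like block correlation matrix: `within_r` inside modules,
    `between_r` across them, optional seeded jitter, projected to the nearest
    unit-diagonal PSD matrix.

    Community structure makes clustering and local efficiency non-trivial
    downstream; with jitter=0 the block values are exact.
    """
    if not (0 <= between_r < within_r < 1):
        raise ValueError("require 0 <= between_r < within_r < 1")
    if not (1 <= n_modules <= n_channels):
        raise ValueError("n_modules must be in [1, n_channels]")
    C = np.full((n_channels, n_channels), between_r, dtype=float)
    for idx in module_partition(n_channels, n_modules):
        C[np.ix_(idx, idx)] = within_r
    np.fill_diagonal(C, 1.0)
    if jitter > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(901,)))
        J = rng.normal(0.0, jitter, size=C.shape)
        J = (J + J.T) / 2.0
        np.fill_diagonal(J, 0.0)
        C = C + J
    C = _project_correlation(C)
    if np.linalg.eigvalsh(C).min() < -1e-10:
        raise ValueError("covariance not PSD after jitter and projection; reduce jitter")
    return C


# ---------------------------------------------------------------------------
# signal + artifact synthesis
# ---------------------------------------------------------------------------


def _band_sos(band: tuple, fs: float, order: int = 3):
    return sps.butter(order, band, btype="bandpass", fs=fs, output="sos")


def _band_limited_noise(rng, n_series: int, n_samples: int, band: tuple, fs: float,
                        order: int = 6) -> np.ndarray:
    """Unit-variance rows of zero-phase band-passed white Gaussian noise.

    Synthesis uses a zero-phase Butterworth of the same family as the
    preprocessing filter but steeper (order 6): an order-3 zero-phase response
    leaves ~4% of white-noise power outside the strict band edges, whereas
    order 6 confines ~98%, so the generated signal genuinely lives inside
    `band`.  A burn-in pad of twice the slowest period is generated on each
    side and discarded, so the emitted stretch carries no filter edge
    transients.
    """
    pad = int(np.ceil(2.0 * fs / band[0]))
    white = rng.standard_normal((n_series, n_samples + 2 * pad))
    x = sps.sosfiltfilt(_band_sos(band, fs, order), white, axis=1)[:, pad:pad + n_samples]
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _subject_run_fc(spec: CohortSpec, subject_index: int, run_index: int):
    """Run-level generating correlation matrix and the latent scalar behind it.

    The population matrix is perturbed on the Fisher-z scale by a multiplicative
    gain exp(lambda), lambda = sd_b * a_subject + sd_w * e_run; a_subject is
    shared across the subject's runs, e_run is independent per run.
    """
    rng_subj = np.random.default_rng(
        np.random.SeedSequence(spec.rng_seed, spawn_key=(1, subject_index)))
    a = rng_subj.standard_normal()
    rng_run = np.random.default_rng(
        np.random.SeedSequence(spec.rng_seed, spawn_key=(2, subject_index, run_index)))
    e = rng_run.standard_normal()
    lam = spec.between_subject_sd * a + spec.within_subject_sd * e
    C = spec.ground_truth_covariance
    off = ~np.eye(C.shape[0], dtype=bool)
    Z = np.arctanh(np.clip(C, -0.999999, 0.999999))
    Cp = np.ones_like(C)
    Cp[off] = np.tanh(Z[off] * np.exp(lam))
    return _project_correlation(Cp), float(lam)


def simulate_run(
    spec: CohortSpec, subject_index: int, run_index: int
) -> tuple[HemodynamicRecording, GroundTruthBundle]:
    """Generate one subject-run recording plus its ground-truth bundle.

    Deterministic given (rng_seed, subject_index, run_index).  The emitted data
    equal ``clean_signal + sum(artifact contributions)`` exactly.
    """
    if not (0 <= subject_index < spec.n_subjects):
        raise ValueError("subject_index out of range")
    if not (0 <= run_index < spec.n_runs):
        raise ValueError("run_index out of range")
    N = spec.n_samples
    fs = spec.sampling_rate_hz
    n_ch = spec.n_channels
    if N < 2 * 60 * fs:  # shortest analysis window is 60 s
        raise ValueError("record must cover at least twice the shortest analysis window")

    fc, lam = _subject_run_fc(spec, subject_index, run_index)
    rng = np.random.default_rng(
        np.random.SeedSequence(spec.rng_seed, spawn_key=(3, subject_index, run_index)))

    # clean neural signal: band-limited iid rows mixed through Cholesky(fc)
    base = _band_limited_noise(rng, n_ch, N, spec.signal_band, fs)
    L = np.linalg.cholesky(fc + 1e-9 * np.eye(n_ch))
    clean = L @ base

    t = np.arange(N) / fs
    ap = spec.artifact_params
    artifacts: list = []
    all_ch = np.arange(n_ch)

    def add(kind: str, channels: np.ndarray, t0: int, t1: int, wave: np.ndarray):
        artifacts.append((kind, channels, (t0, t1), wave))

    # (1) focal spikes / sudden baseline jumps
    if ap.spike_amplitude > 0 and ap.spike_rate_per_min > 0:
        n_events = rng.poisson(ap.spike_rate_per_min * spec.duration_s / 60.0)
        for _ in range(n_events):
            ch = int(rng.integers(n_ch))
            t0 = int(rng.integers(N))
            amp = ap.spike_amplitude * rng.choice([-1.0, 1.0]) * rng.uniform(0.7, 1.3)
            if rng.uniform() < ap.jump_fraction:
                add("jump", np.array([ch]), t0, N,
                    np.full((1, N - t0), amp))
            else:
                tail = np.arange(N - t0) / fs
                add("spike", np.array([ch]), t0, N,
                    (amp * np.exp(-tail / ap.spike_tau_s))[None, :])

    # (2) slow U-shaped drift: one shared quadratic waveform, random loadings
    if ap.drift_amplitude > 0:
        u = (t / t[-1] - 0.5) ** 2
        u = (u - u.mean()) / u.std()
        loadings = ap.drift_amplitude * rng.normal(0.0, 1.0, n_ch)
        add("drift", all_ch, 0, N, np.outer(loadings, u))

    # (3) out-of-band physiological oscillations (systemic: near-uniform maps)
    for kind, amp, f0 in (
        ("cardiac", ap.cardiac_amplitude, ap.cardiac_freq_hz),
        ("respiratory", ap.respiratory_amplitude, ap.respiratory_freq_hz),
    ):
        if amp > 0:
            if f0 >= fs / 2:
                raise ValueError(f"{kind} frequency {f0} Hz is above Nyquist at fs={fs}")
            wave = np.sqrt(2.0) * np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
            loadings = amp * (1.0 + 0.2 * rng.normal(0.0, 1.0, n_ch))
            add(kind, all_ch, 0, N, np.outer(loadings, wave))

    # (4) global, spatially dispersive superficial component (in-band!)
    # the waveform is made super-Gaussian (bursty, like systemic skin-blood-
    # flow fluctuations) by cubing band-limited noise: blind source
    # separation can then isolate it, which a Gaussian waveform would forbid
    if ap.global_amplitude > 0:
        g = _band_limited_noise(rng, 1, N, ap.global_band_hz, fs)[0]
        wave = g ** 3
        wave = wave / wave.std()
        loadings = ap.global_amplitude * (1.0 + 0.1 * rng.normal(0.0, 1.0, n_ch))
        add("global", all_ch, 0, N, np.outer(loadings, wave))

    # (5) white instrument noise (broadband; sets the jump-detection floor)
    if ap.sensor_noise_sd > 0:
        add("sensor_noise", all_ch, 0, N,
            ap.sensor_noise_sd * rng.standard_normal((n_ch, N)))

    # accumulate exactly as GroundTruthBundle.artifact_sum does, so
    # clean + artifact_sum reproduces `data` bit-for-bit
    art_total = np.zeros((n_ch, N))
    for _, channels, (t0, t1), wave in artifacts:
        art_total[np.ix_(channels, np.arange(t0, t1))] += wave
    data = clean + art_total

    rec = HemodynamicRecording(
        subject_id=f"S{subject_index + 1:02d}",
        run_id=str(run_index + 1),
        sampling_rate_hz=fs,
        data=data,
        channel_layout=default_channel_layout(n_ch),
        species="HbO",
    )
    bundle = GroundTruthBundle(
        clean_signal=clean,
        injected_artifacts=artifacts,
        true_fc=fc,
        true_icc=spec.true_icc,
        subject_scalar=lam,
    )
    return rec, bundle


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """All n_subjects x n_runs recordings of a cohort (order-independent)."""
    recordings, bundles = {}, {}
    for s in range(spec.n_subjects):
        for r in range(spec.n_runs):
            rec, bundle = simulate_run(spec, s, r)
            recordings[(s, r)] = rec
            bundles[(s, r)] = bundle
    return Cohort(spec=spec, recordings=recordings, bundles=bundles)


# ---------------------------------------------------------------------------
# optical forward model (two-wavelength Beer-Lambert)
# ---------------------------------------------------------------------------


@dataclass
class OpticalProperties:
    """Extinction coefficients (µM^-1 cm^-1), differential pathlength factors
    and source-detector separation for a two-wavelength CW measurement.

    Default extinction values approximate HbO/HbR at 690 and 830 nm; the
    separation default matches a 3.2 cm whole-head montage.
    """

    wavelengths_nm: tuple = (690.0, 830.0)
    # rows: wavelength; columns: (HbO, HbR)
    extinction: np.ndarray = field(
        default_factory=lambda: np.array([[0.00035, 0.00210], [0.00100, 0.00080]])
    )
    dpf: tuple = (6.0, 6.0)
    separation_cm: float = 3.2

    def system_matrix(self) -> np.ndarray:
        """2x2 map from (dHbO, dHbR) to (dOD_l1, dOD_l2)."""
        E = np.asarray(self.extinction, dtype=float)
        if E.shape != (2, 2):
            raise ValueError("extinction must be 2x2 (wavelength x chromophore)")
        D = np.diag(self.dpf) * self.separation_cm
        M = D @ E
        if abs(np.linalg.det(M)) < 1e-15:
            raise ValueError("singular extinction system; chromophores not separable")
        return M


def simulate_optical_density(
    hbo: HemodynamicRecording,
    hbr: HemodynamicRecording,
    optics: OpticalProperties | None = None,
) -> np.ndarray:
    """Forward Beer-Lambert model: concentration pair -> two-wavelength ΔOD.

    Returns an array of shape (2, n_channels, n_samples), first axis indexing
    the wavelengths of `optics`.  ΔOD(λ) = (ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR)
    · separation · DPF(λ), per channel and sample.
    """
    optics = optics or OpticalProperties()
    if hbo.data.shape != hbr.data.shape:
        raise ValueError("HbO and HbR recordings must share shape")
    M = optics.system_matrix()
    conc = np.stack([hbo.data, hbr.data])           # (2, ch, t)
    return np.einsum("wc,cij->wij", M, conc)


def derive_hbr(
    hbo: HemodynamicRecording, ratio: float = -0.3, noise_sd: float = 0.1,
    seed: int = 0,
) -> HemodynamicRecording:
    """Physiologically anti-correlated HbR companion of an HbO recording
    (scaled negative copy plus independent in-band noise); a convenience for
    exercising the optical forward/inverse model."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
    noise = noise_sd * _band_limited_noise(
        rng, hbo.n_channels, hbo.n_samples, (0.01, 0.1), hbo.sampling_rate_hz
    ) if noise_sd > 0 else 0.0
    from dataclasses import replace

    return replace(hbo, data=ratio * hbo.data + noise, species="HbR")


# ---------------------------------------------------------------------------
# reliability ground truth
# ---------------------------------------------------------------------------


def simulate_reliability_scalars(
    n_subjects: int,
    n_runs: int,
    between_sd: float,
    within_sd: float,
    seed: int = 0,
    mean: float = 0.0,
) -> np.ndarray:
    """Subjects x runs matrix x_ij = mean + sd_b·a_i + sd_w·e_ij, the additive
    two-component model whose population ICC is sd_b^2/(sd_b^2+sd_w^2).

    Used to verify that the ICC estimator recovers a known reliability."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(8,)))
    a = rng.standard_normal((n_subjects, 1))
    e = rng.standard_normal((n_subjects, n_runs))
    return mean + between_sd * a + within_sd * e
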