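"""Preprocessing: Beer-Lambert inversion, PCA+ICA artifact rejection,
zero-phase band-pass filtering, and duration binning.

A decomposition's components are screened by three criteria; a component is
labelled noise if *any* flags true:

(i)  temporal artifact — sudden jumps (robust z of first differences), a
     slowly varying U / inverted-U trend (quadratic R^2), or a high rate of
     intermittent spikes;
(ii) spectral — the dominant Welch-periodogram frequency lies outside the
     low-frequency analysis band (default 0.01-0.1 Hz);
(iii) spatial — the mixing column is globally, near-uniformly loaded across
     channels (spatially dispersive pattern typical of superficial systemic
     interference), quantified by a low spatial kurtosis about zero.

Denoising removes the noise components' subspace (equivalent to zeroing
their mixing columns) by subtracting it from the original data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps
from sklearn.decomposition import PCA, FastICA
from sklearn.exceptions import ConvergenceWarning

from .config import CriteriaConfig
from .recording import DurationWindow, HemodynamicRecording
from .synthetic import OpticalProperties

__all__ = [
    "ComponentDecomposition",
    "mbll_convert",
    "decompose",
    "classify_components",
    "reconstruct_denoised",
    "bandpass",
    "truncate_bins",
    "preprocess_recording",
]


# ---------------------------------------------------------------------------
# MBLL inversion
# ---------------------------------------------------------------------------


def mbll_convert(
    od: np.ndarray,
    optics: OpticalProperties | None = None,
    *,
    sampling_rate_hz: float | None = None,
    subject_id: str = "S00",
    run_id: str = "1",
    cond_warn: float = 1e6,
) -> tuple[HemodynamicRecording, HemodynamicRecording]:
    """Invert two-wavelength ΔOD to (ΔHbO, ΔHbR) concentration recordings.

    `od` has shape (2, n_channels, n_samples) as produced by
    :func:`nirsnet.synthetic.simulate_optical_density`; the same 2x2
    extinction·DPF·separation system is solved per sample.
    """
    optics = optics or OpticalProperties()
    od = np.asarray(od, dtype=float)
    if od.ndim != 3 or od.shape[0] != 2:
        raise ValueError("od must have shape (2, n_channels, n_samples)")
    M = optics.system_matrix()
    cond = np.linalg.cond(M)
    if cond > cond_warn:
        warnings.warn(f"extinction system ill-conditioned (cond={cond:.3g})")
    Minv = np.linalg.inv(M)
    conc = np.einsum("cw,wij->cij", Minv, od)
    fs = sampling_rate_hz or 1.0
    hbo = HemodynamicRecording(subject_id, run_id, fs, conc[0], species="HbO")
    hbr = HemodynamicRecording(subject_id, run_id, fs, conc[1], species="HbR")
    return hbo, hbr


# ---------------------------------------------------------------------------
# PCA + ICA decomposition
# ---------------------------------------------------------------------------


@dataclass
class ComponentDecomposition:
    """PCA-reduced temporal ICA of one recording.

    ``mixing @ sources + channel_means[:, None]`` reconstructs the
    PCA-retained portion of the input.
    """

    recording: HemodynamicRecording
    sources: np.ndarray          # components x samples
    mixing: np.ndarray           # channels x components
    channel_means: np.ndarray    # per-channel offsets
    variance_retained: float
    criteria_flags: dict | None = None   # name -> bool array per component
    labels: np.ndarray | None = None     # "signal" / "noise" per component

    @property
    def n_components(self) -> int:
        return self.sources.shape[0]

    @property
    def sampling_rate_hz(self) -> float:
        return self.recording.sampling_rate_hz

    def reconstruct(self, keep: np.ndarray | None = None) -> np.ndarray:
        mix = self.mixing if keep is None else self.mixing[:, keep]
        src = self.sources if keep is None else self.sources[keep]
        return mix @ src + self.channel_means[:, None]


def decompose(
    recording: HemodynamicRecording,
    variance_retained: float = 0.99,
    random_state: int = 0,
    max_restarts: int = 5,
    max_iter: int = 1500,
    tol: float = 1e-3,
) -> ComponentDecomposition:
    """PCA to the smallest dimension reaching `variance_retained`, then
    FastICA (symmetric decorrelation) in the reduced space.

    A fixed internal seed keeps runs reproducible; non-convergent ICA is
    retried with fresh seeds up to `max_restarts` times before failing.
    """
    if not (0 < variance_retained <= 1):
        raise ValueError("variance_retained must be in (0, 1]")
    X = recording.data.T  # samples x channels
    if variance_retained >= 1.0:
        n_comp = min(X.shape)
    else:
        pca = PCA(n_components=variance_retained, svd_solver="full")
        pca.fit(X)
        n_comp = int(pca.n_components_)
    n_comp = max(n_comp, 1)

    last_err: Exception | None = None
    for attempt in range(max_restarts + 1):
        ica = FastICA(
            n_components=n_comp,
            whiten="unit-variance",
            fun="logcosh",
            algorithm="parallel",
            max_iter=max_iter,
            tol=tol,
            random_state=random_state + attempt,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            try:
                S = ica.fit_transform(X)  # samples x components
            except Exception as err:  # pragma: no cover - rare numeric failure
                last_err = err
                continue
            if not any(issubclass(w.category, ConvergenceWarning) for w in caught):
                break
            last_err = RuntimeError(
                f"FastICA did not converge in {max_iter} iterations "
                f"(attempt {attempt + 1}, seed {random_state + attempt})"
            )
    else:
        raise RuntimeError(
            f"ICA failed after {max_restarts + 1} attempts on "
            f"{recording.subject_id}/run{recording.run_id}: {last_err}"
        )
    return ComponentDecomposition(
        recording=recording,
        sources=S.T,
        mixing=ica.mixing_,
        channel_means=ica.mean_,
        variance_retained=variance_retained,
    )


# ---------------------------------------------------------------------------
# noise-component criteria
# ---------------------------------------------------------------------------


def _robust_z(x: np.ndarray) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    scale = 1.4826 * mad
    if scale <= 0:
        scale = x.std() or 1.0
    return (x - med) / scale


def _quadratic_r2(x: np.ndarray) -> float:
    t = np.linspace(-1.0, 1.0, x.size)
    coef = np.polynomial.polynomial.polyfit(t, x, 2)
    fit = np.polynomial.polynomial.polyval(t, coef)
    ss_tot = np.sum((x - x.mean()) ** 2)
    if ss_tot == 0:
        return 0.0
    return float(1.0 - np.sum((x - fit) ** 2) / ss_tot)


def dominant_frequency(x: np.ndarray, fs: float) -> float:
    """Peak of the Welch power spectrum (DC bin excluded)."""
    nperseg = min(x.size, int(round(256 * fs)))
    nperseg = max(nperseg, 8)
    f, p = sps.welch(x - x.mean(), fs=fs, nperseg=nperseg)
    if f.size > 1:
        f, p = f[1:], p[1:]
    return float(f[np.argmax(p)])


def spatial_kurtosis(column: np.ndarray) -> float:
    """Excess kurtosis of a mixing column about zero: m4/m2^2 - 3 of the
    unit-normalized loadings.  Near-uniform (global) maps approach the
    minimum of -2; focal maps are large and positive.  Sign-blind, scale-free.
    """
    a = np.asarray(column, dtype=float)
    m2 = np.mean(a ** 2)
    if m2 == 0:
        return -2.0
    return float(np.mean(a ** 4) / m2 ** 2 - 3.0)


def classify_components(
    decomp: ComponentDecomposition,
    band: tuple = (0.01, 0.1),
    params: CriteriaConfig | None = None,
) -> ComponentDecomposition:
    """Apply the three rejection criteria; returns the decomposition with
    `criteria_flags` and `labels` filled in (noise iff any flag true).

    All statistics are invariant to component sign and scale.
    """
    if decomp.n_components < 1:
        raise ValueError("decomposition has no components")
    p = params or CriteriaConfig()
    fs = decomp.sampling_rate_hz
    k = decomp.n_components
    temporal = np.zeros(k, dtype=bool)
    out_of_band = np.zeros(k, dtype=bool)
    dispersive = np.zeros(k, dtype=bool)
    details = {
        "dominant_freq_hz": np.zeros(k),
        "jump_z_max": np.zeros(k),
        "ushape_r2": np.zeros(k),
        "spike_rate_per_min": np.zeros(k),
        "spatial_kurtosis": np.zeros(k),
    }
    min_samples_for_spectrum = 2 * max(8, int(round(64 * fs)))
    for i in range(k):
        s = decomp.sources[i]
        jump = float(np.max(np.abs(_robust_z(np.diff(s)))))
        r2 = _quadratic_r2(s)
        z = np.abs(_robust_z(sps.detrend(s)))
        # count spike events, merging contiguous supra-threshold samples
        above = z > p.spike_z
        n_events = int(np.sum(above[1:] & ~above[:-1]) + (1 if above[0] else 0))
        rate = n_events / (s.size / fs / 60.0)
        details["jump_z_max"][i] = jump
        details["ushape_r2"][i] = r2
        details["spike_rate_per_min"][i] = rate
        temporal[i] = (jump > p.jump_z) or (r2 > p.ushape_r2) or (rate > p.spike_rate_per_min)
        if s.size < min_samples_for_spectrum:
            warnings.warn(
                f"component {i}: record too short for spectral criterion; flag left false")
            details["dominant_freq_hz"][i] = np.nan
        else:
            f0 = dominant_frequency(s, fs)
            details["dominant_freq_hz"][i] = f0
            out_of_band[i] = not (band[0] <= f0 <= band[1])
        sk = spatial_kurtosis(decomp.mixing[:, i])
        details["spatial_kurtosis"][i] = sk
        dispersive[i] = sk < p.spatial_kurtosis
    flags = {
        "temporal_artifact": temporal,
        "out_of_band": out_of_band,
        "spatially_dispersive": dispersive,
    }
    flags.update(details)
    noise = temporal | out_of_band | dispersive
    labels = np.where(noise, "noise", "signal")
    return replace(decomp, criteria_flags=flags, labels=labels)


def component_report(decomp: ComponentDecomposition):
    """Per-component criterion table (flags plus the statistics behind them),
    suitable for writing as TSV alongside the denoised recording."""
    import pandas as pd

    if decomp.criteria_flags is None:
        raise ValueError("run classify_components first")
    f = decomp.criteria_flags
    return pd.DataFrame({
        "component": np.arange(decomp.n_components),
        "label": decomp.labels,
        "temporal_artifact": f["temporal_artifact"],
        "out_of_band": f["out_of_band"],
        "spatially_dispersive": f["spatially_dispersive"],
        "jump_z_max": f["jump_z_max"],
        "ushape_r2": f["ushape_r2"],
        "spike_rate_per_min": f["spike_rate_per_min"],
        "dominant_freq_hz": f["dominant_freq_hz"],
        "spatial_kurtosis": f["spatial_kurtosis"],
    })


def reconstruct_denoised(decomp: ComponentDecomposition) -> HemodynamicRecording:
    """Remove the noise components from the recording.

    The identified noise subspace (mixing columns x sources of every
    component labelled noise) is subtracted from the *original* data —
    algebraically the same as zeroing those mixing columns, but the part of
    the signal the PCA reduction did not model is left untouched, so with no
    components flagged the recording passes through exactly.
    """
    if decomp.labels is None:
        raise ValueError("labels not assigned; run classify_components first")
    keep = decomp.labels == "signal"
    if not keep.any():
        raise ValueError("all components labelled noise; nothing left to reconstruct")
    noise = ~keep
    if not noise.any():
        return decomp.recording.with_data(decomp.recording.data.copy())
    removed = decomp.mixing[:, noise] @ decomp.sources[noise]
    return decomp.recording.with_data(decomp.recording.data - removed)


# ---------------------------------------------------------------------------
# band-pass filter and duration bins
# ---------------------------------------------------------------------------


def bandpass(
    recording: HemodynamicRecording,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    order: int = 3,
) -> HemodynamicRecording:
    """Zero-phase (forward-backward) Butterworth band-pass.

    The effective magnitude response is squared, giving >=20 dB attenuation one
    octave outside either edge at the default order; forward-backward
    application cancels group delay.
    """
    fs = recording.sampling_rate_hz
    if high_hz >= fs / 2:
        raise ValueError(f"high edge {high_hz} Hz must be below Nyquist ({fs / 2} Hz)")
    if low_hz <= 0 or low_hz >= high_hz:
        raise ValueError("require 0 < low_hz < high_hz")
    settle_samples = int(round(3 * fs / low_hz))
    if recording.n_samples < settle_samples:
        raise ValueError(
            f"record ({recording.n_samples} samples) shorter than 3x filter "
            f"settling length ({settle_samples} samples at low={low_hz} Hz)")
    sos = sps.butter(order, (low_hz, high_hz), btype="bandpass", fs=fs, output="sos")
    return recording.with_data(sps.sosfiltfilt(sos, recording.data, axis=1))


def truncate_bins(
    recording: HemodynamicRecording,
    min_s: float = 60.0,
    max_s: float = 600.0,
    step_s: float = 30.0,
) -> list[DurationWindow]:
    """Prefix windows of min_s, min_s+step_s, ..., max_s seconds (default
    60..600 step 30 -> 19 windows), all anchored at sample 0."""
    if recording.duration_s < max_s - 1e-9:
        raise ValueError(
            f"recording covers only {recording.duration_s:.1f} s; "
            f"{max_s:.0f} s required (longest duration bin)")
    n = int(round((max_s - min_s) / step_s)) + 1
    return [DurationWindow(recording, min_s + k * step_s) for k in range(n)]


def preprocess_recording(recording, config) -> HemodynamicRecording:
    """Full denoise + filter chain under a :class:`PipelineConfig`."""
    rec = recording
    if config.trim_s > 0:
        start = int(round(config.trim_s * rec.sampling_rate_hz))
        rec = rec.with_data(rec.data[:, start:])
    if config.denoise:
        d = decompose(
            rec,
            variance_retained=config.ica.variance_retained,
            random_state=config.ica.random_state,
            max_restarts=config.ica.max_restarts,
            max_iter=config.ica.max_iter,
            tol=config.ica.tol,
        )
        d = classify_components(
            d, band=(config.filter.low_hz, config.filter.high_hz), params=config.criteria)
        if (d.labels == "signal").any():
            rec = reconstruct_denoised(d)
        else:
            warnings.warn(
                f"{rec.subject_id}/run{rec.run_id}: all components flagged as "
                "noise; skipping ICA rejection for this run")
    return bandpass(rec, config.filter.low_hz, config.filter.high_hz, config.filter.order)
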