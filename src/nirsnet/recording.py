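"""Core in-memory containers for multichannel hemodynamic recordings.

A recording is a channels x samples matrix of concentration changes (µM) for a
single chromophore (HbO or HbR), one subject and one scanning run, together
with the sampling rate and a 2-D channel layout used for spatial maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

VALID_SPECIES = ("HbO", "HbR")


def default_channel_layout(n_channels: int) -> np.ndarray:
    """Evenly spaced positions on two concentric rings (arbitrary head-surface
    coordinates).  Used when no measured optode geometry is supplied; the
    pipeline only needs *some* per-channel 2-D position for map rendering."""
    n_outer = (n_channels + 1) // 2
    n_inner = n_channels - n_outer
    pts = []
    for k in range(n_outer):
        a = 2 * np.pi * k / n_outer
        pts.append((np.cos(a), np.sin(a)))
    for k in range(n_inner):
        a = 2 * np.pi * (k + 0.5) / max(n_inner, 1)
        pts.append((0.55 * np.cos(a), 0.55 * np.sin(a)))
    return np.asarray(pts, dtype=float)


@dataclass
class HemodynamicRecording:
    """One subject-run concentration time series.

    Parameters
    ----------
    subject_id, run_id : str
        Identifiers; runs are conventionally "1" and "2".
    sampling_rate_hz : float
        Acquisition rate.  Must exceed twice the upper analysis band edge.
    data : ndarray, shape (n_channels, n_samples)
        Concentration changes in µM.
    channel_layout : ndarray, shape (n_channels, 2), optional
    species : {"HbO", "HbR"}
    """

    subject_id: str
    run_id: str
    sampling_rate_hz: float
    data: np.ndarray
    channel_layout: np.ndarray | None = None
    species: str = "HbO"
    channel_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        if self.data.shape[0] < 2:
            raise ValueError("a recording needs at least 2 channels")
        if np.isnan(self.data).any():
            raise ValueError("recording contains missing values (NaN)")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.species not in VALID_SPECIES:
            raise ValueError(f"species must be one of {VALID_SPECIES}")
        if self.channel_layout is None:
            self.channel_layout = default_channel_layout(self.data.shape[0])
        else:
            self.channel_layout = np.asarray(self.channel_layout, dtype=float)
            if self.channel_layout.shape != (self.data.shape[0], 2):
                raise ValueError("channel_layout must be (n_channels, 2)")
        if not self.channel_ids:
            self.channel_ids = [f"CH{i + 1:02d}" for i in range(self.data.shape[0])]
        elif len(self.channel_ids) != self.data.shape[0]:
            raise ValueError("channel_ids length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def with_data(self, data: np.ndarray) -> "HemodynamicRecording":
        """Copy of this recording carrying new sample values (same metadata)."""
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class DurationWindow:
    """Prefix slice of a (denoised, filtered) recording.

    Windows are anchored at sample 0, so a shorter window is always a prefix
    of any longer one from the same recording — this is what "increasing
    scanning duration" means in the stability analysis.
    """

    recording: HemodynamicRecording
    duration_s: float

    def __post_init__(self) -> None:
        n = self.n_samples
        if n < 2:
            raise ValueError("window must contain at least 2 samples")
        if n > self.recording.n_samples:
            raise ValueError(
                f"window of {self.duration_s} s exceeds recording length "
                f"({self.recording.duration_s:.1f} s)"
            )

    @property
    def n_samples(self) -> int:
        n = self.duration_s * self.recording.sampling_rate_hz
        n_int = int(round(n))
        if abs(n - n_int) > 1e-9:
            raise ValueError("duration_s x sampling_rate_hz must be an integer sample count")
        return n_int

    @property
    def sampling_rate_hz(self) -> float:
        return self.recording.sampling_rate_hz

    @property
    def data(self) -> np.ndarray:
        return self.recording.data[:, : self.n_samples]
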