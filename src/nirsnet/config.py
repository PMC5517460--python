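"""Pipeline configuration: every tunable threshold in one structured object.

The defaults encode the standard resting-state fNIRS analysis design (band
0.01-0.1 Hz, sparsity grid 0.17..0.50 step 0.01, 30-s duration bins from 60
to 600 s, two runs) together with the package's documented choices (PCA
variance, ICA rejection thresholds, lag cap, ICC bands).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class FilterConfig:
    low_hz: float = 0.01
    high_hz: float = 0.1
    order: int = 3  # zero-phase Butterworth, applied forward-backward


@dataclass
class ICAConfig:
    variance_retained: float = 0.99  # PCA dimensionality criterion
    max_restarts: int = 5
    max_iter: int = 1500
    tol: float = 1e-3
    random_state: int = 0


@dataclass
class CriteriaConfig:
    """Noise-component rejection thresholds (temporal / spectral / spatial)."""

    # jump threshold sits above the null of ICA sources extracted from
    # artifact-free records (FastICA favours maximally non-Gaussian
    # projections, whose diff z reaches ~12 by chance over a 10-min record);
    # genuine discontinuities score ~20-110
    jump_z: float = 15.0
    ushape_r2: float = 0.8       # quadratic-trend R^2
    spike_z: float = 5.0         # robust z of detrended amplitude
    spike_rate_per_min: float = 2.0
    # spatial kurtosis = uncentered excess kurtosis of the mixing column;
    # constant-sign near-uniform (global) maps approach -2, Gaussian-dispersed
    # maps sit near 0, focal maps are large.  The threshold sits between the
    # empirical null of ICA columns on artifact-free records (> -1.6) and
    # near-uniform loading maps (~ -1.9).  Below the threshold => dispersive.
    spatial_kurtosis: float = -1.75


@dataclass
class ConnectivityConfig:
    max_lag_s: float = 20.0
    min_overlap_frac: float = 0.5


@dataclass
class ThresholdConfig:
    sparsity_min: float = 0.17
    sparsity_max: float = 0.50
    sparsity_step: float = 0.01
    edge_rounding: str = "round"  # round-half-away-from-zero | "floor"


@dataclass
class BinsConfig:
    min_s: float = 60.0
    max_s: float = 600.0
    step_s: float = 30.0


@dataclass
class ICCBands:
    """Qualitative reliability bands (Cicchetti-style cut-offs)."""

    fair: float = 0.4
    good: float = 0.6
    excellent: float = 0.75


@dataclass
class PipelineConfig:
    species: str = "HbO"
    denoise: bool = True
    trim_s: float = 0.0  # seconds discarded from the start before binning
    filter: FilterConfig = field(default_factory=FilterConfig)
    ica: ICAConfig = field(default_factory=ICAConfig)
    criteria: CriteriaConfig = field(default_factory=CriteriaConfig)
    connectivity: ConnectivityConfig = field(default_factory=ConnectivityConfig)
    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    bins: BinsConfig = field(default_factory=BinsConfig)
    icc_bands: ICCBands = field(default_factory=ICCBands)

    def validate(self) -> "PipelineConfig":
        if not (0 < self.filter.low_hz < self.filter.high_hz):
            raise ValueError("filter band must satisfy 0 < low < high")
        if not (0 < self.threshold.sparsity_min < self.threshold.sparsity_max < 1):
            raise ValueError("sparsity grid must lie within (0, 1)")
        if not (0 < self.ica.variance_retained <= 1):
            raise ValueError("variance_retained must be in (0, 1]")
        return self

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs: dict = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for key, val in d.items():
            if key not in fields:
                raise KeyError(f"unknown config key: {key!r}")
            ftype = fields[key].default_factory if fields[key].default_factory is not dataclasses.MISSING else None
            if ftype is not None and isinstance(val, dict):
                kwargs[key] = ftype().__class__(**val)
            else:
                kwargs[key] = val
        return cls(**kwargs).validate()

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def apply_overrides(self, pairs: list[str]) -> "PipelineConfig":
        """Apply ``section.key=value`` overrides (CLI ``--set`` mechanism)."""
        d = self.to_dict()
        for pair in pairs:
            if "=" not in pair:
                raise ValueError(f"override must be key=value, got {pair!r}")
            dotted, raw = pair.split("=", 1)
            node = d
            parts = dotted.split(".")
            for p in parts[:-1]:
                if p not in node:
                    raise KeyError(f"unknown config section {p!r} in {dotted!r}")
                node = node[p]
            leaf = parts[-1]
            if leaf not in node:
                raise KeyError(f"unknown config key {dotted!r}")
            node[leaf] = yaml.safe_load(raw)
        return self.from_dict(d)

    def sparsity_grid(self):
        """Strictly increasing sparsity values; default 0.17..0.50 -> 34 points."""
        import numpy as np

        t = self.threshold
        n = int(round((t.sparsity_max - t.sparsity_min) / t.sparsity_step)) + 1
        return np.round(t.sparsity_min + t.sparsity_step * np.arange(n), 10)

    def duration_grid(self):
        """Duration bins in seconds; default 60..600 step 30 -> 19 windows."""
        import numpy as np

        b = self.bins
        n = int(round((b.max_s - b.min_s) / b.step_s)) + 1
        return b.min_s + b.step_s * np.arange(n)
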