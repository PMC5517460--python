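"""Channel-pair functional connectivity for a duration window.

Two estimators:

* ``pearson_fc`` — zero-lag Pearson correlation of every channel pair;
* ``crosscorr_fc`` — maximum-over-lags cross-correlation: for each pair the
  Pearson correlation of the overlapping segments is recomputed at every lag
  d in [-L, +L] (means and variances taken on the overlap, which keeps every
  value a genuine correlation in [-1, 1]); the maximum over lags is the
  connectivity strength and its argmax the best lag.

The lag grid is symmetric (±L) so the resulting matrix is symmetric, as an
undirected graph analysis requires; ties are broken toward the smallest |d|,
negative before positive, making the estimate deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recording import DurationWindow

__all__ = ["ConnectivityMatrix", "pearson_fc", "crosscorr_fc"]


@dataclass
class ConnectivityMatrix:
    """Symmetric channel x channel FC estimate for one duration window."""

    values: np.ndarray
    method: str                      # "pearson" | "crosscorr"
    duration_s: float
    subject_id: str
    run_id: str
    best_lag: np.ndarray | None = None   # samples; antisymmetric (crosscorr only)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be a square matrix")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if np.nanmax(np.abs(v)) > 1 + 1e-12:
            raise ValueError("correlations must lie in [-1, 1]")
        self.values = v

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def _check_window(window: DurationWindow) -> np.ndarray:
    X = np.asarray(window.data, dtype=float)
    if X.shape[1] < 3:
        raise ValueError("window must contain at least 3 samples")
    sd = X.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        ids = [window.recording.channel_ids[i] for i in dead]
        raise ValueError(f"zero-variance channel(s) in window: {ids}")
    return X


def pearson_fc(window: DurationWindow) -> ConnectivityMatrix:
    """Sample Pearson correlation matrix over the window; unit diagonal."""
    X = _check_window(window)
    r = np.corrcoef(X)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    rec = window.recording
    return ConnectivityMatrix(
        values=r, method="pearson", duration_s=window.duration_s,
        subject_id=rec.subject_id, run_id=rec.run_id,
    )


def crosscorr_fc(
    window: DurationWindow,
    max_lag_s: float = 20.0,
    min_overlap_frac: float = 0.5,
) -> ConnectivityMatrix:
    """Maximum lagged cross-correlation over d in [-L, +L] samples.

    With L = 0 this reduces exactly to :func:`pearson_fc`.  Lags whose
    overlap would fall below ``min_overlap_frac`` of the window are skipped;
    if every lag is skipped the call fails.
    """
    X = _check_window(window)
    n, N = X.shape
    fs = window.sampling_rate_hz
    L = int(round(max_lag_s * fs))
    min_overlap = max(int(np.ceil(min_overlap_frac * N)), 3)

    cs = np.concatenate([np.zeros((n, 1)), np.cumsum(X, axis=1)], axis=1)
    cs2 = np.concatenate([np.zeros((n, 1)), np.cumsum(X ** 2, axis=1)], axis=1)

    best = np.full((n, n), -np.inf)
    best_lag = np.zeros((n, n), dtype=int)
    any_lag = False
    for d in range(L + 1):
        m = N - d
        if m < min_overlap:
            break
        any_lag = True
        if d == 0:
            # same computation as pearson_fc, so the L = 0 case reduces to it
            # exactly and crosscorr >= pearson holds with no rounding slack
            R = np.clip(np.corrcoef(X), -1.0, 1.0)
        else:
            A = X[:, d:]                       # x_i(t), t = d..N-1
            B = X[:, :m]                       # x_j(t - d)
            sum_a = cs[:, N] - cs[:, d]
            sum_b = cs[:, m]
            ss_a = cs2[:, N] - cs2[:, d]
            ss_b = cs2[:, m]
            S = A @ B.T
            cov = S - np.outer(sum_a, sum_b) / m
            var_a = np.maximum(ss_a - sum_a ** 2 / m, 0.0)
            var_b = np.maximum(ss_b - sum_b ** 2 / m, 0.0)
            denom = np.sqrt(np.outer(var_a, var_b))
            with np.errstate(invalid="ignore", divide="ignore"):
                R = np.where(denom > 0, cov / denom, -np.inf)
            R = np.clip(R, -1.0, 1.0, out=R, where=np.isfinite(R))
        # r_ij(+d) = R[i, j]; r_ij(-d) = r_ji(+d) = R[j, i].
        # Process -d before +d so equal-value ties keep the negative lag;
        # strict '>' keeps the smallest |d| seen first.
        for lag_sign, cand in (((-1), R.T), ((+1), R)):
            if d == 0 and lag_sign == -1:
                continue
            better = cand > best
            best = np.where(better, cand, best)
            best_lag = np.where(better, lag_sign * d, best_lag)
    if not any_lag:
        raise ValueError(
            f"no lag satisfies min_overlap_frac={min_overlap_frac} for a "
            f"{N}-sample window")
    # max over the symmetric lag set is symmetric by construction; enforce
    # exact symmetry against floating-point asymmetry in the matmuls.
    values = (best + best.T) / 2.0
    np.fill_diagonal(values, 1.0)
    lag = np.triu(best_lag, 1)
    best_lag = lag - lag.T
    rec = window.recording
    return ConnectivityMatrix(
        values=values, method="crosscorr", duration_s=window.duration_s,
        subject_id=rec.subject_id, run_id=rec.run_id, best_lag=best_lag,
    )
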