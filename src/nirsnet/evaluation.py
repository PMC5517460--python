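"""Stability, between-run reproducibility and test-retest reliability of
duration-binned connectomes.

Three questions, answered per duration bin:

* **Stability** — how similar are FC / nodal-metric maps computed from a short
  prefix window to those from the full 10-min record?  (Pearson r of the
  vectorized maps, per subject, summarized as group mean ± sd; paired t-tests
  on global-metric AUCs, short vs reference.)
* **Reproducibility** — how similar are a subject's maps across the two
  scanning runs?  (Per-subject map correlation; for global AUCs a single
  across-subject correlation.)
* **Reliability** — one-way random-effects intraclass correlation
  ICC = (MS_b - MS_w) / (MS_b + (k-1) MS_w) of each measure across runs.

`run_duration_sweep` orchestrates the full design (19 durations x 2 FC
methods x {binary, weighted}); `DurationStabilityAnalysis` wraps it in a
model-like fit()/results interface with a summary table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .connectivity import crosscorr_fc, pearson_fc
from .metrics import metric_auc, network_profile
from .preprocess import preprocess_recording, truncate_bins
from .synthetic import Cohort

__all__ = [
    "vectorize_map",
    "devectorize_map",
    "stability_correlation",
    "stability_ttest",
    "between_run_correlation",
    "icc",
    "classify_icc",
    "run_duration_sweep",
    "DurationSweepResult",
    "DurationStabilityAnalysis",
]

GLOBAL_METRICS = ("clustering_coefficient", "global_efficiency", "local_efficiency")
NODAL_METRICS = ("nodal_efficiency", "nodal_betweenness")


# ---------------------------------------------------------------------------
# map vectorization
# ---------------------------------------------------------------------------


def vectorize_map(m: np.ndarray) -> np.ndarray:
    """Flatten a symmetric matrix to its upper triangle (i < j, lexicographic)
    or pass a nodal vector through unchanged."""
    m = np.asarray(m, dtype=float)
    if m.ndim == 1:
        return m.copy()
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("input must be a square matrix or 1-D vector")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    iu, ju = np.triu_indices(m.shape[0], 1)
    return m[iu, ju]


def devectorize_map(v: np.ndarray, n: int, diag: float = 1.0) -> np.ndarray:
    """Inverse of :func:`vectorize_map` for matrices (round trip)."""
    v = np.asarray(v, dtype=float)
    if v.size != n * (n - 1) // 2:
        raise ValueError(f"vector length {v.size} does not match n={n}")
    m = np.full((n, n), diag)
    iu, ju = np.triu_indices(n, 1)
    m[iu, ju] = v
    m[ju, iu] = v
    return m


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------


def stability_correlation(short_map: np.ndarray, reference_map: np.ndarray):
    """Pearson r (with two-sided p) between a short-duration map and the
    10-min reference map."""
    a = np.asarray(short_map, dtype=float).ravel()
    b = np.asarray(reference_map, dtype=float).ravel()
    if a.size != b.size or a.size < 3:
        raise ValueError("maps must have equal length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance map; correlation undefined")
    if np.array_equal(a, b):
        return 1.0, 0.0   # self-comparison (the 600-s bin) is exact
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def stability_ttest(short_values: np.ndarray, ref_values: np.ndarray):
    """Paired two-sided t-test of per-subject AUCs, short vs reference.

    Degenerate cases: identical arrays give (0, 1); a constant nonzero shift
    with zero spread gives (±inf, 0).
    """
    a = np.asarray(short_values, dtype=float)
    b = np.asarray(ref_values, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("paired samples of equal size >= 3 required")
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0
    if d.std(ddof=1) == 0:
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def between_run_correlation(run1_maps, run2_maps, level: str = "per_subject"):
    """Between-run similarity.

    ``per_subject``: one r per subject from that subject's two map vectors;
    returns (r array, mean, sd).  ``across_subjects``: a single r across the
    subject-indexed scalar pairs; returns (r, p).
    """
    if level == "per_subject":
        if len(run1_maps) != len(run2_maps):
            raise ValueError("matched subject lists required")
        rs = np.array([stability_correlation(a, b)[0]
                       for a, b in zip(run1_maps, run2_maps)])
        return rs, float(rs.mean()), float(rs.std(ddof=1)) if rs.size > 1 else 0.0
    if level == "across_subjects":
        a = np.asarray(run1_maps, dtype=float)
        b = np.asarray(run2_maps, dtype=float)
        if a.size != b.size or a.size < 3:
            raise ValueError("across_subjects mode needs >= 3 subjects")
        r, p = stability_correlation(a, b)
        return float(r), float(p)
    raise ValueError("level must be 'per_subject' or 'across_subjects'")


def icc(measurements: np.ndarray) -> float:
    """One-way random-effects intraclass correlation across k repeated runs.

    MS_b from the between-subject sum of squares (df n-1), MS_w from the
    within-subject sum of squares (df n(k-1));
    ICC = (MS_b - MS_w) / (MS_b + (k-1) MS_w).  May be negative; if all
    values are identical the ratio is 0/0 and 0 is returned with a warning.
    """
    X = np.asarray(measurements, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 2:
        raise ValueError("need a subjects x k matrix with k >= 2, subjects >= 2")
    if np.isnan(X).any():
        raise ValueError("missing cells not allowed")
    n, k = X.shape
    row_means = X.mean(axis=1)
    grand = X.mean()
    ms_b = k * np.sum((row_means - grand) ** 2) / (n - 1)
    ms_w = np.sum((X - row_means[:, None]) ** 2) / (n * (k - 1))
    denom = ms_b + (k - 1) * ms_w
    if denom == 0:
        warnings.warn("all measurements identical; ICC undefined, returning 0")
        return 0.0
    return float((ms_b - ms_w) / denom)


def icc_columns(X: np.ndarray) -> np.ndarray:
    """Vectorized one-way ICC over the last axis pairs: X has shape
    (n_subjects, k, n_features); returns ICC per feature."""
    n, k, _ = X.shape
    row_means = X.mean(axis=1)
    grand = X.mean(axis=(0, 1))
    ms_b = k * np.sum((row_means - grand) ** 2, axis=0) / (n - 1)
    ms_w = np.sum((X - row_means[:, None, :]) ** 2, axis=(0, 1)) / (n * (k - 1))
    denom = ms_b + (k - 1) * ms_w
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (ms_b - ms_w) / np.where(denom > 0, denom, 1.0), 0.0)
    return out


def classify_icc(value: float, bands=None) -> str:
    """Qualitative reliability band: low < 0.4 <= fair < 0.6 <= good < 0.75
    <= excellent (cut-offs config-overridable)."""
    from .config import ICCBands

    b = bands or ICCBands()
    if value < b.fair:
        return "low"
    if value < b.good:
        return "fair"
    if value < b.excellent:
        return "good"
    return "excellent"


# ---------------------------------------------------------------------------
# the duration sweep
# ---------------------------------------------------------------------------


def _fc_for_window(window, method: str, config: PipelineConfig):
    if method == "pearson":
        return pearson_fc(window)
    if method == "crosscorr":
        return crosscorr_fc(
            window,
            max_lag_s=config.connectivity.max_lag_s,
            min_overlap_frac=config.connectivity.min_overlap_frac,
        )
    raise ValueError(f"unknown FC method {method!r}")


@dataclass
class DurationSweepResult:
    """Long-format stability and reliability tables for a cohort sweep."""

    stability: pd.DataFrame
    reliability: pd.DataFrame
    config: PipelineConfig
    durations_s: np.ndarray
    methods: tuple = ("pearson", "crosscorr")
    modes: tuple = ("binary", "weighted")

    def summary(self) -> pd.DataFrame:
        """Compact per-(method, mode, metric) table: shortest duration whose
        stability r >= 0.9 and the 600-s ICC with its qualitative band."""
        rows = []
        ref = float(self.durations_s.max())
        for (method, mode, metric), g in self.stability.groupby(
                ["method", "mode", "metric"]):
            gm = g[g.statistic == "stability_r_mean"].sort_values("duration_s")
            stable_at = np.nan
            if len(gm):
                ok = gm[gm.value >= 0.9]
                stable_at = float(ok.duration_s.min()) if len(ok) else np.nan
            rel = self.reliability
            sel = rel[(rel["method"] == method) & (rel["mode"] == mode)
                      & (rel["metric"] == metric) & (rel["duration_s"] == ref)
                      & (rel["statistic"] == "icc")]
            icc_ref = float(sel.value.iloc[0]) if len(sel) else np.nan
            rows.append({
                "method": method, "mode": mode, "metric": metric,
                "stable_from_s": stable_at,
                "icc_at_reference": icc_ref,
                "icc_band": classify_icc(icc_ref) if np.isfinite(icc_ref) else "n/a",
            })
        return pd.DataFrame(rows)


def run_duration_sweep(
    cohort: Cohort,
    config: PipelineConfig | None = None,
    methods: tuple = ("pearson", "crosscorr"),
    modes: tuple = ("binary", "weighted"),
    progress: bool = False,
) -> DurationSweepResult:
    """Full design: preprocess every recording, estimate FC in every duration
    bin with every method, compute graph-metric profiles in both network
    modes, then assemble stability (vs the longest bin) and reliability
    (between the two runs) tables.

    Deterministic given the cohort and config; every random element upstream
    is fixed by the cohort's seed and the ICA seed in the config.
    """
    config = (config or PipelineConfig()).validate()
    spec = cohort.spec
    durations = config.duration_grid()
    grid = config.sparsity_grid()
    n_dur = len(durations)
    ref_idx = n_dur - 1
    subjects = range(spec.n_subjects)
    runs = range(spec.n_runs)

    # fc_vec[method][(s, r)] : n_dur x n_edgevec
    fc_vec: dict = {m: {} for m in methods}
    profiles: dict = {(m, mo): {} for m in methods for mo in modes}

    for s in subjects:
        for r in runs:
            rec = preprocess_recording(cohort.recordings[(s, r)], config)
            try:
                windows = truncate_bins(
                    rec, config.bins.min_s, config.bins.max_s, config.bins.step_s)
            except ValueError as err:
                raise ValueError(
                    f"subject {s} run {r}: {err}") from err
            for method in methods:
                vecs, profs = [], {mo: [] for mo in modes}
                for w in windows:
                    try:
                        fc = _fc_for_window(w, method, config)
                    except ValueError as err:
                        raise ValueError(
                            f"subject {s} run {r} duration {w.duration_s:.0f}s: "
                            f"{err}") from err
                    vecs.append(vectorize_map(fc.values))
                    for mo in modes:
                        profs[mo].append(network_profile(
                            fc, grid, mode=mo,
                            rounding=config.threshold.edge_rounding))
                fc_vec[method][(s, r)] = np.asarray(vecs)
                for mo in modes:
                    profiles[(method, mo)][(s, r)] = profs[mo]
            if progress:
                print(f"processed subject {s + 1}/{spec.n_subjects} run {r + 1}")

    stab_rows: list = []
    rel_rows: list = []

    def add_stab(**kw):
        stab_rows.append(kw)

    def add_rel(**kw):
        rel_rows.append(kw)

    for method in methods:
        # ---- FC stability (mode-independent) -----------------------------
        for d_idx, dur in enumerate(durations):
            for mo in modes:
                rs = np.array([
                    stability_correlation(
                        fc_vec[method][(s, 0)][d_idx],
                        fc_vec[method][(s, 0)][ref_idx])[0]
                    for s in subjects
                ])
                add_stab(metric="fc", method=method, mode=mo, duration_s=float(dur),
                         statistic="stability_r_mean", value=float(rs.mean()),
                         group_sd=float(rs.std(ddof=1)) if rs.size > 1 else 0.0,
                         p=np.nan)
        # ---- FC reproducibility / reliability ----------------------------
        if spec.n_runs >= 2:
            for d_idx, dur in enumerate(durations):
                rs = np.array([
                    stability_correlation(
                        fc_vec[method][(s, 0)][d_idx],
                        fc_vec[method][(s, 1)][d_idx])[0]
                    for s in subjects
                ])
                edge_stack = np.stack([
                    np.stack([fc_vec[method][(s, r)][d_idx] for r in (0, 1)])
                    for s in subjects
                ])  # subjects x 2 x edges
                icc_edges = icc_columns(edge_stack)
                for mo in modes:
                    add_rel(metric="fc", method=method, mode=mo,
                            duration_s=float(dur), statistic="between_run_r_mean",
                            value=float(rs.mean()),
                            group_sd=float(rs.std(ddof=1)) if rs.size > 1 else 0.0,
                            p=np.nan)
                    add_rel(metric="fc", method=method, mode=mo,
                            duration_s=float(dur), statistic="icc",
                            value=float(icc_edges.mean()), group_sd=np.nan, p=np.nan)

        for mo in modes:
            prof = profiles[(method, mo)]
            # nodal metrics: AUC maps, per subject
            for metric in NODAL_METRICS:
                maps = {
                    (s, r): np.asarray(
                        [prof[(s, r)][d][f"{metric}_auc"] for d in range(n_dur)])
                    for s in subjects for r in runs
                }  # each: n_dur x n_nodes
                for d_idx, dur in enumerate(durations):
                    rs = np.array([
                        stability_correlation(
                            maps[(s, 0)][d_idx], maps[(s, 0)][ref_idx])[0]
                        for s in subjects
                    ])
                    add_stab(metric=metric, method=method, mode=mo,
                             duration_s=float(dur), statistic="stability_r_mean",
                             value=float(rs.mean()),
                             group_sd=float(rs.std(ddof=1)) if rs.size > 1 else 0.0,
                             p=np.nan)
                if spec.n_runs >= 2:
                    for d_idx, dur in enumerate(durations):
                        rs = np.array([
                            stability_correlation(
                                maps[(s, 0)][d_idx], maps[(s, 1)][d_idx])[0]
                            for s in subjects
                        ])
                        node_stack = np.stack([
                            np.stack([maps[(s, r)][d_idx] for r in (0, 1)])
                            for s in subjects
                        ])
                        icc_nodes = icc_columns(node_stack)
                        add_rel(metric=metric, method=method, mode=mo,
                                duration_s=float(dur),
                                statistic="between_run_r_mean",
                                value=float(rs.mean()),
                                group_sd=float(rs.std(ddof=1)) if rs.size > 1 else 0.0,
                                p=np.nan)
                        add_rel(metric=metric, method=method, mode=mo,
                                duration_s=float(dur), statistic="icc",
                                value=float(icc_nodes.mean()), group_sd=np.nan,
                                p=np.nan)
            # global metrics: AUC scalars
            for metric in GLOBAL_METRICS:
                aucs = {
                    (s, r): np.asarray(
                        [prof[(s, r)][d][f"{metric}_auc"] for d in range(n_dur)])
                    for s in subjects for r in runs
                }  # each: n_dur
                for d_idx, dur in enumerate(durations):
                    short = np.array([aucs[(s, 0)][d_idx] for s in subjects])
                    ref = np.array([aucs[(s, 0)][ref_idx] for s in subjects])
                    if short.size >= 3:
                        t, p = stability_ttest(short, ref)
                    else:  # paired t needs >= 3 subjects
                        t, p = np.nan, np.nan
                    add_stab(metric=metric, method=method, mode=mo,
                             duration_s=float(dur), statistic="paired_t",
                             value=t, group_sd=np.nan, p=p)
                if spec.n_runs >= 2:
                    for d_idx, dur in enumerate(durations):
                        a = np.array([aucs[(s, 0)][d_idx] for s in subjects])
                        b = np.array([aucs[(s, 1)][d_idx] for s in subjects])
                        if a.size >= 3 and a.std() > 0 and b.std() > 0:
                            r_ab, p_ab = between_run_correlation(
                                a, b, level="across_subjects")
                        else:
                            r_ab, p_ab = np.nan, np.nan
                        add_rel(metric=metric, method=method, mode=mo,
                                duration_s=float(dur),
                                statistic="between_run_r_across_subjects",
                                value=r_ab, group_sd=np.nan, p=p_ab)
                        add_rel(metric=metric, method=method, mode=mo,
                                duration_s=float(dur), statistic="icc",
                                value=icc(np.stack([a, b], axis=1)),
                                group_sd=np.nan, p=np.nan)

    stability = pd.DataFrame(stab_rows)
    reliability = pd.DataFrame(rel_rows)
    return DurationSweepResult(
        stability=stability, reliability=reliability, config=config,
        durations_s=durations, methods=tuple(methods), modes=tuple(modes),
    )


# ---------------------------------------------------------------------------
# model-style facade
# ---------------------------------------------------------------------------


@dataclass
class DurationStabilityAnalysis:
    """Model-like front end: construct from a cohort (and optional config),
    call :meth:`fit`, inspect the returned :class:`DurationSweepResult`.

    >>> res = DurationStabilityAnalysis(cohort).fit()
    >>> res.summary()
    """

    cohort: Cohort
    config: PipelineConfig = field(default_factory=PipelineConfig)
    methods: tuple = ("pearson", "crosscorr")
    modes: tuple = ("binary", "weighted")

    def fit(self, progress: bool = False) -> DurationSweepResult:
        return run_duration_sweep(
            self.cohort, self.config, methods=self.methods, modes=self.modes,
            progress=progress)
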