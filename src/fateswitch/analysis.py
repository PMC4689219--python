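"""Single-cell measurement analytics.

The measurement side of the pipeline: ROC analysis asking how well a
fluorescence readout separates cells by their eventual fate (AUC, Youden's
J optimal threshold, bootstrap uncertainties, per-frame timecourses),
prediction accuracy, hierarchical clustering of expression traces, and
smoothed-histogram peak detection for flow-cytometry-like intensity samples.

Classification polarity is fixed: high exogenous-GATA reporter predicts the
GATA-high (PrE) outcome, so a cell is called positive iff its value is
``>= threshold``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.signal import find_peaks, peak_prominences
from scipy.stats import gaussian_kde

__all__ = [
    "LabeledSample",
    "ROCFrame",
    "ROCTimecourse",
    "PeakSet",
    "roc_frame",
    "optimal_threshold",
    "roc_timecourse",
    "prediction_accuracy",
    "cluster_traces",
    "histogram_peaks",
    "peak_fold_change",
    "cumulative_exposure",
    "UndefinedROCError",
]


class UndefinedROCError(ValueError):
    """Raised when a ROC quantity is requested with one class empty."""


@dataclass(frozen=True)
class LabeledSample:
    """Intensity values paired with binary end-point fate labels
    (1 = GATA/PrE outcome)."""

    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values",
                           np.asarray(self.values, dtype=float))
        object.__setattr__(self, "labels",
                           np.asarray(self.labels, dtype=int))
        if self.values.shape != self.labels.shape or self.values.ndim != 1:
            raise ValueError("values and labels must be parallel 1-D arrays")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")

    def require_both_classes(self) -> None:
        if self.labels.sum() == 0 or self.labels.sum() == self.labels.size:
            raise UndefinedROCError(
                "ROC undefined: need at least one positive and one negative")


@dataclass
class ROCFrame:
    """ROC curve at a single timepoint/sample."""

    thresholds: np.ndarray  # descending candidate cutoffs, +/-inf sentinels
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    optimal_threshold: float
    J: float  # maximised TPR - FPR (Youden)


@dataclass
class ROCTimecourse:
    """Per-frame ROC summaries with bootstrap standard deviations."""

    times: np.ndarray
    auc_t: np.ndarray
    threshold_t: np.ndarray
    auc_sd_t: np.ndarray
    threshold_sd_t: np.ndarray
    n_boot: int
    flagged_frames: np.ndarray  # frames where bootstrap had to give up


@dataclass
class PeakSet:
    """Ordered local maxima of a kernel-smoothed intensity histogram."""

    positions: np.ndarray    # strictly increasing [a.u.]
    prominences: np.ndarray
    bandwidth: float

    def __len__(self) -> int:
        return len(self.positions)


def _candidate_thresholds(values: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct sorted values, plus +/-inf
    sentinels, in descending order."""
    distinct = np.unique(values)
    mids = 0.5 * (distinct[:-1] + distinct[1:])
    return np.concatenate([[np.inf], mids[::-1], [-np.inf]])


def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as the Mann-Whitney pair statistic, ties counting one half."""
    from scipy.stats import rankdata

    combined = np.concatenate([pos, neg])
    ranks = rankdata(combined)
    r_pos = ranks[:pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def roc_frame(sample: LabeledSample) -> ROCFrame:
    """Full ROC curve for one labelled sample.

    Thresholds are the midpoints between consecutive distinct values with
    ±inf sentinels; a cell is predicted positive iff ``value >= threshold``.
    The AUC equals the Mann-Whitney pair statistic (ties count one half),
    and the optimal threshold maximises Youden's J = TPR − FPR, ties broken
    towards the largest threshold (the most conservative call).
    """
    sample.require_both_classes()
    v, y = sample.values, sample.labels
    pos, neg = np.sort(v[y == 1]), np.sort(v[y == 0])
    thresholds = _candidate_thresholds(v)
    # predictions for descending thresholds: value >= threshold
    # (vectorised via sorted-count lookup)
    tpr = 1.0 - np.searchsorted(pos, thresholds, side="left") / pos.size
    fpr = 1.0 - np.searchsorted(neg, thresholds, side="left") / neg.size
    auc = _mann_whitney_auc(pos, neg)
    j_vals = tpr - fpr
    best = int(np.argmax(j_vals))  # argmax returns FIRST max = largest thr
    return ROCFrame(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc,
                    optimal_threshold=float(thresholds[best]),
                    J=float(j_vals[best]))


def optimal_threshold(sample: LabeledSample) -> tuple[float, float]:
    """The Youden-optimal cutoff and its J value."""
    frame = roc_frame(sample)
    return frame.optimal_threshold, frame.J


def cumulative_exposure(trace_matrix: np.ndarray,
                        times: np.ndarray) -> np.ndarray:
    """Per-frame cumulative time-integral of each trace (trapezoidal).

    An alternative classifier series: total reporter exposure up to each
    frame rather than the instantaneous level.
    """
    trace_matrix = np.asarray(trace_matrix, dtype=float)
    times = np.asarray(times, dtype=float)
    dt = np.diff(times)
    seg = 0.5 * (trace_matrix[:, :-1] + trace_matrix[:, 1:]) * dt
    out = np.zeros_like(trace_matrix)
    out[:, 1:] = np.cumsum(seg, axis=1)
    return out


def roc_timecourse(trace_matrix: np.ndarray, labels: Sequence[int],
                   times: np.ndarray | None = None, n_boot: int = 1000,
                   seed: int | None = None) -> ROCTimecourse:
    """Per-frame ROC analysis of a (cells × frames) value matrix.

    The bootstrap resamples whole cells with replacement (frames within a
    cell are dependent), ``n_boot`` times; replicates that lose one class
    entirely are redrawn (up to 100 attempts, then the frame set is
    flagged).  Deterministic given ``seed``.
    """
    trace_matrix = np.asarray(trace_matrix, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_cells, n_frames = trace_matrix.shape
    if labels.size != n_cells:
        raise ValueError("labels must have one entry per cell")
    if (labels == 1).sum() < 2 or (labels == 0).sum() < 2:
        raise UndefinedROCError("need at least two cells per class")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if times is None:
        times = np.arange(n_frames, dtype=float)
    times = np.asarray(times, dtype=float)

    auc_t = np.empty(n_frames)
    thr_t = np.empty(n_frames)
    for f in range(n_frames):
        frame = roc_frame(LabeledSample(trace_matrix[:, f], labels))
        auc_t[f] = frame.auc
        thr_t[f] = frame.optimal_threshold

    rng = np.random.default_rng(seed)
    boot_auc = np.empty((n_boot, n_frames))
    boot_thr = np.empty((n_boot, n_frames))
    flagged = np.zeros(n_frames, dtype=bool)
    for b in range(n_boot):
        for attempt in range(100):
            idx = rng.integers(0, n_cells, size=n_cells)
            lab = labels[idx]
            if 0 < lab.sum() < n_cells:
                break
        else:
            flagged[:] = True
            boot_auc[b] = np.nan
            boot_thr[b] = np.nan
            continue
        sub = trace_matrix[idx]
        for f in range(n_frames):
            fr = roc_frame(LabeledSample(sub[:, f], lab))
            boot_auc[b, f] = fr.auc
            boot_thr[b, f] = fr.optimal_threshold
    finite_thr = np.where(np.isfinite(boot_thr), boot_thr, np.nan)
    return ROCTimecourse(times=times, auc_t=auc_t, threshold_t=thr_t,
                         auc_sd_t=np.nanstd(boot_auc, axis=0),
                         threshold_sd_t=np.nanstd(finite_thr, axis=0),
                         n_boot=n_boot, flagged_frames=flagged)


def prediction_accuracy(trace_matrix: np.ndarray, labels: Sequence[int],
                        thresholds: Sequence[float], frame: int) -> float:
    """Fraction of cells whose fate is correctly called at ``frame`` by the
    rule ``value >= thresholds[frame]``."""
    trace_matrix = np.asarray(trace_matrix, dtype=float)
    labels = np.asarray(labels, dtype=int)
    thresholds = np.asarray(thresholds, dtype=float)
    if not (0 <= frame < trace_matrix.shape[1]):
        raise IndexError(f"frame {frame} out of range")
    if thresholds.size != trace_matrix.shape[1]:
        raise ValueError("need one threshold per frame")
    pred = (trace_matrix[:, frame] >= thresholds[frame]).astype(int)
    return float((pred == labels).mean())


def cluster_traces(trace_matrix: np.ndarray, k: int,
                   log_transform: bool = True,
                   log_floor: float = 1e-6) -> np.ndarray:
    """Agglomerative (Ward, Euclidean) clustering of expression traces.

    Traces are log-transformed by default (multiplicative noise becomes
    additive); the dendrogram is cut at ``k`` clusters and labels 0..k-1
    are ordered by descending cluster-mean final value.
    """
    X = np.asarray(trace_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("trace_matrix must be 2-D (cells x frames)")
    n_cells = X.shape[0]
    if not 1 <= k <= n_cells:
        raise ValueError(f"k must be in [1, {n_cells}]")
    if np.isnan(X).any():
        raise ValueError("missing frames must be interpolated before "
                         "clustering")
    feats = np.log(np.clip(X, log_floor, None)) if log_transform else X
    if k == 1:
        return np.zeros(n_cells, dtype=int)
    Z = linkage(feats, method="ward", metric="euclidean")
    raw = fcluster(Z, t=k, criterion="maxclust")
    # order cluster ids by descending mean final value
    finals = X[:, -1]
    order = sorted(np.unique(raw),
                   key=lambda c: -finals[raw == c].mean())
    remap = {c: i for i, c in enumerate(order)}
    return np.array([remap[c] for c in raw], dtype=int)


def histogram_peaks(values: Sequence[float], bandwidth=None,
                    grid_size: int = 512,
                    min_prominence_frac: float = 0.05) -> PeakSet:
    """Local maxima of a Gaussian-kernel-smoothed intensity histogram.

    The density is evaluated on a ``grid_size``-point grid spanning the
    data (padded by three bandwidths); maxima with prominence below
    ``min_prominence_frac`` of the global maximum are discarded.
    ``bandwidth`` follows Silverman's rule when not given; a numeric value
    is interpreted on the data scale.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError("need at least 10 values for peak detection")
    if np.ptp(values) == 0:
        # degenerate: all mass at one point
        return PeakSet(positions=np.array([values[0]]),
                       prominences=np.array([1.0]), bandwidth=0.0)
    if bandwidth is None or bandwidth == "silverman":
        kde = gaussian_kde(values, bw_method="silverman")
    else:
        kde = gaussian_kde(values,
                           bw_method=float(bandwidth) / values.std(ddof=1))
    bw = float(kde.factor * values.std(ddof=1))
    # pad by three bandwidths so densities decay before the grid ends and
    # edge peaks keep their full prominence
    lo, hi = values.min() - 3 * bw, values.max() + 3 * bw
    grid = np.linspace(lo, hi, grid_size)
    dens = kde(grid)
    idx, _ = find_peaks(dens)
    # interior maxima plus possible boundary maxima
    if dens[0] > dens[1]:
        idx = np.concatenate([[0], idx])
    if dens[-1] > dens[-2]:
        idx = np.concatenate([idx, [grid_size - 1]])
    idx = np.sort(idx).astype(int)
    if idx.size == 0:
        idx = np.array([int(np.argmax(dens))])
    proms = peak_prominences(dens, idx[(idx > 0) & (idx < grid_size - 1)])[0]
    # boundary peaks get prominence = height above global minimum
    prom_map = {}
    interior = idx[(idx > 0) & (idx < grid_size - 1)]
    for i, pr in zip(interior, proms):
        prom_map[int(i)] = float(pr)
    for i in idx:
        if int(i) not in prom_map:
            prom_map[int(i)] = float(dens[i] - dens.min())
    keep = [i for i in idx
            if prom_map[int(i)] >= min_prominence_frac * dens.max()]
    if not keep:
        keep = [int(np.argmax(dens))]
    keep = np.sort(np.asarray(keep, dtype=int))
    return PeakSet(positions=grid[keep],
                   prominences=np.array([prom_map[int(i)] for i in keep]),
                   bandwidth=bw)


def peak_fold_change(values: Sequence[float], bandwidth=None) -> float:
    """Position of the highest-position histogram peak divided by that of
    the lowest — e.g. the positive-to-negative peak intensity ratio of a
    bimodal flow-cytometry distribution."""
    peaks = histogram_peaks(values, bandwidth=bandwidth)
    if len(peaks) < 2:
        raise ValueError("distribution is unimodal; fold change undefined")
    low, high = peaks.positions[0], peaks.positions[-1]
    if low <= 0:
        raise ValueError("non-positive peak position; fold change requires "
                         "positive intensities")
    return float(high / low)
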