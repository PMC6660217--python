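"""Volumetric calcium-imaging statistics pipeline.

From raw trial volumes (T x Z x Y x X fluorescence) to per-odor response
images and the spatial statistics computed on them: mean z-projection,
dF/F against a pre-stimulus baseline, Gaussian smoothing, peak-window
response images, trial averaging, masked spatial PCA, per-pixel coefficient
of variation across odors, odor-pair correlation and correlation-distance
clustering, cross-population distance regression, and paired before/after
comparisons.

Sign convention: inhibition is negative dF/F; peak detection uses the
absolute ROI-mean deflection so inhibitory and excitatory responses are
both found.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy
import scipy.ndimage
import scipy.spatial.distance
import scipy.stats

__all__ = [
    "TrialVolumeSeries",
    "ResponseImage",
    "PCAResult",
    "DistanceMatrix",
    "LinkageTree",
    "zproject",
    "dff",
    "smooth",
    "peak_response",
    "average_trials",
    "responses_from_trials",
    "pca_responses",
    "pixel_cv",
    "correlation_matrix",
    "linkage_distances",
    "normalize_distances",
    "distance_regression",
    "paired_comparison",
]

logger = logging.getLogger(__name__)


@dataclass
class TrialVolumeSeries:
    """One imaging trial: T volumes of Z frames of Y x X pixels.

    Timing metadata: ``volume_rate`` in volumes/s, baseline = first
    ``baseline_s`` seconds, odor on at ``odor_onset`` s for
    ``odor_duration`` s.
    """

    data: np.ndarray
    volume_rate: float = 6.5
    baseline_s: float = 2.0
    odor_onset: float = 2.0
    odor_duration: float = 1.0
    odor_label: str = ""
    trial_index: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be T x Z x Y x X")
        if np.any(self.data < 0):
            raise ValueError("fluorescence values must be >= 0")
        if self.n_baseline_volumes < 1:
            raise ValueError("trial shorter than the baseline window")

    @property
    def n_baseline_volumes(self) -> int:
        return int(round(self.baseline_s * self.volume_rate))


@dataclass
class ResponseImage:
    """Per-odor 2-D dF/F map (the unit of all spatial statistics)."""

    dff: np.ndarray
    odor_label: str = ""
    n_trials: int = 1
    peak_window: tuple | None = None  # (first, last) volume index, inclusive

    def __post_init__(self):
        self.dff = np.asarray(self.dff, dtype=float)
        if self.dff.ndim != 2:
            raise ValueError("response image must be 2-D")


@dataclass
class PCAResult:
    """Masked spatial PCA of the odor-response set.

    ``component_images[k]`` is the k-th pixel-score image (off-mask pixels
    zero); ``variance_explained`` the fraction of variance per component.
    """

    component_images: list
    variance_explained: np.ndarray


@dataclass
class DistanceMatrix:
    labels: list
    D: np.ndarray

    def condensed(self) -> np.ndarray:
        """Unique pairwise distances (upper triangle, scipy condensed order)."""
        return scipy.spatial.distance.squareform(self.D, checks=False)


@dataclass
class LinkageTree:
    merges: np.ndarray  # scipy linkage matrix
    method: str


# -- frame-level operations ------------------------------------------------


def zproject(trial: TrialVolumeSeries) -> np.ndarray:
    """Mean z-projection per volume: (T, Z, Y, X) -> (T, Y, X)."""
    return trial.data.mean(axis=1)


def dff(frames: np.ndarray, baseline_volumes: int) -> np.ndarray:
    """Per-pixel (F - F0) / F0 with F0 the mean over the baseline volumes.

    Pixels whose baseline is <= 0 are set to NaN, counted and logged.
    """
    frames = np.asarray(frames, dtype=float)
    if baseline_volumes < 1:
        raise ValueError("baseline window must be non-empty")
    f0 = frames[:baseline_volumes].mean(axis=0)
    bad = f0 <= 0
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("dff: %d pixel(s) with non-positive baseline masked", n_bad)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (frames - f0) / f0
    out[:, bad] = np.nan
    return out


def gaussian_kernel(size: int = 4, sigma: float = 1.0) -> np.ndarray:
    """Unit-sum 2-D Gaussian kernel of the given pixel size.

    Even sizes place the grid symmetrically around the center (offsets
    -1.5..1.5 for size 4).
    """
    offsets = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(offsets**2) / (2.0 * sigma**2))
    kernel = np.outer(g, g)
    return kernel / kernel.sum()


def smooth(series: np.ndarray, kernel_size: int = 4, sigma: float = 1.0) -> np.ndarray:
    """2-D Gaussian low-pass per frame, reflective boundary.

    Accepts a (T, Y, X) series or a single (Y, X) frame.
    """
    series = np.asarray(series, dtype=float)
    kernel = gaussian_kernel(kernel_size, sigma)
    single = series.ndim == 2
    frames = series[None] if single else series
    if kernel.shape[0] >= frames.shape[1] or kernel.shape[1] >= frames.shape[2]:
        raise ValueError("kernel must be smaller than the image")
    out = np.empty_like(frames)
    for t in range(frames.shape[0]):
        out[t] = scipy.ndimage.convolve(frames[t], kernel, mode="reflect")
    return out[0] if single else out


def peak_response(
    dff_series: np.ndarray,
    roi: np.ndarray,
    volume_rate: float = 6.5,
    odor_onset: float = 2.0,
    odor_duration: float = 1.0,
    search_tail_s: float = 3.0,
    peak_window: tuple | None = None,
    odor_label: str = "",
) -> ResponseImage:
    """Response image: mean of 3 consecutive volumes centered on the peak.

    The peak volume is the extremum of the absolute ROI-mean dF/F within
    the window from odor onset to ``search_tail_s`` after offset.  Passing
    ``peak_window`` reuses a previously determined window (the window is
    held fixed across trials of a preparation).  A peak at the series edge
    clips the 3-volume window with a warning.
    """
    dff_series = np.asarray(dff_series, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI mask is empty")
    T = dff_series.shape[0]
    if T < 3:
        raise ValueError("series too short for a 3-volume window")

    if peak_window is None:
        first = int(np.floor(odor_onset * volume_rate))
        last = int(np.ceil((odor_onset + odor_duration + search_tail_s) * volume_rate))
        first = min(max(first, 0), T - 1)
        last = min(last, T - 1)
        trace = np.nanmean(dff_series[:, roi], axis=1)
        k = first + int(np.argmax(np.abs(trace[first : last + 1])))
        lo, hi = k - 1, k + 1
        if lo < 0 or hi > T - 1:
            warnings.warn("peak at series edge; clipping the 3-volume window")
            lo, hi = max(lo, 0), min(hi, T - 1)
        peak_window = (lo, hi)
    lo, hi = peak_window
    image = dff_series[lo : hi + 1].mean(axis=0)
    return ResponseImage(
        dff=image, odor_label=odor_label, n_trials=1, peak_window=(lo, hi)
    )


def average_trials(responses) -> ResponseImage:
    """Pixelwise mean of per-trial response images (one odor)."""
    responses = list(responses)
    if not responses:
        raise ValueError("need at least one trial")
    shape = responses[0].dff.shape
    for r in responses:
        if r.dff.shape != shape:
            raise ValueError("response image shapes do not match")
    stack = np.stack([r.dff for r in responses])
    return ResponseImage(
        dff=stack.mean(axis=0),
        odor_label=responses[0].odor_label,
        n_trials=len(responses),
        peak_window=responses[0].peak_window,
    )


def responses_from_trials(trials, roi, kernel_size=4, sigma=1.0):
    """Full front end: trials -> one trial-averaged ResponseImage per odor.

    z-project, dF/F, smooth each trial, determine the peak window once from
    the across-trial average ROI trace of the preparation, extract every
    trial's response at that fixed window, then average trials per odor.
    Returns a dict odor_label -> ResponseImage (insertion order = first
    appearance).
    """
    trials = list(trials)
    if not trials:
        raise ValueError("no trials")
    processed = []
    for trial in trials:
        frames = dff(zproject(trial), trial.n_baseline_volumes)
        processed.append(smooth(frames, kernel_size, sigma))
    # fixed peak window per preparation, from the mean ROI trace
    t0 = trials[0]
    mean_series = np.mean(processed, axis=0)
    ref = peak_response(
        mean_series, roi, t0.volume_rate, t0.odor_onset, t0.odor_duration
    )
    window = ref.peak_window

    by_odor: dict = {}
    for trial, series in zip(trials, processed):
        img = peak_response(
            series,
            roi,
            trial.volume_rate,
            trial.odor_onset,
            trial.odor_duration,
            peak_window=window,
            odor_label=trial.odor_label,
        )
        by_odor.setdefault(trial.odor_label, []).append(img)
    return {odor: average_trials(imgs) for odor, imgs in by_odor.items()}


# -- spatial statistics ----------------------------------------------------


def _response_matrix(responses, mask):
    """Masked pixel x odor matrix and labels from a response collection."""
    items = list(responses.items()) if isinstance(responses, dict) else [
        (r.odor_label or str(i), r) for i, r in enumerate(responses)
    ]
    if len(items) < 2:
        raise ValueError("need at least two odors")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    labels = [label for label, _ in items]
    X = np.column_stack([r.dff[mask] for _, r in items])
    return X, labels, mask


def pca_responses(responses, mask) -> PCAResult:
    """Spatial PCA of the odor-response set within a mask.

    The input matrix has one column per odor (masked pixels as
    observations); columns are mean-centered over pixels.  Pixel scores of
    each component are reshaped back to images with off-mask pixels zero;
    ``variance_explained`` holds the per-component variance fractions
    (non-increasing, summing to 1 for full-rank input).
    """
    X, labels, mask = _response_matrix(responses, mask)
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0:
        return PCAResult(component_images=[], variance_explained=np.array([]))
    var = s**2 / total
    images = []
    shape = mask.shape
    for k in range(len(s)):
        img = np.zeros(shape)
        img[mask] = U[:, k] * s[k]
        images.append(img)
    return PCAResult(component_images=images, variance_explained=var)


def pixel_cv(responses, eps: float = 1e-3) -> float:
    """Mean over pixels of (SD across odors) / |mean across odors|.

    Pixels with ``|mean| < eps`` (dF/F units) are excluded to avoid
    unbounded ratios; raises if every pixel is excluded.
    """
    imgs = (
        [r.dff for r in responses.values()]
        if isinstance(responses, dict)
        else [r.dff for r in responses]
    )
    if len(imgs) < 2:
        raise ValueError("need at least two odors")
    stack = np.stack(imgs)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=0)
    keep = np.abs(mean) >= eps
    if not keep.any():
        raise ValueError("all pixels excluded by the |mean| threshold")
    return float(np.mean(sd[keep] / np.abs(mean[keep])))


def correlation_matrix(responses, mask) -> DistanceMatrix:
    """Pearson correlations between the masked, vectorized odor responses.

    Zero-variance images give NaN correlations and a warning.  Returned as
    a labeled symmetric matrix with unit diagonal.
    """
    X, labels, _ = _response_matrix(responses, mask)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        warnings.warn("zero-variance response image; correlations undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(C, 1.0)
    return DistanceMatrix(labels=labels, D=C)


def linkage_distances(correlations: DistanceMatrix, method: str = "average"):
    """Odor-pair distances and hierarchical clustering from the correlations.

    ``D(i, j)`` is the Euclidean distance between rows i and j of the
    correlation matrix; the linkage (default UPGMA/average, ``single`` and
    ``complete`` also valid) is computed on the condensed distances.
    """
    C = correlations.D
    condensed = scipy.spatial.distance.pdist(C, metric="euclidean")
    D = scipy.spatial.distance.squareform(condensed)
    Z = scipy.cluster.hierarchy.linkage(condensed, method=method)
    return (
        DistanceMatrix(labels=list(correlations.labels), D=D),
        LinkageTree(merges=Z, method=method),
    )


def normalize_distances(distance_matrices):
    """Scale each preparation's distances by its maximum, then average.

    Takes a list of DistanceMatrix (one per preparation, same label order)
    and returns (list of normalized matrices, elementwise mean matrix).
    """
    distance_matrices = list(distance_matrices)
    normalized = []
    for dm in distance_matrices:
        peak = dm.D.max()
        if peak <= 0:
            raise ValueError("all-zero distance matrix cannot be normalized")
        normalized.append(DistanceMatrix(labels=list(dm.labels), D=dm.D / peak))
    mean = DistanceMatrix(
        labels=list(distance_matrices[0].labels),
        D=np.mean([dm.D for dm in normalized], axis=0),
    )
    return normalized, mean


def distance_regression(distances_a, distances_b):
    """OLS of b on a over paired odor-pair distances.

    Returns ``(r_squared, p_value, slope, intercept)``; the p-value is the
    two-sided test of zero slope.
    """
    a = np.asarray(distances_a, dtype=float)
    b = np.asarray(distances_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need paired vectors of equal length >= 3")
    if np.std(a) == 0:
        raise ValueError("zero variance in the predictor")
    fit = scipy.stats.linregress(a, b)
    return fit.rvalue**2, fit.pvalue, fit.slope, fit.intercept


def paired_comparison(before, after):
    """Two-tailed paired t-test; returns ``(t, p)``.

    Zero-variance differences leave p undefined (NaN) with a warning.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or len(before) < 2:
        raise ValueError("need paired vectors of equal length >= 2")
    diff = after - before
    if np.std(diff, ddof=1) == 0:
        if np.all(diff == 0):
            return 0.0, 1.0
        warnings.warn("zero-variance differences; p undefined")
        return float("nan"), float("nan")
    t, p = scipy.stats.ttest_rel(after, before)
    return float(t), float(p)
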