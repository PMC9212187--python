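"""Functional connectivity from ROI time series.

The resting-state pipeline starts from per-subject BOLD time series averaged
within regions of interest (ROIs).  Connectivity between two ROIs is the
Pearson correlation of their time courses; correlations are variance-
stabilized with the Fisher z-transform, z = atanh(r), before any further
analysis.  A binary brain graph is obtained by thresholding the resulting
ROI-to-ROI matrix, either with an absolute cut (keep edges with z above a
fixed value) or a proportional one (keep the strongest fraction of all
possible edges).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import signal

__all__ = [
    "RoiTimeSeries",
    "ConnectivityMatrix",
    "AdjacencySpec",
    "BrainGraph",
    "bandpass_filter",
    "roi_correlation",
    "fisher_z",
    "threshold_adjacency",
]

#: |r| is clipped to 1 - FISHER_CLIP before atanh so z stays finite.
FISHER_CLIP = 1e-7


@dataclass
class RoiTimeSeries:
    """A T x N matrix of BOLD-like signals for one subject.

    Parameters
    ----------
    subject_id : str
        Identifier of the subject.
    data : ndarray, shape (T, N)
        One column per ROI, one row per acquisition timepoint.
    roi_labels : sequence of str
        Unique label per ROI column.
    dt : float
        Sampling interval (repetition time) in seconds; 3.0 s by default.
    """

    subject_id: str
    data: np.ndarray
    roi_labels: Sequence[str]
    dt: float = 3.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.roi_labels = list(self.roi_labels)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (timepoints x ROIs) array")
        t, n = self.data.shape
        if t < 4:
            raise ValueError(f"need at least 4 timepoints, got {t}")
        if n < 2:
            raise ValueError(f"need at least 2 ROIs, got {n}")
        if len(self.roi_labels) != n:
            raise ValueError("roi_labels length must match number of columns")
        if len(set(self.roi_labels)) != n:
            raise ValueError("roi_labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    def select(self, labels: Sequence[str]) -> "RoiTimeSeries":
        """Return a copy restricted to ``labels``, in that order."""
        index = {lab: i for i, lab in enumerate(self.roi_labels)}
        missing = [lab for lab in labels if lab not in index]
        if missing:
            raise KeyError(f"ROIs not present in time series: {missing}")
        cols = [index[lab] for lab in labels]
        return RoiTimeSeries(self.subject_id, self.data[:, cols], list(labels), self.dt)


class MatrixKind(str, Enum):
    pearson_r = "pearson_r"
    fisher_z = "fisher_z"


@dataclass
class ConnectivityMatrix:
    """Symmetric N x N ROI-to-ROI correlation matrix (raw r or Fisher z)."""

    values: np.ndarray
    roi_labels: Sequence[str]
    kind: MatrixKind = MatrixKind.pearson_r

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.roi_labels = list(self.roi_labels)
        self.kind = MatrixKind(self.kind)
        n = len(self.roi_labels)
        if self.values.shape != (n, n):
            raise ValueError("values must be square and match roi_labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero by convention")
        if self.kind is MatrixKind.pearson_r:
            off = self.values[~np.eye(n, dtype=bool)]
            if off.size and (off.min() < -1 - 1e-12 or off.max() > 1 + 1e-12):
                raise ValueError("Pearson correlations must lie in [-1, 1]")

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)


class ThresholdMode(str, Enum):
    absolute = "absolute"
    proportional = "proportional"


@dataclass
class AdjacencySpec:
    """How to binarize a Fisher-z matrix into a graph.

    ``absolute`` keeps edges with z > value (signed, one-sided); the
    ``proportional`` mode keeps the ceil(value * N(N-1)/2) strongest pairs.
    Set ``use_magnitude`` to rank/threshold on |z| instead of signed z.
    """

    mode: ThresholdMode
    value: float
    use_magnitude: bool = False

    def __post_init__(self) -> None:
        self.mode = ThresholdMode(self.mode)
        if self.mode is ThresholdMode.absolute and self.value <= 0:
            raise ValueError("absolute threshold must be positive")
        if self.mode is ThresholdMode.proportional and not (0 < self.value <= 1):
            raise ValueError("proportional density must lie in (0, 1]")


@dataclass
class BrainGraph:
    """Undirected binary graph over ROIs."""

    adjacency: np.ndarray
    roi_labels: Sequence[str]
    spec: AdjacencySpec | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        self.roi_labels = list(self.roi_labels)
        n = len(self.roi_labels)
        if a.shape != (n, n):
            raise ValueError("adjacency must be square and match roi_labels")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return len(self.roi_labels)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)


def bandpass_filter(ts: RoiTimeSeries, low: float = 0.01, high: float = 0.1) -> RoiTimeSeries:
    """Zero-phase band-pass filter of every ROI column.

    A 2nd-order Butterworth band-pass is applied forward and backward
    (``filtfilt``), which doubles the effective order and cancels phase
    distortion.  Column means are removed first, so a constant column maps
    to (numerically) zero.  The default 0.01-0.1 Hz band retains the slow
    fluctuations conventionally analysed in resting-state studies.
    """
    nyquist = 1.0 / (2.0 * ts.dt)
    if not (0 <= low < high):
        raise ValueError(f"need 0 <= low < high, got ({low}, {high})")
    if high >= nyquist:
        raise ValueError(
            f"high cutoff {high} Hz must lie below the Nyquist frequency "
            f"{nyquist:.4g} Hz for dt={ts.dt} s"
        )
    b, a = signal.butter(2, [low, high], btype="bandpass", fs=1.0 / ts.dt)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if ts.n_timepoints <= padlen:
        raise ValueError(
            f"time series too short for stable filtering: T={ts.n_timepoints} "
            f"<= required padding {padlen}"
        )
    centred = ts.data - ts.data.mean(axis=0, keepdims=True)
    filtered = signal.filtfilt(b, a, centred, axis=0)
    return RoiTimeSeries(ts.subject_id, filtered, ts.roi_labels, ts.dt)


def roi_correlation(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pearson correlation between every pair of ROI time courses.

    The diagonal is set to zero by convention (self-connectivity carries no
    information downstream).  Raises if any ROI has zero variance.
    """
    sd = ts.data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [ts.roi_labels[i] for i in dead]
        raise ValueError(f"zero-variance ROI column(s): {names}")
    r = np.corrcoef(ts.data, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)  # symmetrize away rounding noise
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(r, ts.roi_labels, MatrixKind.pearson_r)


def fisher_z(c: ConnectivityMatrix) -> ConnectivityMatrix:
    """Fisher z-transform, z = atanh(r), applied elementwise.

    |r| is clipped to 1 - 1e-7 beforehand so perfectly correlated pairs map
    to a large finite value rather than infinity.
    """
    if c.kind is not MatrixKind.pearson_r:
        raise ValueError("fisher_z expects a pearson_r matrix")
    r = np.clip(c.values, -1 + FISHER_CLIP, 1 - FISHER_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z, c.roi_labels, MatrixKind.fisher_z)


def threshold_adjacency(c: ConnectivityMatrix, spec: AdjacencySpec) -> BrainGraph:
    """Binarize a Fisher-z matrix into an undirected graph.

    Absolute mode keeps pairs with z > spec.value.  Proportional mode keeps
    exactly ceil(value * N(N-1)/2) pairs with the largest z, ties broken by
    (i, j) lexicographic order for bit-reproducibility.
    """
    if c.kind is not MatrixKind.fisher_z:
        raise ValueError("threshold_adjacency expects a fisher_z matrix")
    n = c.n_rois
    z = np.abs(c.values) if spec.use_magnitude else c.values
    a = np.zeros((n, n), dtype=np.int8)
    iu, ju = np.triu_indices(n, k=1)
    if spec.mode is ThresholdMode.absolute:
        keep = z[iu, ju] > spec.value
        a[iu[keep], ju[keep]] = 1
    else:
        n_pairs = iu.size
        raw = spec.value * n_pairs
        m = int(np.ceil(raw))
        if raw < 1:
            warnings.warn(
                f"proportional density {spec.value} selects fewer than one of "
                f"{n_pairs} pairs; rounding up to a single edge",
                RuntimeWarning,
                stacklevel=2,
            )
        # sort by z descending, then (i, j) lexicographic
        order = np.lexsort((ju, iu, -z[iu, ju]))[:m]
        a[iu[order], ju[order]] = 1
    a = a + a.T
    return BrainGraph(a, c.roi_labels, spec)
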