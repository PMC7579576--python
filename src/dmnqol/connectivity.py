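"""From ROI time series to binary undirected brain graphs.

The chain mirrors the standard resting-state pipeline: average voxels into
ROI signals, band-pass the slow BOLD fluctuations (0.01–0.08 Hz), correlate
every ROI pair (Pearson), and binarize the correlation matrix into an
adjacency matrix.  Binarization defaults to proportional thresholding at
density 0.2 over the *positive* correlations; negative correlations are
never admitted as edges unless absolute-value thresholding is explicitly
requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .errors import (
    DegenerateSignalError,
    ParameterError,
    SchemaError,
)
from .io_formats import ROITimeSeriesSet

__all__ = [
    "BrainGraph",
    "ConnectivityConfig",
    "ConnectivityMatrix",
    "average_voxels_to_roi",
    "bandpass_filter",
    "binarize_graph",
    "pearson_connectivity",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric matrix of pairwise ROI correlations with unit diagonal."""

    values: np.ndarray
    roi_labels: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != n:
            raise ValueError("connectivity matrix must be square")
        if not self.roi_labels:
            self.roi_labels = [f"ROI{i}" for i in range(n)]
        self.roi_labels = list(self.roi_labels)
        if len(self.roi_labels) != n:
            raise SchemaError("label count does not match matrix size")
        if np.abs(self.values - self.values.T).max(initial=0.0) > 1e-12:
            raise ValueError("connectivity matrix must be symmetric")
        if np.abs(np.diag(self.values) - 1.0).max(initial=0.0) > 1e-12:
            raise ValueError("connectivity diagonal must be 1")
        if np.abs(self.values).max(initial=0.0) > 1.0 + 1e-12:
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class BrainGraph:
    """Binary undirected graph over ROIs: a_ij in {0,1}, a_ii = 0."""

    adjacency: np.ndarray
    labels: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if (a != a.T).any():
            raise ValueError("adjacency must be symmetric")
        if np.diag(a).any():
            raise ValueError("self-loops are not allowed (a_ii = 0)")
        self.adjacency = a.astype(np.int8)
        if not self.labels:
            self.labels = [f"ROI{i}" for i in range(a.shape[0])]
        self.labels = list(self.labels)
        if len(self.labels) != a.shape[0]:
            raise SchemaError("label count does not match adjacency size")

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        g.add_edges_from(zip(i.tolist(), j.tolist()))
        return g


@dataclass
class ConnectivityConfig:
    """Settings for filtering and binarization.

    band
        Pass band in Hz; the study band is (0.01, 0.08), inside which the
        resting-state BOLD fluctuations of interest live.
    threshold_method
        ``"density"`` keeps the ``floor(threshold_value * m)`` largest
        positive correlations among the m = n(n-1)/2 pairs; ``"absolute"``
        keeps pairs with correlation strictly above ``threshold_value``.
    use_absolute_correlation
        Admit anti-correlations by magnitude (off by default).
    discard_initial
        Saturation volumes to drop when reading raw series.
    """

    band: tuple[float, float] = (0.01, 0.08)
    threshold_method: str = "density"
    threshold_value: float = 0.2
    use_absolute_correlation: bool = False
    discard_initial: int = 10

    def __post_init__(self) -> None:
        low, high = self.band
        if not (0.0 < low < high):
            raise ParameterError("band must satisfy 0 < low < high")
        if self.threshold_method not in ("density", "absolute"):
            raise ParameterError(
                f"unknown threshold_method {self.threshold_method!r}"
            )
        if self.threshold_method == "density" and not (
            0.0 < self.threshold_value <= 1.0
        ):
            raise ParameterError("density threshold must lie in (0, 1]")


def average_voxels_to_roi(
    voxel_series: np.ndarray,
    assignment: Sequence[str] | Mapping[int, str],
    roi_labels: Sequence[str] | None = None,
    subject_id: str = "subject",
    tr_seconds: float = 2.0,
) -> ROITimeSeriesSet:
    """Average voxel time series into one series per ROI.

    ``assignment`` maps each voxel row to an ROI label (a sequence aligned
    with rows, or a mapping from row index to label).  Each ROI's series is
    the unweighted mean of its voxels' series.
    """
    voxel_series = np.asarray(voxel_series, dtype=float)
    n_vox = voxel_series.shape[0]
    if isinstance(assignment, Mapping):
        labels_per_voxel = [assignment[i] for i in range(n_vox)]
    else:
        labels_per_voxel = list(assignment)
    if len(labels_per_voxel) != n_vox:
        raise SchemaError("assignment length does not match voxel count")
    if roi_labels is None:
        seen: dict[str, None] = {}
        for lab in labels_per_voxel:
            seen.setdefault(lab, None)
        roi_labels = list(seen)
    rows = []
    for roi in roi_labels:
        idx = [i for i, lab in enumerate(labels_per_voxel) if lab == roi]
        if not idx:
            raise SchemaError(f"ROI {roi!r} has no assigned voxels")
        rows.append(voxel_series[idx].mean(axis=0))
    return ROITimeSeriesSet(
        subject_id=subject_id,
        values=np.vstack(rows),
        tr_seconds=tr_seconds,
        roi_labels=list(roi_labels),
    )


def bandpass_filter(
    ts: ROITimeSeriesSet, config: ConnectivityConfig | None = None
) -> ROITimeSeriesSet:
    """Zero-phase band-pass filter of every ROI series.

    An order-4 Butterworth band-pass is applied forward and backward
    (``sosfiltfilt``) so phase is preserved — a requirement when the next
    step correlates series against each other.  Rows are demeaned first;
    the pass band must sit below the Nyquist frequency 1/(2 TR).
    """
    config = config or ConnectivityConfig()
    low, high = config.band
    nyquist = 1.0 / (2.0 * ts.tr_seconds)
    if high >= nyquist:
        raise ParameterError(
            f"high cutoff {high} Hz is not below Nyquist {nyquist} Hz"
        )
    sos = signal.butter(
        4, [low, high], btype="bandpass", fs=1.0 / ts.tr_seconds, output="sos"
    )
    demeaned = ts.values - ts.values.mean(axis=1, keepdims=True)
    filtered = signal.sosfiltfilt(sos, demeaned, axis=1)
    return ROITimeSeriesSet(
        subject_id=ts.subject_id,
        values=filtered,
        tr_seconds=ts.tr_seconds,
        roi_labels=ts.roi_labels,
    )


def pearson_connectivity(ts: ROITimeSeriesSet) -> ConnectivityMatrix:
    """Product-moment correlation between every pair of ROI series."""
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 time points to correlate")
    variances = ts.values.var(axis=1)
    dead = np.nonzero(variances == 0)[0]
    if dead.size:
        raise DegenerateSignalError(
            f"zero-variance signal for ROI {ts.roi_labels[dead[0]]!r}"
        )
    r = np.corrcoef(ts.values)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(values=r, roi_labels=ts.roi_labels)


def binarize_graph(
    conn: ConnectivityMatrix, config: ConnectivityConfig | None = None
) -> BrainGraph:
    """Threshold a connectivity matrix into a binary graph.

    Density mode keeps the ``floor(value * m)`` strongest positive
    correlations (or strongest magnitudes under
    ``use_absolute_correlation``); ties at the cutoff are broken by
    lexicographic ROI index so runs are reproducible.  Absolute mode keeps
    pairs strictly above the threshold.
    """
    config = config or ConnectivityConfig()
    n = conn.n
    weights = (
        np.abs(conn.values) if config.use_absolute_correlation
        else conn.values
    )
    iu, ju = np.triu_indices(n, 1)
    pair_w = weights[iu, ju]
    adj = np.zeros((n, n), dtype=np.int8)
    if config.threshold_method == "absolute":
        keep = pair_w > config.threshold_value
        adj[iu[keep], ju[keep]] = 1
    else:
        m = n * (n - 1) // 2
        k = int(np.floor(config.threshold_value * m))
        positive = np.nonzero(pair_w > 0)[0]
        # sort by (-weight, i, j): deterministic lexicographic tie-break
        order = sorted(
            positive.tolist(),
            key=lambda idx: (-pair_w[idx], int(iu[idx]), int(ju[idx])),
        )
        chosen = order[: min(k, len(order))]
        adj[iu[chosen], ju[chosen]] = 1
    adj = adj | adj.T
    return BrainGraph(adjacency=adj, labels=conn.roi_labels)
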