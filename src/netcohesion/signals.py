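"""Node-signal preparation and the sliding-window grid shared by all stages.

The analysis operates on node-by-time BOLD matrices sampled at one volume
per TR (3 s by default).  The first ``trim`` volumes are discarded to avoid
stimulus-onset transients, and every downstream statistic is computed on a
grid of heavily overlapping sliding windows over the trimmed span.  With the
default acquisition of 165 TRs, a 5-TR trim and 10-TR windows advancing one
TR at a time (90 % overlap), the grid has exactly 151 windows.

Voxel-level helpers (global-mean scaling, mask-average node extraction) are
provided for pipelines that start from 4-D volumes; cohorts stored as node
matrices skip them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .nci import NetworkSpec

__all__ = [
    "SubjectRecord",
    "WindowGrid",
    "scale_by_global_mean",
    "extract_node_signal",
    "trim_onset",
    "make_window_grid",
    "network_activity_series",
    "load_nifti_nodes",
]


@dataclass
class SubjectRecord:
    """One subject's node signals plus group label and optional phenotypes.

    Parameters
    ----------
    subject_id : str
        Unique subject label.
    group : str
        ``"patient"`` or ``"control"``.
    node_labels : sequence of str
        Row labels of ``signals``; must be unique.
    signals : ndarray, shape (n_nodes, T)
        Node-by-time signal matrix, no missing values.
    symptoms : dict or None
        Optional PANSS subscores with keys ``positive``, ``negative``,
        ``general``.
    rating : RatingTrace or None
        Optional continuous emotion-rating trace at 10 Hz.
    """

    subject_id: str
    group: str
    node_labels: Sequence[str]
    signals: np.ndarray
    symptoms: dict | None = None
    rating: "object | None" = None

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError(
                f"subject {self.subject_id}: signals must be 2-D (nodes x time)"
            )
        if len(self.node_labels) != self.signals.shape[0]:
            raise ValueError(
                f"subject {self.subject_id}: {len(self.node_labels)} node labels "
                f"for {self.signals.shape[0]} signal rows"
            )
        if len(set(self.node_labels)) != len(self.node_labels):
            raise ValueError(f"subject {self.subject_id}: duplicate node labels")
        if not np.isfinite(self.signals).all():
            raise ValueError(f"subject {self.subject_id}: non-finite signal values")
        if self.group not in ("patient", "control"):
            raise ValueError(f"subject {self.subject_id}: unknown group {self.group!r}")

    @property
    def n_timepoints(self) -> int:
        return self.signals.shape[1]

    def node_matrix(self, nodes: Iterable[str]) -> np.ndarray:
        """Return the signal rows for ``nodes`` in the requested order."""
        index = {lab: i for i, lab in enumerate(self.node_labels)}
        rows = []
        for node in nodes:
            if node not in index:
                raise KeyError(
                    f"subject {self.subject_id} is missing node {node!r}"
                )
            rows.append(index[node])
        return self.signals[rows, :]


@dataclass(frozen=True)
class WindowGrid:
    """Sliding-window grid over a trimmed time series.

    Windows are half-open index ranges ``[s, s + window)`` on the trimmed
    series, for starts ``s = 0, step, 2*step, ...``.  A window is identified
    by its start index.
    """

    n_timepoints: int
    window: int = 10
    step: int = 1
    trim: int = 5
    starts: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.window < 1 or self.step < 1 or self.trim < 0:
            raise ValueError("window and step must be >= 1, trim >= 0")
        if self.window > self.n_timepoints:
            raise ValueError(
                f"window length {self.window} exceeds trimmed series "
                f"length {self.n_timepoints}"
            )
        n = (self.n_timepoints - self.window) // self.step + 1
        object.__setattr__(
            self, "starts", np.arange(n, dtype=int) * self.step
        )

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    def slices(self) -> list[slice]:
        return [slice(s, s + self.window) for s in self.starts]

    def window_view(self, series: np.ndarray) -> np.ndarray:
        """Stack the grid's windows of ``series`` along a new leading axis.

        ``series`` may be 1-D ``(T,)`` or 2-D ``(nodes, T)``; the result is
        ``(n_windows, window)`` or ``(n_windows, nodes, window)``.
        """
        series = np.asarray(series, dtype=float)
        if series.shape[-1] != self.n_timepoints:
            raise ValueError(
                f"series length {series.shape[-1]} does not match grid span "
                f"{self.n_timepoints}"
            )
        view = np.lib.stride_tricks.sliding_window_view(
            series, self.window, axis=-1
        )
        # view shape: (..., T - window + 1, window); subsample by step
        view = view[..., :: self.step, :]
        return np.moveaxis(view, -2, 0)


def scale_by_global_mean(voxel_matrix: np.ndarray) -> np.ndarray:
    """Scale every time point's voxel vector by its own global mean.

    Each column (time point) of the voxel-by-time matrix is divided by the
    mean over voxels at that time point, so every output column has mean 1.

    Raises
    ------
    ValueError
        If some time point has a zero global mean; the message names the
        offending time index.
    """
    voxel_matrix = np.asarray(voxel_matrix, dtype=float)
    col_means = voxel_matrix.mean(axis=0)
    bad = np.flatnonzero(col_means == 0.0)
    if bad.size:
        raise ValueError(
            f"global mean is zero at time index {bad[0]}; cannot scale"
        )
    return voxel_matrix / col_means


def extract_node_signal(
    voxel_matrix: np.ndarray, mask: Sequence[int] | np.ndarray
) -> np.ndarray:
    """Average the voxel time series inside ``mask`` into one node signal.

    ``mask`` is a set of row indices into the voxel-by-time matrix; the
    node's signal is the unweighted mean over those voxels per time point.
    """
    voxel_matrix = np.asarray(voxel_matrix, dtype=float)
    mask = np.asarray(mask, dtype=int)
    if mask.size == 0:
        raise ValueError("empty voxel mask")
    if mask.min() < 0 or mask.max() >= voxel_matrix.shape[0]:
        raise IndexError("mask index out of range")
    return voxel_matrix[mask, :].mean(axis=0)


def trim_onset(data: np.ndarray, trim: int = 5) -> np.ndarray:
    """Drop the first ``trim`` time samples (last axis) of a series or matrix."""
    data = np.asarray(data)
    if trim < 0:
        raise ValueError("trim must be non-negative")
    if trim >= data.shape[-1]:
        raise ValueError(
            f"trim {trim} leaves no samples from length {data.shape[-1]}"
        )
    return data[..., trim:]


def make_window_grid(
    n_timepoints: int, window: int = 10, step: int = 1, trim: int = 5
) -> WindowGrid:
    """Build the sliding-window grid for an already-trimmed series.

    ``n_timepoints`` is the trimmed length; with the defaults
    ``(160, 10, 1)`` the grid has 151 windows.
    """
    return WindowGrid(n_timepoints=n_timepoints, window=window, step=step, trim=trim)


def network_activity_series(
    subject: SubjectRecord, network: "NetworkSpec", grid: WindowGrid
) -> np.ndarray:
    """Per-window mean BOLD amplitude of a network (the activity control).

    Each node signal (already trimmed to the grid span) is z-scored over the
    trimmed span, the z-scored nodes are averaged, and the averaged series is
    averaged again inside each window.  Comparing this series between groups
    checks that NCI differences reflect connectivity rather than amplitude.
    """
    mat = subject.node_matrix(network.nodes)
    if mat.shape[1] != grid.n_timepoints:
        raise ValueError(
            f"subject {subject.subject_id}: signals span {mat.shape[1]} samples "
            f"but grid expects {grid.n_timepoints}"
        )
    sd = mat.std(axis=1, ddof=0)
    flat = np.flatnonzero(sd == 0.0)
    if flat.size:
        raise ValueError(
            f"node {network.nodes[flat[0]]!r} of subject {subject.subject_id} "
            "has zero variance; cannot z-score"
        )
    z = (mat - mat.mean(axis=1, keepdims=True)) / sd[:, None]
    pooled = z.mean(axis=0)
    return grid.window_view(pooled).mean(axis=-1)


def load_nifti_nodes(
    bold_path: str,
    roi_path: str,
    node_prefix: str = "node",
    scale_global_mean: bool = True,
) -> tuple[list[str], np.ndarray]:
    """Node signals from a 4-D BOLD volume and an integer-labelled ROI mask.

    Voxels sharing a nonzero integer label in the ROI volume form one node
    (label value = node id); the node signal is the unweighted voxel mean
    per time point, after optional scaling of every volume by its own
    within-mask global mean.  Returns ``(node_labels, node_by_time_matrix)``
    with labels ``"<prefix>_<label>"`` in ascending label order.
    """
    import nibabel as nib

    bold = np.asanyarray(nib.load(bold_path).dataobj, dtype=float)
    rois = np.asanyarray(nib.load(roi_path).dataobj)
    rois = np.rint(rois).astype(int)
    if bold.ndim != 4:
        raise ValueError(f"{bold_path}: expected a 4-D BOLD volume")
    if rois.shape != bold.shape[:3]:
        raise ValueError(
            f"ROI grid {rois.shape} does not match BOLD grid {bold.shape[:3]}"
        )
    labels = np.unique(rois)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise ValueError(f"{roi_path}: no nonzero ROI labels")
    in_mask = rois > 0
    voxels = bold[in_mask, :]  # (n_mask_voxels, T)
    if scale_global_mean:
        voxels = scale_by_global_mean(voxels)
    roi_of_voxel = rois[in_mask]
    names, rows = [], []
    for lab in labels:
        rows.append(extract_node_signal(voxels, np.flatnonzero(roi_of_voxel == lab)))
        names.append(f"{node_prefix}_{int(lab)}")
    return names, np.asarray(rows)
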