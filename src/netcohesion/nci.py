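"""Network Cohesion Index (NCI) computation.

For a network of ``n >= 3`` nodes and a sliding window, all ``n(n-1)/2``
pairwise Pearson correlations of the node signals inside the window are
computed, Fisher z-transformed (``arctanh``), and summarised by the
t-statistic of a one-sample Student's t-test against ``mu = 0``:

    t = mean(z) / (sd(z) / sqrt(m)),   m = n(n-1)/2,  sd with ddof=1.

The t-statistic itself is the index: it is large when the mean pairwise
correlation is high *and* its dispersion across pairs is low, hence "cohesion".
One NCI value is produced per subject, network and window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .signals import SubjectRecord, WindowGrid

__all__ = [
    "NetworkSpec",
    "NCISeries",
    "pairwise_correlations",
    "fisher_z",
    "nci_t",
    "compute_nci_series",
]

#: correlations of magnitude >= 1 are clipped to this before arctanh
_R_CLIP = 1.0 - 1e-10


@dataclass(frozen=True)
class NetworkSpec:
    """A named network: an ordered list of at least three node labels.

    Three nodes give three pairwise correlations, the minimum for a
    one-sample t-test with positive degrees of freedom; two-node networks
    are rejected outright.
    """

    name: str
    nodes: tuple[str, ...]

    def __init__(self, name: str, nodes: Sequence[str]):
        nodes = tuple(nodes)
        if len(nodes) < 3:
            raise ValueError(
                f"network {name!r} has {len(nodes)} nodes; at least 3 required "
                "for a defined cohesion t-statistic"
            )
        if len(set(nodes)) != len(nodes):
            raise ValueError(f"network {name!r} has duplicate node labels")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "nodes", nodes)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_pairs(self) -> int:
        n = len(self.nodes)
        return n * (n - 1) // 2


@dataclass
class NCISeries:
    """Per-window NCI values for one subject and network.

    ``degenerate`` flags windows where some node had zero variance or the
    pairwise z-values had zero spread; flagged values carry a signed-infinity
    or NaN sentinel and are excluded from downstream rank tests.
    """

    subject_id: str
    network: str
    values: np.ndarray
    grid: WindowGrid
    degenerate: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.degenerate is None:
            self.degenerate = ~np.isfinite(self.values)
        self.degenerate = np.asarray(self.degenerate, dtype=bool)
        if len(self.values) != self.grid.n_windows:
            raise ValueError(
                f"{len(self.values)} values for a {self.grid.n_windows}-window grid"
            )


def pairwise_correlations(window_matrix: np.ndarray) -> np.ndarray:
    """All pairwise Pearson correlations of the rows of a node-by-time block.

    Returns the upper triangle of the correlation matrix in row-major order
    (``(0,1), (0,2), ..., (1,2), ...``), length ``n(n-1)/2``.  A zero-variance
    row yields NaN entries for its pairs (flagged degenerate downstream).
    """
    window_matrix = np.asarray(window_matrix, dtype=float)
    n = window_matrix.shape[0]
    if n < 3:
        raise ValueError("need at least 3 nodes for pairwise correlations")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(window_matrix)
    iu = np.triu_indices(n, k=1)
    return corr[iu]


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher z-transform ``arctanh(r)``, clipping |r| >= 1 with a warning."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        warnings.warn(
            "correlation of magnitude 1 clipped before Fisher z-transform",
            RuntimeWarning,
            stacklevel=2,
        )
        r = np.clip(r, -_R_CLIP, _R_CLIP)
    out = np.arctanh(r)
    return out if out.ndim else float(out)


def nci_t(z_values: np.ndarray) -> tuple[float, bool]:
    """One-sample t-statistic of Fisher-z coefficients against zero.

    Returns ``(t, degenerate)``.  With zero spread the statistic is
    undefined; the sentinel is ``sign(mean) * inf`` (NaN when the mean is
    also zero) and the degenerate flag is set.
    """
    z = np.asarray(z_values, dtype=float)
    if len(z) < 3:
        raise ValueError("need at least 3 z-values")
    if not np.isfinite(z).all():
        return float("nan"), True
    m = z.mean()
    if np.ptp(z) == 0.0:  # exact zero spread, not a float-epsilon sd
        return float(np.sign(m) * np.inf) if m != 0.0 else float("nan"), True
    s = z.std(ddof=1)
    return float(m / (s / np.sqrt(len(z)))), False


def _nci_values_vectorized(mat: np.ndarray, grid: WindowGrid) -> np.ndarray:
    """NCI per window for a node-by-time matrix, all windows at once."""
    blocks = grid.window_view(mat)  # (W, n_nodes, window)
    blocks = blocks - blocks.mean(axis=-1, keepdims=True)
    norms = np.linalg.norm(blocks, axis=-1)  # (W, n_nodes)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = blocks / norms[..., None]
        corr = unit @ np.swapaxes(unit, -1, -2)  # (W, n, n)
    n = mat.shape[0]
    iu = np.triu_indices(n, k=1)
    r = corr[:, iu[0], iu[1]]  # (W, n_pairs)
    clip_needed = np.abs(r) >= 1.0
    if clip_needed.any():
        warnings.warn(
            "correlation of magnitude 1 clipped before Fisher z-transform",
            RuntimeWarning,
            stacklevel=2,
        )
        r = np.clip(r, -_R_CLIP, _R_CLIP)
    z = np.arctanh(r)
    bad = ~np.isfinite(z).all(axis=1)
    mean = z.mean(axis=1)
    sd = z.std(axis=1, ddof=1)
    zero_spread = np.ptp(z, axis=1) == 0.0
    m = z.shape[1]
    values = np.full(len(r), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        ok = ~bad & ~zero_spread
        values[ok] = mean[ok] / (sd[ok] / np.sqrt(m))
        flat = ~bad & zero_spread
        values[flat] = np.where(
            mean[flat] == 0.0, np.nan, np.sign(mean[flat]) * np.inf
        )
    degenerate = bad | zero_spread
    return values, degenerate


def compute_nci_series(
    subject: SubjectRecord, network: NetworkSpec, grid: WindowGrid
) -> NCISeries:
    """Compute the NCI time course of ``subject`` on ``network`` over ``grid``.

    ``subject.signals`` must already be trimmed to the grid span.  Missing
    network nodes raise a KeyError naming subject and node.
    """
    mat = subject.node_matrix(network.nodes)
    if mat.shape[1] != grid.n_timepoints:
        raise ValueError(
            f"subject {subject.subject_id}: signals span {mat.shape[1]} samples "
            f"but grid expects {grid.n_timepoints}"
        )
    values, degenerate = _nci_values_vectorized(mat, grid)
    return NCISeries(
        subject_id=subject.subject_id,
        network=network.name,
        values=values,
        grid=grid,
        degenerate=degenerate,
    )
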