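"""Window-wise two-group inference with FDR control.

Each measure (network NCI, windowed rating, or the amplitude control) gives
one value per subject per window; groups are contrasted per window with the
two-sample Wilcoxon rank-sum test in its normal approximation with tie
correction, oriented control-minus-patient (Z > 0 when controls tend
larger).  The resulting p-value series is corrected with Benjamini-Hochberg
FDR over the comparison span.

The comparison span defaults to the lag-truncated central span (131 windows
with the default grid and max lag 10), matching the count used by the
cross-correlation stage; the full 151-window span is available via
``span="full"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .nci import NetworkSpec, compute_nci_series
from .rating import align_to_tr, window_rating
from .signals import SubjectRecord, WindowGrid, network_activity_series, trim_onset

__all__ = [
    "GroupDiffSeries",
    "ranksum_z",
    "ranksum_z_matrix",
    "fdr_bh",
    "central_span",
    "measure_matrix",
    "groupdiff_series",
]


@dataclass
class GroupDiffSeries:
    """Per-window rank-sum Z, p and BH-FDR q for a two-group contrast.

    Orientation is fixed control-minus-patient.  ``window_starts`` carries
    the original grid start indices, so a truncated span keeps addressable
    window labels.
    """

    measure: str
    window_starts: np.ndarray
    z: np.ndarray
    p: np.ndarray
    q: np.ndarray
    untestable: np.ndarray
    orientation: str = "control-minus-patient"
    n_comparisons: int = field(default=0)

    def __post_init__(self) -> None:
        if self.n_comparisons == 0:
            self.n_comparisons = int(np.sum(~self.untestable))

    def significant_windows(self, alpha: float = 0.05) -> np.ndarray:
        """Window start indices with q <= alpha."""
        ok = ~self.untestable & (self.q <= alpha)
        return self.window_starts[ok]


def _tie_term(column: np.ndarray) -> float:
    _, counts = np.unique(column, return_counts=True)
    counts = counts[counts > 1]
    return float(np.sum(counts**3 - counts))


def ranksum_z(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum Z and two-sided p (normal approximation).

    ``Z > 0`` when ``values_a`` tends larger than ``values_b``.  Tied values
    receive midranks and the variance carries the standard tie correction;
    no continuity correction is applied, so Z is the plain standardized rank
    sum reported in the neuroimaging literature.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 finite values per group")
    n1, n2 = len(a), len(b)
    n = n1 + n2
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w = ranks[:n1].sum()
    mean = n1 * (n + 1) / 2.0
    tie = _tie_term(pooled)
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if var <= 0.0:
        return 0.0, 1.0  # all pooled values identical
    z = (w - mean) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def ranksum_z_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise rank-sum Z for two subjects-by-windows matrices.

    All values must be finite (degenerate windows are handled by the callers
    via the scalar path).  Vectorized for the bootstrap's inner loop; with
    continuous data ties are absent and the tie correction short-circuits.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.shape[0], b.shape[0]
    n = n1 + n2
    pooled = np.vstack([a, b])
    ranks = stats.rankdata(pooled, axis=0)
    w = ranks[:n1].sum(axis=0)
    mean = n1 * (n + 1) / 2.0
    base_var = n1 * n2 * (n + 1) / 12.0
    var = np.full(pooled.shape[1], base_var)
    has_ties = (np.diff(np.sort(pooled, axis=0), axis=0) == 0.0).any(axis=0)
    for j in np.flatnonzero(has_ties):
        tie = _tie_term(pooled[:, j])
        var[j] = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    z = np.zeros(pooled.shape[1])
    ok = var > 0.0
    z[ok] = (w[ok] - mean) / np.sqrt(var[ok])
    return z


def fdr_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    NaN entries (untestable windows) are excluded from the correction and
    stay NaN in the output.
    """
    p = np.asarray(p, dtype=float)
    finite = np.isfinite(p)
    if ((p[finite] < 0.0) | (p[finite] > 1.0)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if finite.any():
        _, q_fin, _, _ = multipletests(p[finite], method="fdr_bh")
        q[finite] = q_fin
    return q


def central_span(n_windows: int, max_lag: int) -> slice:
    """The lag-truncated central span shared by all lags: ``[L, n - L)``."""
    if n_windows <= 2 * max_lag:
        raise ValueError(
            f"{n_windows} windows cannot accommodate max lag {max_lag}"
        )
    return slice(max_lag, n_windows - max_lag)


def measure_matrix(
    cohort: Sequence[SubjectRecord],
    measure: str,
    grid: WindowGrid,
    network: NetworkSpec | None = None,
    tr_seconds: float = 3.0,
) -> np.ndarray:
    """Subjects-by-windows matrix of a per-window measure.

    ``measure`` is ``"nci"``, ``"activity"`` or ``"rating"``; the first two
    require ``network``.  Degenerate NCI windows are NaN.  For ratings the
    subject's 10 Hz trace is TR-averaged, onset-trimmed like the signals and
    window-averaged.
    """
    rows = []
    for subj in cohort:
        if measure == "nci":
            series = compute_nci_series(subj, network, grid)
            vals = np.where(series.degenerate, np.nan, series.values)
        elif measure == "activity":
            vals = network_activity_series(subj, network, grid)
        elif measure == "rating":
            if subj.rating is None:
                raise ValueError(f"subject {subj.subject_id} has no rating trace")
            n_trs = grid.n_timepoints + grid.trim
            per_tr = align_to_tr(subj.rating, tr_seconds, n_trs)
            vals = window_rating(trim_onset(per_tr, grid.trim), grid)
        else:
            raise ValueError(f"unknown measure {measure!r}")
        rows.append(vals)
    return np.asarray(rows)


def groupdiff_series(
    cohort: Sequence[SubjectRecord],
    measure: str,
    grid: WindowGrid,
    network: NetworkSpec | None = None,
    span: str = "truncated",
    max_lag: int = 10,
    tr_seconds: float = 3.0,
) -> GroupDiffSeries:
    """Window-wise control-vs-patient rank-sum contrast of one measure.

    Computes the measure for every subject, applies the rank-sum test per
    window (control minus patient), and BH-corrects over the comparison span
    (``"truncated"``: central ``n - 2*max_lag`` windows; ``"full"``: all).
    """
    controls = [s for s in cohort if s.group == "control"]
    patients = [s for s in cohort if s.group == "patient"]
    if len(controls) < 2 or len(patients) < 2:
        raise ValueError("need at least 2 subjects per group")
    mat_c = measure_matrix(controls, measure, grid, network, tr_seconds)
    mat_p = measure_matrix(patients, measure, grid, network, tr_seconds)

    if span == "truncated":
        sel = central_span(grid.n_windows, max_lag)
    elif span == "full":
        sel = slice(None)
    else:
        raise ValueError(f"unknown span {span!r}")
    starts = grid.starts[sel]
    mat_c = mat_c[:, sel]
    mat_p = mat_p[:, sel]

    n_win = mat_c.shape[1]
    z = np.full(n_win, np.nan)
    p = np.full(n_win, np.nan)
    untestable = np.zeros(n_win, dtype=bool)
    clean = np.isfinite(mat_c).all() and np.isfinite(mat_p).all()
    if clean:
        z = ranksum_z_matrix(mat_c, mat_p)
        p = np.minimum(2.0 * stats.norm.sf(np.abs(z)), 1.0)
    else:
        for j in range(n_win):
            a = mat_c[:, j][np.isfinite(mat_c[:, j])]
            b = mat_p[:, j][np.isfinite(mat_p[:, j])]
            if len(a) < 2 or len(b) < 2:
                untestable[j] = True
                continue
            z[j], p[j] = ranksum_z(a, b)
    q = fdr_bh(np.where(untestable, np.nan, p))
    name = measure if network is None else f"{measure}:{network.name}"
    return GroupDiffSeries(
        measure=name,
        window_starts=starts,
        z=z,
        p=p,
        q=q,
        untestable=untestable,
    )
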