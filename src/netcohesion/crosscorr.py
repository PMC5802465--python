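"""Lagged cross-correlation of NCI and rating group differences.

The per-window rank-sum Z series contrasting the groups on network NCI is
cross-correlated (Spearman) with the corresponding Z series for the
continuous rating, at integer window shifts from ``-L`` to ``+L``
(default L = 10).  Every lag is evaluated on the identical central span of
length ``n - 2L`` (131 windows with the defaults), so all 2L+1 = 21
correlations compare equally sized series.  Positive lag means the NCI
series precedes the rating series.

Significance comes from a phase-randomization bootstrap: each iteration
replaces every subject's NCI series by a Fourier surrogate with the same
amplitude spectrum but random phases, recomputes the per-window Z series,
and re-evaluates the 21 lagged correlations, yielding a null that preserves
the autocorrelation structure of the observed series.  Bootstrap p-values
use the ``(#exceedances + 1)/(n_boot + 1)`` correction, two-sided on |rho|,
and are BH-FDR corrected over the 21 lags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .inference import central_span, fdr_bh, ranksum_z_matrix

__all__ = [
    "LagCorrProfile",
    "shift_align",
    "spearman_rho",
    "phase_randomize",
    "crosscorr_bootstrap",
]

logger = logging.getLogger(__name__)


@dataclass
class LagCorrProfile:
    """Spearman rho, bootstrap p and FDR q per lag, plus the peak summary."""

    lags: np.ndarray
    rho: np.ndarray
    p_boot: np.ndarray
    q: np.ndarray
    aligned_length: int
    n_boot: int
    n_discarded: int = 0

    @property
    def peak_lag(self) -> int:
        """Lag of the extremal |rho|."""
        return int(self.lags[np.nanargmax(np.abs(self.rho))])

    @property
    def peak_rho(self) -> float:
        return float(self.rho[np.nanargmax(np.abs(self.rho))])


def shift_align(
    series_x: np.ndarray, series_y: np.ndarray, lag: int, max_lag: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pair ``x[t - lag]`` with ``y[t]`` over the lag-independent central span.

    Both outputs have length ``len - 2*max_lag`` regardless of ``lag``, so
    correlations at different lags are computed on equally sized series.
    Positive lag pairs x's earlier values with y's later values (x precedes y).
    """
    x = np.asarray(series_x, dtype=float)
    y = np.asarray(series_y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if abs(lag) > max_lag:
        raise ValueError(f"|lag| = {abs(lag)} exceeds max lag {max_lag}")
    span = central_span(len(x), max_lag)
    lo, hi = span.start, span.stop
    return x[lo - lag : hi - lag], y[lo:hi]


def spearman_rho(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rank correlation; NaN (flagged undefined) for constant input."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        return float("nan")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def phase_randomize(series: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Fourier surrogate: random phases, identical amplitude spectrum.

    The DC component (and, for even length, the Nyquist component) is kept
    real and untouched, so the surrogate preserves the mean and — by
    Parseval's identity — the variance of the input, while destroying any
    phase-locked temporal structure.  Accepts a 1-D series or a 2-D stack of
    series (randomized independently per row).
    """
    x = np.asarray(series, dtype=float)
    n = x.shape[-1]
    if n < 4:
        raise ValueError("series too short to phase-randomize")
    spec = np.fft.rfft(x, axis=-1)
    n_bins = spec.shape[-1]
    # randomizable bins: exclude DC; exclude Nyquist when n is even
    hi = n_bins - 1 if n % 2 == 0 else n_bins
    phases = rng.uniform(0.0, 2.0 * np.pi, size=spec.shape[:-1] + (hi - 1,))
    out = np.abs(spec).astype(complex)
    out[..., 1:hi] *= np.exp(1j * phases)
    # DC (and Nyquist, where present) keep their original signed real value
    out[..., 0] = spec[..., 0]
    if hi == n_bins - 1:
        out[..., -1] = spec[..., -1]
    return np.fft.irfft(out, n=n, axis=-1)


def crosscorr_bootstrap(
    nci_control: np.ndarray,
    nci_patient: np.ndarray,
    rating_z: np.ndarray,
    max_lag: int = 10,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> LagCorrProfile:
    """Lagged NCI-vs-rating cross-correlation with a phase-randomization null.

    Parameters
    ----------
    nci_control, nci_patient : ndarray, shape (n_subjects, n_windows)
        Per-subject NCI series on the full window grid.  Subjects with any
        non-finite (degenerate) window are dropped with a log message.
    rating_z : ndarray, shape (n_windows,)
        Observed per-window rating group-difference Z series (full span);
        held fixed across bootstrap iterations.
    max_lag : int
        Maximal shift L in window units; 2L+1 lags are evaluated.
    n_boot : int
        Bootstrap iterations (>= 100).

    Returns
    -------
    LagCorrProfile
        Observed rho per lag, bootstrap p per lag
        (``(#{null |rho| >= |observed|} + 1)/(n_boot + 1)``), and BH-FDR q
        over the 2L+1 lags.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = np.random.default_rng(rng)
    rating_z = np.asarray(rating_z, dtype=float)

    def _clean(mat: np.ndarray, label: str) -> np.ndarray:
        mat = np.asarray(mat, dtype=float)
        keep = np.isfinite(mat).all(axis=1)
        if not keep.all():
            logger.warning(
                "dropping %d %s subject(s) with degenerate NCI windows "
                "from the cross-correlation bootstrap",
                int((~keep).sum()), label,
            )
        return mat[keep]

    nci_control = _clean(nci_control, "control")
    nci_patient = _clean(nci_patient, "patient")
    if len(nci_control) < 2 or len(nci_patient) < 2:
        raise ValueError("need at least 2 usable subjects per group")
    n_win = nci_control.shape[1]
    if len(rating_z) != n_win:
        raise ValueError("rating Z series length does not match NCI windows")

    lags = np.arange(-max_lag, max_lag + 1)

    def _profile(z_series: np.ndarray) -> np.ndarray:
        out = np.empty(len(lags))
        for i, lag in enumerate(lags):
            xa, ya = shift_align(z_series, rating_z, int(lag), max_lag)
            out[i] = spearman_rho(xa, ya)
        return out

    z_obs = ranksum_z_matrix(nci_control, nci_patient)
    rho_obs = _profile(z_obs)

    exceed = np.zeros(len(lags))
    used = 0
    discarded = 0
    for _ in range(n_boot):
        sur_c = phase_randomize(nci_control, rng)
        sur_p = phase_randomize(nci_patient, rng)
        z_null = ranksum_z_matrix(sur_c, sur_p)
        if np.ptp(z_null) == 0.0:
            discarded += 1
            logger.warning("discarding bootstrap iteration with constant Z series")
            continue
        rho_null = _profile(z_null)
        exceed += np.abs(rho_null) >= np.abs(rho_obs)
        used += 1
    if used == 0:
        raise RuntimeError("all bootstrap iterations degenerate")
    p_boot = (exceed + 1.0) / (used + 1.0)
    q = fdr_bh(p_boot)
    return LagCorrProfile(
        lags=lags,
        rho=rho_obs,
        p_boot=p_boot,
        q=q,
        aligned_length=n_win - 2 * max_lag,
        n_boot=used,
        n_discarded=discarded,
    )
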