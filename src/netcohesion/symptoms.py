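"""Window-wise association between patients' NCI and PANSS symptom scores.

For each network and PANSS subscale (positive, negative, general) the
Spearman correlation between the patients' NCI values and their subscale
score is computed in every window of the comparison span, and the p-value
series is BH-FDR corrected over that span's window count.  Each
(network, subscale) pair is its own hypothesis family with its own
correction, and no combined correction across families is offered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .inference import central_span, fdr_bh, measure_matrix
from .nci import NetworkSpec
from .signals import SubjectRecord, WindowGrid

__all__ = ["SymptomAssociation", "symptom_corr_series"]

SUBSCALES = ("positive", "negative", "general")

#: fewer testable patients than this in a window makes it untestable
MIN_PATIENTS = 4


@dataclass
class SymptomAssociation:
    """Spearman rho/p/q per window for one network x subscale hypothesis."""

    network: str
    subscale: str
    window_starts: np.ndarray
    rho: np.ndarray
    p: np.ndarray
    q: np.ndarray
    untestable: np.ndarray

    @property
    def peak_window(self) -> int:
        """Window start of the maximal |rho| among testable windows."""
        masked = np.where(self.untestable, np.nan, np.abs(self.rho))
        return int(self.window_starts[np.nanargmax(masked)])

    @property
    def peak_rho(self) -> float:
        masked = np.where(self.untestable, np.nan, np.abs(self.rho))
        return float(self.rho[np.nanargmax(masked)])


def symptom_corr_series(
    patients: Sequence[SubjectRecord],
    network: NetworkSpec,
    subscale: str,
    grid: WindowGrid,
    span: str = "truncated",
    max_lag: int = 10,
) -> SymptomAssociation:
    """Correlate patients' per-window NCI with one PANSS subscale.

    Windows where fewer than four patients have both a finite NCI value and
    a score, or where either variable is constant across patients, are
    flagged untestable and excluded from the FDR correction.
    """
    if subscale not in SUBSCALES:
        raise ValueError(f"unknown PANSS subscale {subscale!r}")
    scores = []
    for subj in patients:
        if subj.symptoms is None or subscale not in subj.symptoms:
            raise ValueError(
                f"patient {subj.subject_id} lacks the {subscale!r} subscore"
            )
        scores.append(float(subj.symptoms[subscale]))
    scores = np.asarray(scores)

    nci = measure_matrix(patients, "nci", grid, network)
    if span == "truncated":
        sel = central_span(grid.n_windows, max_lag)
    elif span == "full":
        sel = slice(None)
    else:
        raise ValueError(f"unknown span {span!r}")
    nci = nci[:, sel]
    starts = grid.starts[sel]

    n_win = nci.shape[1]
    rho = np.full(n_win, np.nan)
    p = np.full(n_win, np.nan)
    untestable = np.zeros(n_win, dtype=bool)
    for j in range(n_win):
        ok = np.isfinite(nci[:, j]) & np.isfinite(scores)
        x, y = nci[ok, j], scores[ok]
        if ok.sum() < MIN_PATIENTS or np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
            untestable[j] = True
            continue
        res = stats.spearmanr(x, y)
        rho[j], p[j] = float(res.statistic), float(res.pvalue)
    q = fdr_bh(np.where(untestable, np.nan, p))
    return SymptomAssociation(
        network=network.name,
        subscale=subscale,
        window_starts=starts,
        rho=rho,
        p=p,
        q=q,
        untestable=untestable,
    )
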