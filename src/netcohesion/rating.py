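"""Continuous emotion-rating traces and their projection onto the NCI grid.

Ratings are acquired at 10 Hz on a 0-21 scale (seven labelled intensity
levels of three units each).  To compare them with the sliding-window NCI
series they are first averaged inside each TR interval (30 samples per 3-s
TR), trimmed identically to the imaging data, and then averaged inside each
sliding window, yielding one rating value per window — 151 with the default
grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signals import WindowGrid

__all__ = ["RatingTrace", "align_to_tr", "window_rating"]

RATING_MIN = 0.0
RATING_MAX = 21.0
RATING_HZ = 10.0


@dataclass
class RatingTrace:
    """A continuous rating trace sampled at 10 Hz on the 0-21 scale."""

    samples: np.ndarray
    hz: float = RATING_HZ

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("rating trace must be 1-D")
        if self.samples.size == 0:
            raise ValueError("empty rating trace")
        if (self.samples < RATING_MIN).any() or (self.samples > RATING_MAX).any():
            raise ValueError(
                f"rating values must lie in [{RATING_MIN:g}, {RATING_MAX:g}]"
            )

    def __len__(self) -> int:
        return len(self.samples)


def align_to_tr(
    trace: RatingTrace, tr_seconds: float, n_trs: int
) -> np.ndarray:
    """Average the 10 Hz rating samples inside each TR interval.

    TR interval ``i`` covers samples ``[i*s, (i+1)*s)`` with
    ``s = hz * tr_seconds`` (30 with the defaults).  The trace must cover the
    full acquisition of ``n_trs`` TRs.
    """
    per_tr = trace.hz * tr_seconds
    if abs(per_tr - round(per_tr)) > 1e-9:
        raise ValueError("TR must be an integer number of rating samples")
    per_tr = int(round(per_tr))
    needed = per_tr * n_trs
    if len(trace) < needed:
        raise ValueError(
            f"rating trace has {len(trace)} samples but {needed} are needed "
            f"to cover {n_trs} TRs at {trace.hz:g} Hz x {tr_seconds:g} s"
        )
    return trace.samples[:needed].reshape(n_trs, per_tr).mean(axis=1)


def window_rating(per_tr: np.ndarray, grid: WindowGrid) -> np.ndarray:
    """Average an (already trimmed) per-TR rating series inside each window.

    The per-TR series must have been trimmed exactly like the node signals,
    so it spans ``grid.n_timepoints`` samples; the result has one value per
    window.
    """
    per_tr = np.asarray(per_tr, dtype=float)
    if per_tr.ndim != 1 or len(per_tr) != grid.n_timepoints:
        raise ValueError(
            f"per-TR series of length {per_tr.shape[-1]} does not match the "
            f"grid span of {grid.n_timepoints} samples"
        )
    return grid.window_view(per_tr).mean(axis=-1)
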