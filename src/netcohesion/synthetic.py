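"""Synthetic cohorts with the statistical structure the analysis assumes.

Node signals follow a shared-factor model: inside a network with
time-varying coupling ``c(t) in [0, 1)``, node ``i`` of a subject in group
``g`` is

    node_i(t) = sqrt(c_g(t)) * f(t) + sqrt(1 - c_g(t)) * eps_i(t),

with ``f`` (the network's common factor) and ``eps_i`` independent
unit-variance innovations.  The expected Pearson correlation between any
two nodes in a span of constant coupling ``c`` is then exactly ``c``, which
makes NCI recovery directly testable.  Innovations are white by default; an
AR(1) switch provides a case with known spectral structure for calibrating
the phase-randomization null.

Group effects are planted as additive offsets on ``c(t)``; by default the
control group's ES coupling is raised during designated "emotional peak"
windows, mirroring the elevated embodied-simulation cohesion the analysis
is designed to detect.  Rating traces (10 Hz, 0-21 scale) are generated so
the group difference tracks the ES coupling difference shifted by
``rating_lag`` TRs (positive lag: coupling precedes rating), and patients'
linked PANSS subscale is a linear function of their NCI in one designated
window plus noise.  All planted parameters are returned as a ground-truth
record for parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .nci import NetworkSpec, compute_nci_series
from .rating import RATING_MAX, RATING_MIN, RatingTrace
from .signals import SubjectRecord, make_window_grid, trim_onset

__all__ = [
    "CouplingProfile",
    "SimConfig",
    "default_networks",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

_COUPLING_CEIL = 1.0 - 1e-9


def default_networks() -> tuple[NetworkSpec, NetworkSpec]:
    """The two default networks: 7-node ToM and 5-node ES."""
    tom = NetworkSpec("ToM", tuple(f"ToM_{i}" for i in range(1, 8)))
    es = NetworkSpec("ES", tuple(f"ES_{i}" for i in range(1, 6)))
    return tom, es


@dataclass
class CouplingProfile:
    """Within-network target correlation per time sample, per group.

    ``base`` is the shared coupling series ``c(t)`` (length T, values in
    [0, 1)); ``group_offsets`` maps a group label to an additive modulation,
    and the effective per-group coupling is clipped back into [0, 1).
    """

    network_name: str
    base: np.ndarray
    group_offsets: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.base = np.asarray(self.base, dtype=float)
        if self.base.ndim != 1:
            raise ValueError("coupling profile must be 1-D")
        if (self.base < 0.0).any() or (self.base >= 1.0).any():
            raise ValueError(
                f"coupling for {self.network_name!r} must lie in [0, 1)"
            )
        self.group_offsets = {
            g: np.broadcast_to(
                np.asarray(off, dtype=float), self.base.shape
            ).copy()
            for g, off in self.group_offsets.items()
        }

    def coupling(self, group: str) -> np.ndarray:
        """Effective coupling series for ``group``, clipped into [0, 1)."""
        c = self.base + self.group_offsets.get(group, 0.0)
        return np.clip(c, 0.0, _COUPLING_CEIL)

    @classmethod
    def windows_boost(
        cls,
        network_name: str,
        T: int,
        baseline: float,
        boosted: float,
        window_range: tuple[int, int],
        group: str = "control",
        trim: int = 5,
        window: int = 10,
    ) -> "CouplingProfile":
        """Constant baseline with ``group`` boosted over a window range.

        ``window_range = (w_lo, w_hi)`` (inclusive, start indices on the
        trimmed grid) boosts exactly the samples those windows cover:
        original samples ``[w_lo + trim, w_hi + trim + window)``.
        """
        base = np.full(T, float(baseline))
        offset = np.zeros(T)
        w_lo, w_hi = window_range
        offset[w_lo + trim : w_hi + trim + window] = boosted - baseline
        return cls(network_name, base, {group: offset})


@dataclass
class SimConfig:
    """Cohort-generation parameters; the defaults are the study conditions.

    Two groups of 25 subjects, a 165-TR acquisition at 3 s/TR, a 7-node ToM
    and a 5-node ES network.  ES coupling is 0.2 at baseline and raised to
    0.6 for controls during windows 40-70 (the "emotional peak"); ToM
    coupling is 0.2 for both groups.  The rating group difference follows
    the ES coupling difference with a +10 TR lag, and patients' general
    PANSS subscore is linearly linked to their ToM NCI at window 30.
    """

    n_per_group: int = 25
    T: int = 165
    tr_seconds: float = 3.0
    networks: tuple[tuple[str, int], ...] = (("ToM", 7), ("ES", 5))
    coupling: dict[str, CouplingProfile] | None = None
    es_boost: tuple[float, float, int, int] = (0.2, 0.6, 40, 70)
    rating_lag: int = 10
    rating_gain: float = 10.0
    rating_noise_sd: float = 1.5
    symptom_link: tuple[str, str, int, float, float] = ("ToM", "general", 30, 6.0, 3.0)
    symptom_intercept: float = 40.0
    trim: int = 5
    window: int = 10
    step: int = 1
    ar1_phi: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.T < self.window + self.trim:
            raise ValueError("T must cover trim + one window")
        for name, n_nodes in self.networks:
            if n_nodes < 3:
                raise ValueError(f"network {name!r} needs at least 3 nodes")
        if self.rating_noise_sd <= 0.0:
            raise ValueError("rating_noise_sd must be positive")
        if self.symptom_link[4] <= 0.0:
            raise ValueError("symptom noise sd must be positive")
        if not -1.0 < self.ar1_phi < 1.0:
            raise ValueError("ar1_phi must lie in (-1, 1)")
        if self.coupling is None:
            lo, hi, w_lo, w_hi = self.es_boost
            profiles = {}
            for name, _ in self.networks:
                if name == "ES":
                    profiles[name] = CouplingProfile.windows_boost(
                        name, self.T, lo, hi, (w_lo, w_hi),
                        trim=self.trim, window=self.window,
                    )
                else:
                    profiles[name] = CouplingProfile(name, np.full(self.T, lo))
            self.coupling = profiles
        for name, _ in self.networks:
            if name not in self.coupling:
                raise ValueError(f"no coupling profile for network {name!r}")
            if len(self.coupling[name].base) != self.T:
                raise ValueError(
                    f"coupling profile for {name!r} has length "
                    f"{len(self.coupling[name].base)}, expected T={self.T}"
                )

    def network_specs(self) -> list[NetworkSpec]:
        return [
            NetworkSpec(name, tuple(f"{name}_{i}" for i in range(1, n + 1)))
            for name, n in self.networks
        ]


def _innovations(
    rng: np.random.Generator, shape: tuple[int, ...], phi: float
) -> np.ndarray:
    """Unit-variance innovations, white or stationary AR(1)."""
    white = rng.standard_normal(shape)
    if phi == 0.0:
        return white
    out = np.empty_like(white)
    out[..., 0] = white[..., 0]
    scale = np.sqrt(1.0 - phi**2)
    for t in range(1, shape[-1]):
        out[..., t] = phi * out[..., t - 1] + scale * white[..., t]
    return out


def _smooth_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """Temporally smooth zero-mean noise with standard deviation ``sd``."""
    raw = rng.standard_normal(n + 40)
    kernel = np.exp(-0.5 * (np.arange(-20, 21) / 10.0) ** 2)
    kernel /= kernel.sum()
    smooth = np.convolve(raw, kernel, mode="same")[20:-20]
    s = smooth.std()
    return smooth / s * sd if s > 0 else smooth


def _rating_base(T: int) -> np.ndarray:
    """Shared movie-driven rating profile on the TR grid (two broad peaks)."""
    t = np.arange(T)
    return (
        6.0
        + 3.0 * np.exp(-0.5 * ((t - 60) / 15.0) ** 2)
        + 3.0 * np.exp(-0.5 * ((t - 120) / 12.0) ** 2)
    )


def generate_cohort(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[SubjectRecord], dict]:
    """Simulate a two-group cohort plus its ground-truth record.

    Returns ``(subjects, ground_truth)``; subjects carry full-length
    (untrimmed) signals, a 10 Hz rating trace, and — for patients — PANSS
    subscores whose linked subscale is ``intercept + slope * NCI(window) +
    noise``.  The ground truth holds the per-group coupling series, the
    planted rating lag and the symptom-link parameters.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    specs = config.network_specs()
    samples_per_tr = int(round(10.0 * config.tr_seconds))
    n_rating = samples_per_tr * config.T

    # rating group difference tracks the ES coupling difference, delayed by
    # rating_lag TRs (positive lag: coupling change precedes rating change)
    if "ES" in dict(config.networks):
        prof = config.coupling["ES"]
        c_diff = prof.coupling("control") - prof.coupling("patient")
    else:
        c_diff = np.zeros(config.T)
    d_shift = np.zeros(config.T)
    lag = config.rating_lag
    if lag >= 0:
        d_shift[lag:] = c_diff[: config.T - lag]
    else:
        d_shift[:lag] = c_diff[-lag:]
    base_tr = _rating_base(config.T)

    subjects: list[SubjectRecord] = []
    for group, prefix in (("control", "C"), ("patient", "P")):
        for i in range(config.n_per_group):
            sid = f"{prefix}{i + 1:03d}"
            blocks, labels = [], []
            for spec in specs:
                c = config.coupling[spec.name].coupling(group)
                f = _innovations(rng, (config.T,), config.ar1_phi)
                eps = _innovations(
                    rng, (spec.n_nodes, config.T), config.ar1_phi
                )
                blocks.append(np.sqrt(c) * f + np.sqrt(1.0 - c) * eps)
                labels.extend(spec.nodes)
            signals = np.vstack(blocks)

            per_tr = base_tr + (config.rating_gain * d_shift
                                if group == "control" else 0.0)
            trace = np.repeat(per_tr, samples_per_tr)
            trace = trace + _smooth_noise(rng, n_rating, config.rating_noise_sd)
            trace = np.clip(trace, RATING_MIN, RATING_MAX)

            subjects.append(
                SubjectRecord(
                    subject_id=sid,
                    group=group,
                    node_labels=labels,
                    signals=signals,
                    rating=RatingTrace(trace),
                )
            )

    # patient symptom scores from their NCI at the designated window
    net_name, subscale, link_window, slope, noise_sd = config.symptom_link
    grid = make_window_grid(
        config.T - config.trim, config.window, config.step, config.trim
    )
    spec_by_name = {s.name: s for s in specs}
    for subj in subjects:
        if subj.group != "patient":
            continue
        trimmed = SubjectRecord(
            subject_id=subj.subject_id,
            group=subj.group,
            node_labels=subj.node_labels,
            signals=trim_onset(subj.signals, config.trim),
        )
        series = compute_nci_series(trimmed, spec_by_name[net_name], grid)
        nci_at = float(series.values[link_window])
        symptoms = {
            "positive": float(np.clip(rng.normal(20.0, 4.0), 7, 49)),
            "negative": float(np.clip(rng.normal(20.0, 4.0), 7, 49)),
            "general": float(np.clip(rng.normal(40.0, 6.0), 16, 112)),
        }
        symptoms[subscale] = float(
            config.symptom_intercept + slope * nci_at + rng.normal(0.0, noise_sd)
        )
        subj.symptoms = symptoms

    ground_truth = {
        "coupling": {
            name: {
                "control": config.coupling[name].coupling("control").tolist(),
                "patient": config.coupling[name].coupling("patient").tolist(),
            }
            for name, _ in config.networks
        },
        "rating_lag": config.rating_lag,
        "rating_gain": config.rating_gain,
        "symptom_link": {
            "network": net_name,
            "subscale": subscale,
            "window": link_window,
            "slope": slope,
            "noise_sd": noise_sd,
            "intercept": config.symptom_intercept,
        },
        "ar1_phi": config.ar1_phi,
        "seed": config.seed,
    }
    return subjects, ground_truth


def write_cohort(
    cohort: Sequence[SubjectRecord],
    directory: str | Path,
    ground_truth: dict | None = None,
) -> None:
    """Write a cohort as TSV files plus a JSON ground-truth sidecar.

    Per subject: ``<id>_signals.tsv`` (rows = labelled nodes, columns =
    time samples) and, if present, ``<id>_rating.tsv`` (time_seconds,
    rating).  One ``manifest.tsv`` lists subject_id, group and the PANSS
    subscores.  Values round-trip bit-exactly through :func:`read_cohort`.
    """
    if len(cohort) == 0:
        raise ValueError("cannot write an empty cohort")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for subj in cohort:
        df = pd.DataFrame(
            subj.signals,
            index=list(subj.node_labels),
            columns=[f"t{t}" for t in range(subj.n_timepoints)],
        )
        df.index.name = "node"
        # %.17g round-trips float64 bit-exactly through the text format
        df.to_csv(
            directory / f"{subj.subject_id}_signals.tsv", sep="\t",
            float_format="%.17g",
        )
        if subj.rating is not None:
            times = np.arange(len(subj.rating)) / subj.rating.hz
            pd.DataFrame(
                {"time_seconds": times, "rating": subj.rating.samples}
            ).to_csv(
                directory / f"{subj.subject_id}_rating.tsv", sep="\t",
                index=False, float_format="%.17g",
            )
        sym = subj.symptoms or {}
        manifest_rows.append(
            {
                "subject_id": subj.subject_id,
                "group": subj.group,
                "panss_positive": sym.get("positive"),
                "panss_negative": sym.get("negative"),
                "panss_general": sym.get("general"),
            }
        )
    pd.DataFrame(manifest_rows).to_csv(
        directory / "manifest.tsv", sep="\t", index=False, float_format="%.17g"
    )
    if ground_truth is not None:
        with open(directory / "ground_truth.json", "w") as fh:
            json.dump(ground_truth, fh, indent=1)


def read_cohort(directory: str | Path) -> tuple[list[SubjectRecord], dict | None]:
    """Read a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    manifest_path = directory / "manifest.tsv"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.tsv in {directory}")
    try:
        manifest = pd.read_csv(
            manifest_path, sep="\t", float_precision="round_trip"
        )
        _ = manifest["subject_id"], manifest["group"]
    except (KeyError, pd.errors.ParserError) as exc:
        raise ValueError(f"corrupted manifest {manifest_path}: {exc}") from exc
    subjects = []
    for row in manifest.itertuples(index=False):
        sig = pd.read_csv(
            directory / f"{row.subject_id}_signals.tsv", sep="\t",
            index_col="node", float_precision="round_trip",
        )
        rating = None
        rating_path = directory / f"{row.subject_id}_rating.tsv"
        if rating_path.exists():
            rdf = pd.read_csv(rating_path, sep="\t",
                              float_precision="round_trip")
            rating = RatingTrace(rdf["rating"].to_numpy())
        symptoms = None
        sym = {
            "positive": row.panss_positive,
            "negative": row.panss_negative,
            "general": row.panss_general,
        }
        if all(pd.notna(v) for v in sym.values()):
            symptoms = {k: float(v) for k, v in sym.items()}
        subjects.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                group=str(row.group),
                node_labels=list(sig.index),
                signals=sig.to_numpy(),
                symptoms=symptoms,
                rating=rating,
            )
        )
    gt_path = directory / "ground_truth.json"
    ground_truth = None
    if gt_path.exists():
        with open(gt_path) as fh:
            ground_truth = json.load(fh)
    return subjects, ground_truth
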