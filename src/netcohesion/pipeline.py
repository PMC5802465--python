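"""One-shot orchestration of the full analysis from a single configuration.

Stages run in dependency order on a cohort directory: NCI computation,
window-wise group contrasts (NCI, rating, and the amplitude control),
lagged cross-correlation with the phase-randomization bootstrap, symptom
association, and KNN classification.  Every output carries a provenance
header (config hash, master seed, package version), and a master seed is
split into independent per-stage substreams so stages are individually
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import build_feature_matrix, permutation_test
from .crosscorr import crosscorr_bootstrap
from .inference import central_span, groupdiff_series, measure_matrix
from .nci import NetworkSpec, compute_nci_series
from .signals import SubjectRecord, make_window_grid, trim_onset
from .symptoms import SUBSCALES, symptom_corr_series
from .synthetic import read_cohort

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

ALL_STAGES = ("nci", "groupdiff", "xcorr", "symptoms", "classify")

_STAGE_SEED_OFFSET = {name: i for i, name in enumerate(ALL_STAGES)}


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    cohort_dir: str
    output_dir: str
    trim: int = 5
    window: int = 10
    step: int = 1
    tr_seconds: float = 3.0
    max_lag: int = 10
    span: str = "truncated"
    n_boot: int = 1000
    knn_k: int = 10
    knn_folds: int = 5
    knn_repetitions: int = 1000
    n_permutations: int = 1000
    perm_repetitions: int = 50
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if self.window < 2 or self.step < 1 or self.trim < 0:
            raise ValueError("invalid window grid parameters")
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded)."""
        params = {k: v for k, v in asdict(self).items()
                  if k not in ("cohort_dir", "output_dir")}
        blob = json.dumps(params, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _provenance(config: RunConfig) -> str:
    return (
        f"# netcohesion {__version__} config_hash={config.config_hash()} "
        f"seed={config.seed}\n"
    )


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(config))
        df.to_csv(fh, sep="\t", index=False)


def _stage_rng(config: RunConfig, stage: str) -> np.random.Generator:
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(ALL_STAGES))
    return np.random.default_rng(children[_STAGE_SEED_OFFSET[stage]])


def run_pipeline(
    config: RunConfig, cohort: Sequence[SubjectRecord] | None = None
) -> dict:
    """Execute the configured stages and return the machine-readable summary.

    ``cohort`` may be passed directly (untrimmed signals); otherwise it is
    read from ``config.cohort_dir``.  Any stage failure aborts with an error
    naming the stage.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        cohort, _ = read_cohort(config.cohort_dir)
    if not cohort:
        raise ValueError(f"empty cohort in {config.cohort_dir}")

    T = cohort[0].n_timepoints
    grid = make_window_grid(T - config.trim, config.window, config.step, config.trim)
    trimmed = [
        SubjectRecord(
            subject_id=s.subject_id,
            group=s.group,
            node_labels=s.node_labels,
            signals=trim_onset(s.signals, config.trim),
            symptoms=s.symptoms,
            rating=s.rating,
        )
        for s in cohort
    ]
    node_sets = {lab.split("_")[0] for s in trimmed for lab in s.node_labels}
    networks = [
        NetworkSpec(
            name,
            tuple(sorted(
                (lab for lab in trimmed[0].node_labels
                 if lab.split("_")[0] == name),
                key=lambda lab: int(lab.split("_")[1]),
            )),
        )
        for name in sorted(node_sets)
    ]

    summary: dict = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "version": __version__,
        "n_subjects": len(trimmed),
        "n_windows": grid.n_windows,
        "n_lags": 2 * config.max_lag + 1,
        "networks": [n.name for n in networks],
        "stages_run": [],
    }

    nci_all: dict[str, dict] = {}
    try:
        if "nci" in config.stages:
            rows = []
            for subj in trimmed:
                nci_all[subj.subject_id] = {}
                for net in networks:
                    series = compute_nci_series(subj, net, grid)
                    nci_all[subj.subject_id][net.name] = series
                    for w, v, d in zip(
                        grid.starts, series.values, series.degenerate
                    ):
                        rows.append(
                            (subj.subject_id, net.name, int(w), v, bool(d))
                        )
            _write_tsv(
                pd.DataFrame(
                    rows,
                    columns=["subject_id", "network", "window_start",
                             "nci", "degenerate_flag"],
                ),
                out_dir / "nci.tsv",
                config,
            )
            summary["stages_run"].append("nci")
    except Exception as exc:
        raise RuntimeError(f"stage 'nci' failed: {exc}") from exc

    has_rating = all(s.rating is not None for s in trimmed)
    net_by_name = {n.name: n for n in networks}

    try:
        if "groupdiff" in config.stages:
            sig_intervals = {}
            contrasts = [("nci", n) for n in networks]
            contrasts += [("activity", n) for n in networks]
            if has_rating:
                contrasts.append(("rating", None))
            for measure, net in contrasts:
                gd = groupdiff_series(
                    trimmed, measure, grid, net,
                    span=config.span, max_lag=config.max_lag,
                    tr_seconds=config.tr_seconds,
                )
                _write_tsv(
                    pd.DataFrame(
                        {
                            "window_start": gd.window_starts,
                            "z": gd.z,
                            "p": gd.p,
                            "q": gd.q,
                            "untestable": gd.untestable,
                        }
                    ),
                    out_dir / f"groupdiff_{gd.measure.replace(':', '_')}.tsv",
                    config,
                )
                sig_intervals[gd.measure] = [
                    int(w) for w in gd.significant_windows()
                ]
            summary["groupdiff_significant_windows"] = sig_intervals
            summary["stages_run"].append("groupdiff")
    except Exception as exc:
        raise RuntimeError(f"stage 'groupdiff' failed: {exc}") from exc

    try:
        if "xcorr" in config.stages:
            if not has_rating:
                raise ValueError("cross-correlation requires rating traces")
            rng = _stage_rng(config, "xcorr")
            controls = [s for s in trimmed if s.group == "control"]
            patients = [s for s in trimmed if s.group == "patient"]
            rating_gd = groupdiff_series(
                trimmed, "rating", grid, span="full",
                max_lag=config.max_lag, tr_seconds=config.tr_seconds,
            )
            xcorr_summary = {}
            for net in networks:
                mat_c = measure_matrix(controls, "nci", grid, net)
                mat_p = measure_matrix(patients, "nci", grid, net)
                profile = crosscorr_bootstrap(
                    mat_c, mat_p, rating_gd.z,
                    max_lag=config.max_lag, n_boot=config.n_boot, rng=rng,
                )
                _write_tsv(
                    pd.DataFrame(
                        {
                            "lag": profile.lags,
                            "rho": profile.rho,
                            "p_boot": profile.p_boot,
                            "q": profile.q,
                        }
                    ),
                    out_dir / f"xcorr_{net.name}.tsv",
                    config,
                )
                xcorr_summary[net.name] = {
                    "peak_lag": profile.peak_lag,
                    "peak_rho": profile.peak_rho,
                    "peak_q": float(
                        profile.q[np.nanargmax(np.abs(profile.rho))]
                    ),
                    "aligned_length": profile.aligned_length,
                }
            summary["xcorr"] = xcorr_summary
            summary["stages_run"].append("xcorr")
    except Exception as exc:
        raise RuntimeError(f"stage 'xcorr' failed: {exc}") from exc

    try:
        if "symptoms" in config.stages:
            patients = [s for s in trimmed if s.group == "patient"]
            with_scores = [p for p in patients if p.symptoms is not None]
            sym_summary = {}
            for net in networks:
                for subscale in SUBSCALES:
                    assoc = symptom_corr_series(
                        with_scores, net, subscale, grid,
                        span=config.span, max_lag=config.max_lag,
                    )
                    _write_tsv(
                        pd.DataFrame(
                            {
                                "window_start": assoc.window_starts,
                                "rho": assoc.rho,
                                "p": assoc.p,
                                "q": assoc.q,
                                "untestable": assoc.untestable,
                            }
                        ),
                        out_dir / f"symptoms_{net.name}_{subscale}.tsv",
                        config,
                    )
                    sym_summary[f"{net.name}:{subscale}"] = {
                        "peak_window": assoc.peak_window,
                        "peak_rho": assoc.peak_rho,
                        "n_q_significant": int(
                            np.sum(~assoc.untestable & (assoc.q <= 0.05))
                        ),
                    }
            summary["symptoms"] = sym_summary
            summary["stages_run"].append("symptoms")
    except Exception as exc:
        raise RuntimeError(f"stage 'symptoms' failed: {exc}") from exc

    try:
        if "classify" in config.stages:
            if not nci_all:
                for subj in trimmed:
                    nci_all[subj.subject_id] = {
                        net.name: compute_nci_series(subj, net, grid)
                        for net in networks
                    }
            rng = _stage_rng(config, "classify")
            order = [n for n in ("ES", "ToM") if n in net_by_name] or [
                n.name for n in networks
            ]
            X, y, ids = build_feature_matrix(
                nci_all, order, {s.subject_id: s.group for s in trimmed}
            )
            report = permutation_test(
                X, y,
                k=config.knn_k, folds=config.knn_folds,
                repetitions=config.knn_repetitions,
                n_permutations=config.n_permutations,
                perm_repetitions=config.perm_repetitions,
                rng=rng,
            )
            result = {"n_features": X.shape[1], **report.summary(),
                      "config": report.config}
            with open(out_dir / "classification.json", "w") as fh:
                json.dump(
                    {"provenance": _provenance(config).strip("#\n "),
                     **result},
                    fh, indent=1,
                )
            summary["classification"] = result
            summary["stages_run"].append("classify")
    except Exception as exc:
        raise RuntimeError(f"stage 'classify' failed: {exc}") from exc

    with open(out_dir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    return summary
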