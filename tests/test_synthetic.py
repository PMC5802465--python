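"""Synthetic cohort generator: planted structure, determinism, round-trips."""

import numpy as np
import pytest

from netcohesion import (
    CouplingProfile,
    SimConfig,
    SubjectRecord,
    generate_cohort,
    make_window_grid,
    pairwise_correlations,
    read_cohort,
    write_cohort,
)
from netcohesion.nci import compute_nci_series
from netcohesion.signals import trim_onset
from netcohesion.synthetic import default_networks


def constant_coupling_config(c, n_per_group=10, seed=0, **kw):
    T = kw.pop("T", 165)
    profiles = {
        name: CouplingProfile(name, np.full(T, c))
        for name in ("ToM", "ES")
    }
    return SimConfig(
        n_per_group=n_per_group, T=T, coupling=profiles, seed=seed,
        rating_gain=0.0, **kw,
    )


class TestConfigValidation:
    def test_coupling_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\)"):
            CouplingProfile("ES", np.full(165, 1.0))

    def test_nonpositive_noise_sd_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            SimConfig(rating_noise_sd=0.0)
        with pytest.raises(ValueError, match="sd"):
            SimConfig(symptom_link=("ToM", "general", 30, 6.0, -1.0))

    def test_single_subject_group_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_per_group=1)

    def test_offsets_clipped_into_unit_interval(self):
        prof = CouplingProfile(
            "ES", np.full(10, 0.8), {"control": np.full(10, 0.5)}
        )
        c = prof.coupling("control")
        assert (c < 1.0).all() and (c >= 0.0).all()


class TestPlantedCorrelationStructure:
    def test_zero_coupling_gives_near_zero_correlation_and_nci(self):
        cohort, _ = generate_cohort(constant_coupling_config(0.0, seed=7))
        _, es = default_networks()
        grid = make_window_grid(160)
        rs, ncis = [], []
        for subj in cohort:
            mat = trim_onset(subj.node_matrix(es.nodes), 5)
            for start in range(0, 160, 10):
                rs.append(pairwise_correlations(mat[:, start:start + 10]).mean())
            series = compute_nci_series(
                SubjectRecord(subj.subject_id, subj.group, es.nodes, mat),
                es, grid,
            )
            ncis.append(np.nanmean(np.where(series.degenerate, np.nan,
                                            series.values)))
        assert abs(np.mean(rs)) < 0.05
        assert abs(np.mean(ncis)) < 0.2

    def test_constant_coupling_recovered_within_monte_carlo_band(self, rng):
        """Mean within-window pair correlation matches an independent
        Monte-Carlo oracle for the shared-factor model at c = 0.8."""
        c = 0.8
        # oracle: direct simulation of the factor model, >= 10^4 windows
        n_mc = 12000
        f = rng.standard_normal((n_mc, 10))
        e = rng.standard_normal((2, n_mc, 10))
        x = np.sqrt(c) * f + np.sqrt(1 - c) * e
        xc = x - x.mean(axis=-1, keepdims=True)
        num = (xc[0] * xc[1]).sum(axis=-1)
        den = np.sqrt((xc[0] ** 2).sum(-1) * (xc[1] ** 2).sum(-1))
        oracle_mean = (num / den).mean()  # finite-window E[r], slightly < c
        oracle_se = (num / den).std() / np.sqrt(n_mc)

        cohort, _ = generate_cohort(
            constant_coupling_config(c, n_per_group=50, seed=21)
        )
        _, es = default_networks()
        rs = []
        for subj in cohort:
            mat = trim_onset(subj.node_matrix(es.nodes), 5)
            for start in range(0, 160, 10):
                rs.append(pairwise_correlations(mat[:, start:start + 10]).mean())
        est = np.mean(rs)
        # cohort windows/pairs are correlated; allow a generous multiple of
        # the oracle's standard error plus the oracle's own uncertainty
        assert est == pytest.approx(oracle_mean, abs=10 * oracle_se + 0.01)
        assert abs(est - c) < 0.05  # and the target coupling itself

    def test_rating_traces_respect_scale(self):
        cohort, _ = generate_cohort(SimConfig(n_per_group=5, seed=3))
        for subj in cohort:
            assert subj.rating.samples.min() >= 0.0
            assert subj.rating.samples.max() <= 21.0

    def test_symptom_link_ground_truth_reproducible(self):
        config = SimConfig(
            n_per_group=8, seed=5, symptom_link=("ToM", "general", 30, 6.0, 0.1)
        )
        cohort, truth = generate_cohort(config)
        assert truth["symptom_link"]["window"] == 30
        tom, _ = default_networks()
        grid = make_window_grid(160)
        patients = [s for s in cohort if s.group == "patient"]
        ncis = []
        for subj in patients:
            mat = trim_onset(subj.node_matrix(tom.nodes), 5)
            series = compute_nci_series(
                SubjectRecord(subj.subject_id, subj.group, tom.nodes, mat),
                tom, grid,
            )
            ncis.append(series.values[30])
        scores = [s.symptoms["general"] for s in patients]
        # scores = intercept + slope * NCI + small noise
        slope_hat = np.polyfit(ncis, scores, 1)[0]
        assert slope_hat == pytest.approx(6.0, abs=0.5)

    def test_ar1_innovations_keep_unit_variance(self):
        cohort, _ = generate_cohort(
            constant_coupling_config(0.0, n_per_group=20, seed=9, ar1_phi=0.5)
        )
        pooled = np.concatenate([s.signals.ravel() for s in cohort])
        assert pooled.var() == pytest.approx(1.0, abs=0.05)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        a, _ = generate_cohort(SimConfig(n_per_group=3, seed=42))
        b, _ = generate_cohort(SimConfig(n_per_group=3, seed=42))
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.signals, sb.signals)
            assert np.array_equal(sa.rating.samples, sb.rating.samples)

    def test_different_seeds_differ(self):
        a, _ = generate_cohort(SimConfig(n_per_group=3, seed=1))
        b, _ = generate_cohort(SimConfig(n_per_group=3, seed=2))
        assert not np.array_equal(a[0].signals, b[0].signals)


class TestCohortIo:
    def test_round_trip_identity(self, tmp_path):
        cohort, truth = generate_cohort(SimConfig(n_per_group=3, seed=8))
        write_cohort(cohort, tmp_path, truth)
        back, truth_back = read_cohort(tmp_path)
        assert len(back) == len(cohort)
        for orig, loaded in zip(cohort, back):
            assert loaded.subject_id == orig.subject_id
            assert loaded.group == orig.group
            assert list(loaded.node_labels) == list(orig.node_labels)
            assert np.array_equal(loaded.signals, orig.signals)
            assert np.array_equal(loaded.rating.samples, orig.rating.samples)
            if orig.symptoms is not None:
                assert loaded.symptoms == orig.symptoms
        assert truth_back["rating_lag"] == truth["rating_lag"]

    def test_empty_cohort_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="empty"):
            write_cohort([], tmp_path)

    def test_single_subject_manifest(self, tmp_path, rng):
        subj = SubjectRecord(
            "S1", "control", ["A", "B", "C"], rng.standard_normal((3, 20))
        )
        write_cohort([subj], tmp_path)
        manifest = (tmp_path / "manifest.tsv").read_text().strip().splitlines()
        assert len(manifest) == 2  # header + one row

    def test_missing_manifest_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="manifest"):
            read_cohort(tmp_path)
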