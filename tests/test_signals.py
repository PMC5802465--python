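"""Signal preparation and sliding-window grid."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from netcohesion import (
    load_nifti_nodes,
    NetworkSpec,
    SubjectRecord,
    extract_node_signal,
    make_window_grid,
    network_activity_series,
    scale_by_global_mean,
    trim_onset,
)
from conftest import make_subject


class TestScaleByGlobalMean:
    def test_constant_matrix_becomes_ones(self):
        out = scale_by_global_mean(np.full((4, 6), 7.0))
        assert np.array_equal(out, np.ones((4, 6)))

    def test_single_column(self):
        out = scale_by_global_mean(np.array([[2.0], [4.0]]))
        assert np.allclose(out[:, 0], [2 / 3, 4 / 3])

    def test_every_column_mean_is_one(self, rng):
        out = scale_by_global_mean(rng.lognormal(size=(50, 20)))
        assert np.allclose(out.mean(axis=0), 1.0, atol=1e-12)

    def test_zero_mean_column_names_time_index(self):
        mat = np.ones((2, 3))
        mat[:, 1] = [1.0, -1.0]
        with pytest.raises(ValueError, match="time index 1"):
            scale_by_global_mean(mat)


class TestExtractNodeSignal:
    def test_single_voxel_identity(self, rng):
        mat = rng.standard_normal((5, 8))
        assert np.array_equal(extract_node_signal(mat, [3]), mat[3])

    def test_duplicated_voxel_same_series(self, rng):
        mat = rng.standard_normal((5, 8))
        assert np.allclose(extract_node_signal(mat, [2, 2]), mat[2])

    def test_matches_loop_oracle(self, rng):
        mat = rng.standard_normal((30, 12))
        mask = [0, 3, 5, 7, 9, 11, 14, 20, 22, 29]
        oracle = np.array(
            [np.mean([mat[v, t] for v in mask]) for t in range(12)]
        )
        assert np.allclose(extract_node_signal(mat, mask), oracle, atol=1e-12)

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            extract_node_signal(rng.standard_normal((4, 5)), [])


class TestTrimOnset:
    def test_acquisition_length_after_default_trim(self, rng):
        assert trim_onset(rng.standard_normal(165), 5).shape == (160,)

    def test_zero_trim_is_identity(self, rng):
        x = rng.standard_normal(10)
        assert np.array_equal(trim_onset(x, 0), x)

    def test_trimming_everything_rejected(self):
        with pytest.raises(ValueError):
            trim_onset(np.arange(5.0), 5)

    def test_matrix_trim_drops_leading_columns(self, rng):
        mat = rng.standard_normal((3, 20))
        assert np.array_equal(trim_onset(mat, 4), mat[:, 4:])


class TestWindowGrid:
    @pytest.mark.parametrize(
        "T,window,step,expected",
        [(160, 10, 1, 151), (10, 10, 1, 1), (20, 10, 5, 3)],
    )
    def test_window_counts(self, T, window, step, expected):
        assert make_window_grid(T, window, step).n_windows == expected

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            make_window_grid(8, window=10)

    @given(
        T=st.integers(1, 200),
        window=st.integers(1, 200),
        step=st.integers(1, 20),
    )
    def test_count_matches_exhaustive_enumeration(self, T, window, step):
        if window > T:
            with pytest.raises(ValueError):
                make_window_grid(T, window, step)
            return
        grid = make_window_grid(T, window, step)
        starts = [s for s in range(0, T, step) if s + window <= T]
        assert grid.n_windows == len(starts)
        assert list(grid.starts) == starts
        for sl in grid.slices():
            assert 0 <= sl.start and sl.stop <= T

    def test_window_view_matches_slicing(self, rng):
        grid = make_window_grid(30, 10, 3)
        x = rng.standard_normal(30)
        view = grid.window_view(x)
        for i, sl in enumerate(grid.slices()):
            assert np.array_equal(view[i], x[sl])


class TestNetworkActivitySeries:
    def test_matches_two_stage_loop_oracle(self, rng, es_network, default_grid):
        subj = make_subject(rng, n_nodes=5, T=160)
        got = network_activity_series(subj, es_network, default_grid)
        # independent oracle: explicit z-score, node average, window average
        zscored = []
        for row in subj.signals:
            zscored.append((row - row.mean()) / row.std())
        pooled = np.mean(zscored, axis=0)
        oracle = np.array(
            [pooled[s : s + 10].mean() for s in range(151)]
        )
        assert np.allclose(got, oracle, atol=1e-12)

    def test_antisymmetric_nodes_cancel(self, rng, default_grid):
        base = rng.standard_normal(160)
        third = rng.standard_normal(160)
        subj = SubjectRecord(
            "S1", "control", ["N_1", "N_2", "N_3"],
            np.vstack([base, -base, third]),
        )
        net = NetworkSpec("N", ("N_1", "N_2", "N_3"))
        got = network_activity_series(subj, net, default_grid)
        # z-scoring makes node 2 the exact negative of node 1; the third
        # node's z-score alone survives the average
        third_z = (third - third.mean()) / third.std()
        oracle = np.array([third_z[s : s + 10].mean() / 3 for s in range(151)])
        assert np.allclose(got, oracle, atol=1e-12)

    def test_flat_node_is_named_in_error(self, rng, default_grid):
        sig = rng.standard_normal((3, 160))
        sig[1] = 2.5
        subj = SubjectRecord("S1", "control", ["N_1", "N_2", "N_3"], sig)
        net = NetworkSpec("N", ("N_1", "N_2", "N_3"))
        with pytest.raises(ValueError, match="N_2"):
            network_activity_series(subj, net, default_grid)


class TestSubjectRecord:
    def test_duplicate_node_labels_rejected(self, rng):
        with pytest.raises(ValueError, match="duplicate"):
            SubjectRecord(
                "S1", "control", ["A", "A"], rng.standard_normal((2, 5))
            )

    def test_non_finite_signals_rejected(self):
        sig = np.ones((3, 4))
        sig[1, 2] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            SubjectRecord("S1", "control", ["A", "B", "C"], sig)

    def test_node_matrix_orders_rows(self, rng):
        sig = rng.standard_normal((3, 5))
        subj = SubjectRecord("S1", "control", ["A", "B", "C"], sig)
        assert np.array_equal(subj.node_matrix(["C", "A"]), sig[[2, 0]])
        with pytest.raises(KeyError, match="S1.*'D'"):
            subj.node_matrix(["D"])


class TestLoadNiftiNodes:
    def _write_pair(self, tmp_path, rng, T=8):
        nib = pytest.importorskip("nibabel")
        bold = rng.lognormal(size=(4, 4, 2, T))
        rois = np.zeros((4, 4, 2), dtype=np.int16)
        rois[0, :2, 0] = 1   # node 1: two voxels
        rois[2, 2:, 1] = 3   # node 3: two voxels
        bold_p, roi_p = tmp_path / "bold.nii", tmp_path / "rois.nii"
        nib.save(nib.Nifti1Image(bold, np.eye(4)), bold_p)
        nib.save(nib.Nifti1Image(rois, np.eye(4)), roi_p)
        return bold, rois, str(bold_p), str(roi_p)

    def test_mask_average_matches_manual_extraction(self, tmp_path, rng):
        bold, rois, bold_p, roi_p = self._write_pair(tmp_path, rng)
        labels, mat = load_nifti_nodes(bold_p, roi_p, scale_global_mean=False)
        assert labels == ["node_1", "node_3"]
        for lab_val, row in zip((1, 3), mat):
            oracle = bold[rois == lab_val, :].mean(axis=0)
            assert np.allclose(row, oracle, atol=1e-12)

    def test_global_mean_scaling_uses_within_mask_mean(self, tmp_path, rng):
        bold, rois, bold_p, roi_p = self._write_pair(tmp_path, rng)
        _, mat = load_nifti_nodes(bold_p, roi_p, scale_global_mean=True)
        scaled = bold[rois > 0, :] / bold[rois > 0, :].mean(axis=0)
        oracle = scaled[rois[rois > 0] == 1].mean(axis=0)
        assert np.allclose(mat[0], oracle, atol=1e-12)

    def test_empty_roi_volume_rejected(self, tmp_path, rng):
        nib = pytest.importorskip("nibabel")
        bold_p, roi_p = tmp_path / "b.nii", tmp_path / "r.nii"
        nib.save(nib.Nifti1Image(rng.lognormal(size=(2, 2, 2, 4)), np.eye(4)),
                 bold_p)
        nib.save(nib.Nifti1Image(np.zeros((2, 2, 2), dtype=np.int16),
                                 np.eye(4)), roi_p)
        with pytest.raises(ValueError, match="no nonzero ROI labels"):
            load_nifti_nodes(str(bold_p), str(roi_p))
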