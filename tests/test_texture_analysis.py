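import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from _oracles import rlm_counts_oracle, rlm_to_dict
from myotex.t2_mapping import fit_t2
from myotex.texture_analysis import (
    DIRECTIONS_13,
    LabelMap,
    RunLengthMatrix,
    TextureConfig,
    hi,
    histogram_entropy,
    muscle_features,
    quantize,
    run_length_matrix,
    sli,
    weighted_composite,
)


class TestQuantize:
    def test_equal_width_bins_by_hand(self):
        vals = np.array([10.0, 20.0, 30.0, 40.0]).reshape(4, 1, 1)
        mask = np.ones((4, 1, 1), bool)
        q = quantize(vals, mask, 2)
        assert q[:, 0, 0].tolist() == [1, 1, 2, 2]

    def test_constant_roi_warns_level_one(self):
        vals = np.full((3, 3, 1), 5.0)
        mask = np.ones((3, 3, 1), bool)
        with pytest.warns(UserWarning, match="constant ROI"):
            q = quantize(vals, mask, 8)
        assert (q[mask] == 1).all()

    def test_out_of_mask_zero(self):
        vals = np.arange(8.0).reshape(2, 2, 2)
        mask = np.zeros((2, 2, 2), bool)
        mask[0] = True
        q = quantize(vals, mask, 4)
        assert (q[~mask] == 0).all()
        assert (q[mask] >= 1).all()

    def test_max_maps_to_top_level(self):
        vals = np.linspace(0, 1, 16).reshape(16, 1, 1)
        q = quantize(vals, np.ones((16, 1, 1), bool), 16)
        assert q.max() == 16

    def test_uniform_occupancy_monte_carlo(self):
        rng = np.random.default_rng(0)
        n = 200_000
        vals = rng.uniform(0, 1, n).reshape(n, 1, 1)
        q = quantize(vals, np.ones((n, 1, 1), bool), 16)
        freq = np.bincount(q.ravel())[1:] / n
        assert np.allclose(freq, 1 / 16, atol=4 * np.sqrt((1 / 16) * (15 / 16) / n) + 1e-4)

    def test_fixed_range(self):
        vals = np.array([35.0, 45.0, 55.0]).reshape(3, 1, 1)
        mask = np.ones((3, 1, 1), bool)
        q = quantize(vals, mask, 4, binning="fixed_range", fixed_range=(30.0, 70.0))
        assert q[:, 0, 0].tolist() == [1, 2, 3]

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            quantize(np.ones((2, 2, 2)), np.zeros((2, 2, 2), bool), 4)

    def test_g_below_two_raises(self):
        with pytest.raises(ValueError, match=">= 2"):
            quantize(np.ones((2, 2, 2)), np.ones((2, 2, 2), bool), 1)


class TestRunLengthMatrix:
    def test_hand_enumeration_1d(self):
        q = np.zeros((3, 1, 1), int)
        q[:, 0, 0] = [1, 1, 2]
        m = np.ones((3, 1, 1), bool)
        rlm = run_length_matrix(q, m, (1, 0, 0))
        assert rlm.n_runs == 2
        assert rlm_to_dict(rlm.counts) == {(1, 2): 1, (2, 1): 1}

    def test_checkerboard_all_length_one(self):
        q = np.indices((4, 4, 4)).sum(axis=0) % 2 + 1
        m = np.ones((4, 4, 4), bool)
        rlm = run_length_matrix(q, m, (1, 0, 0))
        assert rlm.counts.shape[1] == 1
        assert rlm.n_runs == 64

    def test_runs_break_at_mask_boundary(self):
        q = np.ones((5, 1, 1), int)
        m = np.ones((5, 1, 1), bool)
        m[2] = False  # hole splits one run into two
        rlm = run_length_matrix(q, m, (1, 0, 0))
        assert rlm_to_dict(rlm.counts) == {(1, 2): 2}

    def test_direction_validation(self):
        q = np.ones((2, 2, 2), int)
        m = np.ones((2, 2, 2), bool)
        with pytest.raises(ValueError):
            run_length_matrix(q, m, (0, 0, 0))
        with pytest.raises(ValueError):
            run_length_matrix(q, m, (2, 0, 0))

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            run_length_matrix(np.ones((2, 2, 2), int), np.zeros((2, 2, 2), bool), (1, 0, 0))

    @pytest.mark.parametrize("direction", DIRECTIONS_13)
    def test_random_volume_matches_oracle(self, direction):
        rng = np.random.default_rng(hash(direction) % 2**32)
        q = rng.integers(1, 5, size=(8, 8, 8))
        mask = rng.random((8, 8, 8)) < 0.8
        mask.flat[0] = True
        rlm = run_length_matrix(q, mask, direction)
        assert rlm_to_dict(rlm.counts) == rlm_counts_oracle(q, mask, direction)

    @given(
        q=arrays(np.int64, (3, 3, 3), elements=st.integers(1, 2)),
        d=st.sampled_from(DIRECTIONS_13),
    )
    @settings(max_examples=60, deadline=None)
    def test_property_matches_oracle(self, q, d):
        mask = np.ones((3, 3, 3), bool)
        rlm = run_length_matrix(q, mask, d)
        assert rlm_to_dict(rlm.counts) == rlm_counts_oracle(q, mask, d)

    @given(
        q=arrays(np.int64, (4, 4, 4), elements=st.integers(1, 3)),
        d=st.sampled_from(DIRECTIONS_13),
    )
    @settings(max_examples=40, deadline=None)
    def test_voxel_conservation(self, q, d):
        """sum_ij j * counts(i, j) equals the in-mask voxel count."""
        mask = np.ones((4, 4, 4), bool)
        rlm = run_length_matrix(q, mask, d)
        assert rlm.n_voxels == 64


class TestFeatures:
    def test_sli_all_runs_length_one(self):
        rlm = RunLengthMatrix(np.array([[3], [2]]), (1, 0, 0))
        assert sli([rlm]) == 1.0

    def test_sli_single_run_length_two(self):
        rlm = RunLengthMatrix(np.array([[0, 1]]), (1, 0, 0))
        assert sli([rlm]) == 0.25

    def test_sli_mixed(self):
        rlm = RunLengthMatrix(np.array([[3, 1]]), (1, 0, 0))
        assert sli([rlm]) == pytest.approx(0.8125)

    def test_hi_all_same_length(self):
        rlm = RunLengthMatrix(np.array([[0, 7]]), (1, 0, 0))
        assert hi([rlm]) == 7.0

    def test_hi_one_run_per_length(self):
        rlm = RunLengthMatrix(np.array([[1, 1, 1, 1]]), (1, 0, 0))
        assert hi([rlm]) == 1.0

    def test_hi_mixed(self):
        rlm = RunLengthMatrix(np.array([[3, 1]]), (1, 0, 0))
        assert hi([rlm]) == pytest.approx(2.5)

    def test_zero_runs_error(self):
        rlm = RunLengthMatrix(np.zeros((1, 1), int), (1, 0, 0))
        with pytest.raises(ValueError, match="zero runs"):
            sli([rlm])
        with pytest.raises(ValueError, match="zero runs"):
            hi([rlm])

    @given(
        q=arrays(np.int64, (4, 4, 4), elements=st.integers(1, 4)),
        d=st.sampled_from(DIRECTIONS_13),
    )
    @settings(max_examples=40, deadline=None)
    def test_bounds(self, q, d):
        rlm = run_length_matrix(q, np.ones((4, 4, 4), bool), d)
        s, h = sli([rlm]), hi([rlm])
        assert 0 < s <= 1
        assert 1 <= h <= rlm.n_runs
        all_len_one = rlm.counts.shape[1] == 1
        assert (s == 1.0) == all_len_one

    def test_rotation_consistency(self):
        """13-direction-averaged SLI/HI are invariant to axis permutations."""
        rng = np.random.default_rng(5)
        q = rng.integers(1, 5, size=(6, 7, 8))
        mask = rng.random((6, 7, 8)) < 0.9

        def feats(qv, mv):
            rlms = [run_length_matrix(qv, mv, d) for d in DIRECTIONS_13]
            return sli(rlms), hi(rlms)

        base = feats(q, mask)
        for perm in itertools.permutations((0, 1, 2)):
            got = feats(np.transpose(q, perm), np.transpose(mask, perm))
            assert got[0] == pytest.approx(base[0], rel=1e-12)
            assert got[1] == pytest.approx(base[1], rel=1e-12)


class TestEntropy:
    def test_constant_roi_zero(self):
        vals = np.full((3, 3, 3), 2.0)
        with pytest.warns(UserWarning):
            h = histogram_entropy(vals, np.ones((3, 3, 3), bool), 8)
        assert h == 0.0

    def test_uniform_occupancy_log2_g(self):
        vals = np.arange(16.0).repeat(4).reshape(64, 1, 1)
        h = histogram_entropy(vals, np.ones((64, 1, 1), bool), 16)
        assert h == pytest.approx(4.0)

    def test_two_bin_closed_form(self):
        vals = np.array([0.0] * 3 + [1.0]).reshape(4, 1, 1)
        h = histogram_entropy(vals, np.ones((4, 1, 1), bool), 2)
        assert h == pytest.approx(-(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25)))
        assert h == pytest.approx(0.8113, abs=5e-5)


class TestMuscleFeatures:
    def test_volume_is_count_times_voxel_volume(self, clean_phantom):
        spec, vol, lmap = clean_phantom
        t2map = fit_t2(vol, mask=lmap.labels > 0)
        table = muscle_features(t2map, lmap, TextureConfig(n_slices=None))
        for _, row in table.iterrows():
            expected = int((lmap.labels == row["label"]).sum())
            assert row["n_voxels"] == expected
            assert row["volume_mm3"] == pytest.approx(expected * lmap.voxel_volume)

    def test_mean_t2_matches_programmed(self, clean_phantom):
        spec, vol, lmap = clean_phantom
        t2map = fit_t2(vol, mask=lmap.labels > 0)
        table = muscle_features(t2map, lmap)
        by_name = table.set_index("muscle")
        assert by_name.loc["muscle_a", "mean_t2"] == pytest.approx(43.0, abs=1e-8)
        assert by_name.loc["muscle_b", "mean_t2"] == pytest.approx(39.0, abs=1e-8)

    def test_missing_label_flagged_not_dropped(self, clean_phantom):
        spec, vol, lmap = clean_phantom
        t2map = fit_t2(vol, mask=lmap.labels > 0)
        lmap2 = LabelMap(lmap.labels, dict(lmap.names), lmap.voxel_size)
        lmap2.names[9] = "ghost_muscle"
        table = muscle_features(t2map, lmap2)
        ghost = table[table["muscle"] == "ghost_muscle"]
        assert len(ghost) == 1
        assert bool(ghost["missing"].iloc[0])
        assert np.isnan(ghost["mean_t2"].iloc[0])


class TestWeightedComposite:
    def _table(self, volumes, values):
        return pd.DataFrame(
            {
                "muscle": [f"m{i}" for i in range(len(volumes))],
                "volume_mm3": volumes,
                "feat": values,
                "missing": [False] * len(volumes),
            }
        )

    def test_equal_volumes_is_mean(self):
        t = self._table([5.0, 5.0, 5.0], [1.0, 2.0, 6.0])
        assert weighted_composite(t, "feat") == pytest.approx(3.0)

    def test_single_muscle(self):
        t = self._table([4.0], [0.37])
        assert weighted_composite(t, "feat") == pytest.approx(0.37)

    def test_hand_weights(self):
        t = self._table([2.0, 1.0], [0.6, 0.9])
        assert weighted_composite(t, "feat") == pytest.approx(0.7)

    def test_missing_excluded_with_renormalization(self):
        t = self._table([2.0, 1.0, 10.0], [0.6, 0.9, 99.0])
        t.loc[2, "missing"] = True
        assert weighted_composite(t, "feat") == pytest.approx(0.7)

    def test_all_zero_volume_raises(self):
        t = self._table([0.0, 0.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="zero"):
            weighted_composite(t, "feat")

    @given(st.lists(st.tuples(st.floats(0.1, 100), st.floats(-10, 10)), min_size=1, max_size=8))
    def test_within_min_max(self, pairs):
        vols, vals = zip(*pairs)
        t = self._table(list(vols), list(vals))
        c = weighted_composite(t, "feat")
        assert min(vals) - 1e-9 <= c <= max(vals) + 1e-9
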