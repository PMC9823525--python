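import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import skelkin as sk
from skelkin.losses_metrics import LossConfig, summarize_distribution


class TestRootRelativeL1:
    def test_identical_inputs_give_zero(self, rng):
        y = rng.normal(size=(5, 3))
        assert sk.root_relative_l1(y, y) == 0.0

    def test_global_translation_cancels(self, rng):
        y = rng.normal(size=(7, 3))
        assert sk.root_relative_l1(y + np.array([0.3, -1.0, 2.0]), y) == pytest.approx(0.0)

    def test_hand_computed_1d_example(self):
        # two points in 1-D, root = point 0: |(3-0)-(1-0)| = 2
        pred = np.array([[0.0], [3.0]])
        truth = np.array([[0.0], [1.0]])
        assert sk.root_relative_l1(pred, truth, root_index=0) == pytest.approx(2.0)


class TestCompositeLoss:
    def _equal_pack(self, rng):
        return {
            "joint_positions": rng.normal(size=(4, 3)),
            "marker_positions": rng.normal(size=(6, 3)),
            "body_scales": rng.uniform(0.9, 1.1, (3, 3)),
            "joint_angles": rng.normal(size=5),
        }

    def test_perfect_prediction_gives_zero_everywhere(self, rng):
        pack = self._equal_pack(rng)
        total, terms = sk.composite_loss(pack, pack)
        assert total == 0.0
        assert all(v == 0.0 for v in terms.values())

    def test_single_angle_error_isolates_the_angle_term(self, rng):
        truth = self._equal_pack(rng)
        pred = {k: np.array(v, copy=True) for k, v in truth.items()}
        pred["joint_angles"][2] += 0.5
        total, terms = sk.composite_loss(pred, truth)
        assert terms["joint"] == terms["marker"] == terms["body"] == 0.0
        assert total == pytest.approx(0.06 * 0.5)

    def test_weighted_sum_identity_with_unit_terms(self):
        # crafted so each of the four terms equals exactly 1
        truth = {
            "joint_positions": np.zeros((2, 1)),
            "marker_positions": np.zeros((2, 1)),
            "body_scales": np.zeros(1),
            "joint_angles": np.zeros(1),
        }
        pred = {
            "joint_positions": np.array([[0.0], [1.0]]),
            "marker_positions": np.array([[0.0], [1.0]]),
            "body_scales": np.array([1.0]),
            "joint_angles": np.array([1.0]),
        }
        total, terms = sk.composite_loss(pred, truth)
        assert all(v == pytest.approx(1.0) for v in terms.values())
        assert total == pytest.approx(1.0 + 2.0 + 0.1 + 0.06)

    def test_homogeneous_in_each_weight(self, rng):
        truth = self._equal_pack(rng)
        pred = {k: v + 0.1 for k, v in truth.items()}
        base_total, base_terms = sk.composite_loss(pred, truth, LossConfig())
        doubled, terms2 = sk.composite_loss(pred, truth, LossConfig(lambda_marker=4.0))
        assert doubled - base_total == pytest.approx(2.0 * base_terms["marker"])
        assert terms2 == base_terms

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(lambda_joint=-1.0)


class TestMpblpe:
    def test_identical_trajectories_give_zero(self, rng):
        y = rng.normal(size=(4, 6, 3))
        bony = np.array([True, False, True, True, False, False])
        assert sk.mpblpe(y, y, bony) == 0.0

    def test_per_frame_global_translation_cancels(self, rng):
        y = rng.normal(size=(4, 6, 3))
        shift = rng.normal(size=(4, 1, 3))
        bony = np.ones(6, dtype=bool)
        assert sk.mpblpe(y + shift, y, bony) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_10mm_offset_reads_10mm(self, rng):
        y = rng.normal(size=(3, 5, 3))
        bony = np.array([False, True, True, True, True])
        pred = y.copy()
        pred[:, bony] += np.array([0.0, 0.01, 0.0])  # root (index 0) not bony
        assert sk.mpblpe(pred, y, bony, pred_root=0, truth_root=0) == pytest.approx(10.0)

    def test_empty_bony_subset_rejected(self, rng):
        y = rng.normal(size=(2, 3, 3))
        with pytest.raises(ValueError, match="empty"):
            sk.mpblpe(y, y, np.zeros(3, dtype=bool))


class TestBodyScaleErrors:
    def test_perfect_scales_give_zero(self):
        s = np.ones((4, 3))
        assert sk.body_scale_errors(s, s, np.full(4, 300.0)) == (0.0, 0.0)

    def test_longest_axis_conversion_to_mm(self):
        truth = np.ones((1, 3))
        pred = truth.copy()
        pred[0, 1] += 0.025  # long axis y by default
        _, mae_mm = sk.body_scale_errors(pred, truth, np.array([400.0]))
        assert mae_mm == pytest.approx(10.0)

    def test_rmse_pools_all_entries(self):
        truth = np.zeros((1, 1, 3))
        pred = np.array([[[0.3, 0.4, 0.0]]])
        rmse, _ = sk.body_scale_errors(pred + 1, truth + 1, np.array([100.0]))
        assert rmse == pytest.approx(np.sqrt((0.3**2 + 0.4**2) / 3))

    def test_two_entry_hand_rmse(self):
        # errors 0.3 and 0.4 over two entries -> sqrt(mean) = 0.3536
        pred = np.array([[[1.3, 1.0, 1.0]], [[1.4, 1.0, 1.0]]])  # (F=2, B=1, 3)
        truth = np.ones((1, 3))
        rmse, _ = sk.body_scale_errors(pred, truth, np.array([100.0]))
        assert rmse == pytest.approx(np.sqrt((0.3**2 + 0.4**2) / 6))


class TestAngleErrors:
    def test_perfect_angles_give_zeros(self, rng):
        t = rng.normal(size=(10, 3))
        stats = sk.angle_errors(t, t)
        assert stats.mae == stats.sd == stats.rmse == 0.0

    def test_constant_offset_has_zero_sd(self, rng):
        t = rng.normal(size=(10, 2))
        stats = sk.angle_errors(t + np.deg2rad(2.0), t)
        assert stats.mae == pytest.approx(2.0)
        assert stats.sd == pytest.approx(0.0, abs=1e-9)
        assert stats.rmse == pytest.approx(2.0)

    def test_hand_computed_population_convention(self):
        truth = np.zeros((2, 1))
        pred = np.deg2rad(np.array([[1.0], [-3.0]]))
        stats = sk.angle_errors(pred, truth)
        assert stats.mae == pytest.approx(2.0)
        assert stats.rmse == pytest.approx(np.sqrt(5.0))
        assert stats.sd == pytest.approx(2.0)  # population SD of (+1, -3)

    def test_valid_mask_excludes_entries(self):
        truth = np.zeros((3, 1))
        pred = np.deg2rad(np.array([[1.0], [100.0], [1.0]]))
        valid = np.array([[True], [False], [True]])
        assert sk.angle_errors(pred, truth, valid).mae == pytest.approx(1.0)


class TestMeanVelocity:
    def test_constant_series_is_zero(self):
        assert sk.mean_velocity(np.full(10, 3.2), 0.1) == pytest.approx(0.0)

    @pytest.mark.parametrize("dt", [0.5, 0.01])
    def test_linear_ramp_gives_slope(self, dt):
        t = np.arange(20) * dt
        assert sk.mean_velocity(5.0 * t, dt) == pytest.approx(5.0)

    def test_hand_computed_example(self):
        assert sk.mean_velocity(np.array([0.0, 1.0, -1.0]), 0.5) == pytest.approx(3.0)

    @settings(deadline=None, max_examples=25)
    @given(
        slope=st.floats(-50, 50),
        intercept=st.floats(-10, 10),
        n=st.integers(2, 40),
    )
    def test_affine_signals_give_absolute_slope(self, slope, intercept, n):
        dt = 0.02
        s = intercept + slope * np.arange(n) * dt
        assert sk.mean_velocity(s, dt) == pytest.approx(abs(slope), abs=1e-9)


class TestPearsonCategories:
    def test_perfect_and_anticorrelated_are_excellent(self, rng):
        a = rng.normal(size=50)
        rho, cat = sk.pearson_with_category(a, a)
        assert rho == pytest.approx(1.0) and cat == "excellent"
        rho, cat = sk.pearson_with_category(a, -a)
        assert rho == pytest.approx(-1.0) and cat == "excellent"

    @pytest.mark.parametrize(
        "mag,expected",
        [(0.2, "weak"), (0.35, "weak"), (0.5, "moderate"), (0.67, "moderate"),
         (0.8, "strong"), (0.90, "strong"), (0.95, "excellent")],
    )
    def test_category_boundaries_are_inclusive_below(self, mag, expected, monkeypatch):
        from skelkin import losses_metrics

        class FakeResult:
            def __init__(self, v):
                self.statistic = v

        monkeypatch.setattr(
            losses_metrics.stats, "pearsonr", lambda a, b: FakeResult(mag)
        )
        _, cat = sk.pearson_with_category(np.arange(5.0), np.arange(5.0) ** 2)
        assert cat == expected

    def test_constant_series_is_undefined(self):
        with pytest.raises(ValueError, match="constant"):
            sk.pearson_with_category(np.ones(5), np.arange(5.0))


class TestSummarize:
    def test_median_of_small_vector(self):
        assert summarize_distribution([1, 2, 3, 4, 5])["median"] == 3

    def test_constant_vector_has_zero_spread(self):
        s = summarize_distribution(np.full(9, 2.5))
        assert s["iqr"] == 0.0 and s["sd"] == 0.0

    def test_matches_sorting_based_quantile_oracle(self, rng):
        v = rng.normal(size=101)
        s = summarize_distribution(v)
        x = np.sort(v)

        def quantile(q):  # linear interpolation on sorted order statistics
            pos = q * (len(x) - 1)
            lo = int(np.floor(pos))
            frac = pos - lo
            return x[lo] * (1 - frac) + x[min(lo + 1, len(x) - 1)] * frac

        assert s["median"] == pytest.approx(quantile(0.5))
        assert s["iqr"] == pytest.approx(quantile(0.75) - quantile(0.25))


class TestChannelPermutationInvariance:
    def test_angle_metrics_invariant_under_consistent_permutation(self, rng):
        pred = rng.normal(size=(12, 5))
        truth = rng.normal(size=(12, 5))
        valid = rng.random((12, 5)) > 0.2
        perm = rng.permutation(5)
        a = sk.angle_errors(pred, truth, valid)
        b = sk.angle_errors(pred[:, perm], truth[:, perm], valid[:, perm])
        assert a.mae == pytest.approx(b.mae)
        assert a.rmse == pytest.approx(b.rmse)
        np.testing.assert_allclose(a.per_coordinate_mae[perm], b.per_coordinate_mae)

    def test_mpblpe_invariant_under_marker_permutation(self, rng):
        pred = rng.normal(size=(6, 8, 3))
        truth = rng.normal(size=(6, 8, 3))
        bony = rng.random(8) > 0.4
        perm = rng.permutation(8)
        a = sk.mpblpe(pred, truth, bony, 0, 0)
        where_root = int(np.where(perm == 0)[0][0])
        b = sk.mpblpe(pred[:, perm], truth[:, perm], bony[perm], where_root, where_root)
        assert a == pytest.approx(b)
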