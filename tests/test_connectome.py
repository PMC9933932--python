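import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conntda import (
    Connectome,
    MotionTrace,
    Parcellation,
    RoiTimeSeries,
    expand_confounds,
    from_distance,
    pearson_connectome,
    qc_session,
    regress_confounds,
    subset_network,
    to_distance,
)
from conntda.connectome import NETWORKS


class TestExpandConfounds:
    def test_nine_signals_become_36(self, rng):
        base = rng.standard_normal((9, 150))
        out = expand_confounds(base)
        assert out.shape == (36, 150)
        np.testing.assert_array_equal(out[:9], base)

    def test_zero_base_gives_zero_rows(self):
        assert not expand_confounds(np.zeros((9, 10))).any()

    def test_hand_computed_derivative_and_squares(self):
        base = np.zeros((9, 3))
        base[0] = [1.0, 2.0, 3.0]
        out = expand_confounds(base)
        np.testing.assert_array_equal(out[9], [0.0, 1.0, 1.0])   # derivative
        np.testing.assert_array_equal(out[18], [1.0, 4.0, 9.0])  # square of base
        np.testing.assert_array_equal(out[27], [0.0, 1.0, 1.0])  # square of deriv

    def test_row_count_is_four_times_input(self, rng):
        out = expand_confounds(rng.standard_normal((9, 20)))
        assert out.shape[0] == 4 * 9

    def test_wrong_row_count_rejected(self, rng):
        with pytest.raises(ValueError, match="9 base"):
            expand_confounds(rng.standard_normal((6, 50)))

    def test_nonfinite_rejected(self):
        base = np.zeros((9, 10))
        base[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            expand_confounds(base)


class TestQcSession:
    def test_spike_mask_thresholding(self):
        res = qc_session(MotionTrace(fd=[0.1, 0.3, 0.2], tr=2.0), spike_threshold=0.25)
        np.testing.assert_array_equal(res["spike_mask"], [False, True, False])

    @pytest.mark.parametrize("n_spikes,expected", [(30, True), (31, False)])
    def test_four_minute_rule_boundary(self, n_spikes, expected):
        # 150 volumes at TR=2 s; 4 min = 120 clean volumes
        fd = np.full(150, 0.1)
        fd[:n_spikes] = 0.5
        res = qc_session(MotionTrace(fd=fd, tr=2.0))
        assert res["pass_flag"] is expected

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            MotionTrace(fd=[], tr=2.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=5, max_size=50), st.integers(0, 4))
    def test_adding_spikes_never_rescues_a_session(self, fds, k):
        fd = np.asarray(fds)
        res_before = qc_session(MotionTrace(fd=fd, tr=2.0), min_clean=0.1)
        fd2 = fd.copy()
        fd2[: min(k, fd.size)] = 1.0  # force extra spikes
        res_after = qc_session(MotionTrace(fd=fd2, tr=2.0), min_clean=0.1)
        assert res_after["pass_flag"] <= res_before["pass_flag"]


class TestRegressConfounds:
    def test_constant_confound_demeans(self, rng):
        ts = RoiTimeSeries(data=rng.standard_normal((30, 4)), tr=2.0)
        out = regress_confounds(ts, np.ones((1, 30)))
        np.testing.assert_allclose(out.data, ts.data - ts.data.mean(0), atol=1e-10)

    def test_signal_equal_to_confound_vanishes(self, rng):
        conf = rng.standard_normal((1, 40))
        data = rng.standard_normal((40, 3))
        data[:, 1] = conf[0]
        out = regress_confounds(RoiTimeSeries(data=data, tr=2.0), conf)
        assert np.abs(out.data[:, 1]).max() < 1e-8

    def test_residuals_orthogonal_to_design(self, rng):
        ts = RoiTimeSeries(data=rng.standard_normal((50, 6)), tr=2.0)
        conf = rng.standard_normal((4, 50))
        out = regress_confounds(ts, conf)
        assert np.abs(conf @ out.data).max() < 1e-8

    def test_spike_volumes_zeroed(self, rng):
        ts = RoiTimeSeries(data=rng.standard_normal((30, 3)), tr=2.0)
        mask = np.zeros(30, dtype=bool)
        mask[5] = True
        out = regress_confounds(ts, np.ones((1, 30)), spike_mask=mask)
        assert np.abs(out.data[5]).max() < 1e-8

    def test_rank_deficient_design_warns_and_drops(self, rng, caplog):
        conf = np.vstack([np.ones((1, 30)), np.ones((1, 30))])
        ts = RoiTimeSeries(data=rng.standard_normal((30, 3)), tr=2.0)
        with caplog.at_level(logging.WARNING, logger="conntda.connectome"):
            out = regress_confounds(ts, conf)
        assert "collinear" in caplog.text
        np.testing.assert_allclose(out.data, ts.data - ts.data.mean(0), atol=1e-10)

    def test_overdetermined_design_rejected(self, rng):
        ts = RoiTimeSeries(data=rng.standard_normal((10, 3)), tr=2.0)
        with pytest.raises(ValueError, match="regressors"):
            regress_confounds(ts, rng.standard_normal((12, 10)))


class TestPearsonConnectome:
    def test_duplicate_and_negated_columns(self, rng):
        x = rng.standard_normal(80)
        data = np.column_stack([x, x, -x])
        c = pearson_connectome(RoiTimeSeries(data=data, tr=2.0))
        assert c.r[0, 1] == pytest.approx(1.0)
        assert c.r[0, 2] == pytest.approx(-1.0)
        np.testing.assert_array_equal(np.diag(c.r), 1.0)

    def test_orthogonal_sinusoids_uncorrelated(self):
        t = np.arange(100)
        data = np.column_stack(
            [np.sin(2 * np.pi * t / 50), np.cos(2 * np.pi * t / 50)]
        )
        c = pearson_connectome(RoiTimeSeries(data=data, tr=2.0))
        assert abs(c.r[0, 1]) < 0.05

    def test_constant_column_names_roi(self, rng):
        data = rng.standard_normal((30, 3))
        data[:, 2] = 4.2
        with pytest.raises(ValueError, match="roi002"):
            pearson_connectome(RoiTimeSeries(data=data, tr=2.0))

    def test_affine_rescaling_invariance(self, rng):
        data = rng.standard_normal((60, 5))
        c1 = pearson_connectome(RoiTimeSeries(data=data, tr=2.0))
        data2 = data.copy()
        data2[:, 0] = 3.5 * data2[:, 0] - 7.0
        c2 = pearson_connectome(RoiTimeSeries(data=data2, tr=2.0))
        assert np.abs(c1.r - c2.r).max() < 1e-10


class TestDistance:
    def test_correlation_extremes_map_to_0_1_2(self):
        r = np.array([[1.0, 1.0, 0.0, -1.0],
                      [1.0, 1.0, 0.0, -1.0],
                      [0.0, 0.0, 1.0, 0.0],
                      [-1.0, -1.0, 0.0, 1.0]])
        d = to_distance(Connectome(r=r))
        assert d.d[0, 1] == 0.0
        assert d.d[0, 2] == 1.0
        assert d.d[0, 3] == 2.0

    def test_identity_connectome_gives_zero_distances(self):
        d = to_distance(Connectome(r=np.ones((4, 4))))
        assert not d.d.any()

    def test_arithmetic(self):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = 0.432
        assert to_distance(Connectome(r=r)).d[0, 1] == pytest.approx(0.568)

    def test_round_trip_within_one_ulp_and_idempotent(self, rng):
        r = np.corrcoef(rng.standard_normal((40, 6)), rowvar=False)
        c = Connectome(r=r)
        back = from_distance(to_distance(c))
        # 1 - (1 - r) can legitimately move by one ulp in IEEE arithmetic;
        # after one pass the map must be an exact fixpoint
        np.testing.assert_allclose(back.r, c.r, atol=2 ** -52, rtol=0.0)
        twice = from_distance(to_distance(back))
        np.testing.assert_array_equal(twice.r, back.r)

    def test_asymmetric_matrix_rejected(self, rng):
        r = np.eye(3)
        r[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            Connectome(r=r)


class TestSubsetNetwork:
    def test_whole_brain_sentinel_is_identity(self, parcellation264, rng):
        r = np.corrcoef(rng.standard_normal((50, 264)), rowvar=False)
        c = Connectome(r=r, roi_ids=parcellation264.roi_ids)
        assert subset_network(c, parcellation264, "ALL") is c

    def test_network_submatrix_size(self, parcellation264, rng):
        r = np.corrcoef(rng.standard_normal((300, 264)), rowvar=False)
        c = Connectome(r=r, roi_ids=parcellation264.roi_ids)
        sub = subset_network(c, parcellation264, "FPN")
        n_fpn = sum(1 for lab in parcellation264.network if lab == "FPN")
        assert sub.r.shape == (n_fpn, n_fpn)

    def test_subset_commutes_with_distance(self, parcellation264, rng):
        r = np.corrcoef(rng.standard_normal((300, 264)), rowvar=False)
        c = Connectome(r=r, roi_ids=parcellation264.roi_ids)
        d1 = to_distance(subset_network(c, parcellation264, "DMN"))
        d2 = subset_network(to_distance(c), parcellation264, "DMN")
        np.testing.assert_array_equal(d1.d, d2.d)

    def test_unknown_label_lists_valid_ones(self, parcellation264, rng):
        r = np.corrcoef(rng.standard_normal((300, 264)), rowvar=False)
        c = Connectome(r=r, roi_ids=parcellation264.roi_ids)
        with pytest.raises(ValueError, match="AUD"):
            subset_network(c, parcellation264, "NOPE")

    def test_small_subset_rejected(self, rng):
        p = Parcellation(
            roi_ids=["a", "b", "c", "d"],
            network=["FPN", "FPN", "DMN", "DMN"],
        )
        r = np.corrcoef(rng.standard_normal((30, 4)), rowvar=False)
        c = Connectome(r=r, roi_ids=["a", "b", "c", "d"])
        with pytest.raises(ValueError, match="at least 3"):
            subset_network(c, p, "FPN")

    def test_thirteen_network_labels_enforced(self):
        with pytest.raises(ValueError, match="unknown network"):
            Parcellation(roi_ids=["a", "b"], network=["FPN", "XXX"])
        assert len(NETWORKS) == 13
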