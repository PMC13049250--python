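"""Evaluation statistics: wCV oracle, ROI summaries, correlation gate, bias."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ispgr import (
    bias_table,
    correlate_with_diameter,
    get_protocol,
    repeatability,
    roi_summary,
    sensitivity_analysis,
)
from ispgr.fitting import FLAG_OK, FLAG_OUTSIDE, ParameterMaps


def _maps_from(t1, t2=None, m0=None, flag=None):
    t1 = np.asarray(t1, dtype=float)
    t2 = np.full_like(t1, 50.0) if t2 is None else np.asarray(t2, dtype=float)
    m0 = np.ones_like(t1) if m0 is None else np.asarray(m0, dtype=float)
    flag = np.full(t1.shape, FLAG_OK) if flag is None else flag
    return ParameterMaps(t1=t1, t2=t2, m0=m0,
                         resid_norm=np.zeros_like(t1), flag=flag)


class TestRepeatability:
    def test_two_pair_hand_oracle(self):
        """Cross-check against direct enumeration of the wCV definition."""
        pairs = np.array([[100.0, 102.0], [200.0, 196.0]])
        res = repeatability(pairs)
        d = pairs[:, 0] - pairs[:, 1]                    # [-2, 4]
        within_sd = np.sqrt(np.mean(d ** 2) / 2.0)       # sqrt(10/2) = sqrt 5
        grand = pairs.mean()                             # 149.5
        assert res.within_subject_sd == pytest.approx(np.sqrt(5.0))
        assert res.wcv == pytest.approx(within_sd / grand)
        assert res.mean_difference == pytest.approx(1.0)

    def test_identical_pairs_zero(self):
        res = repeatability(np.array([[5.0, 5.0], [9.0, 9.0], [2.0, 2.0]]))
        assert res.wcv == 0.0
        assert res.mean_difference == 0.0

    @given(c=st.floats(0.1, 1e4))
    def test_scale_invariance(self, c):
        pairs = np.array([[100.0, 102.0], [200.0, 196.0], [150.0, 151.0]])
        assert repeatability(c * pairs).wcv == pytest.approx(
            repeatability(pairs).wcv, rel=1e-12)

    def test_limits_symmetric_about_mean_difference(self):
        pairs = np.array([[10.0, 12.0], [20.0, 15.0], [30.0, 33.0]])
        res = repeatability(pairs)
        assert (res.loa_upper - res.mean_difference) == pytest.approx(
            res.mean_difference - res.loa_lower)

    def test_zero_grand_mean_rejected(self):
        with pytest.raises(ZeroDivisionError):
            repeatability(np.array([[1.0, -1.0], [-2.0, 2.0]]))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            repeatability(np.array([[1.0, 2.0]]))


class TestRoiSummary:
    def test_uniform_region(self):
        maps = _maps_from(np.full((4, 4, 1), 700.0))
        df = roi_summary(maps)
        assert df.loc["all", "t1_median"] == 700.0
        assert df.loc["all", "t1_q75"] - df.loc["all", "t1_q25"] == 0.0

    def test_linear_interpolation_quantiles(self):
        vals = np.arange(1.0, 101.0).reshape(10, 10, 1)
        df = roi_summary(_maps_from(vals))
        assert df.loc["all", "t1_median"] == pytest.approx(50.5)
        assert df.loc["all", "t1_q25"] == pytest.approx(25.75)
        assert df.loc["all", "t1_q75"] == pytest.approx(75.25)

    def test_label_mask_restricts_summary(self):
        t1 = np.zeros((4, 4, 1))
        t1[:2] = 100.0
        t1[2:] = 900.0
        labels = np.zeros((4, 4, 1), dtype=int)
        labels[:2] = 1
        labels[2:] = 2
        df = roi_summary(_maps_from(t1), labels)
        assert df.loc[1, "t1_median"] == 100.0
        assert df.loc[2, "t1_median"] == 900.0

    def test_nonconverged_excluded(self):
        t1 = np.full((2, 2, 1), 500.0)
        flag = np.full((2, 2, 1), FLAG_OK)
        flag[0, 0, 0] = 2
        t1[0, 0, 0] = 9999.0
        df = roi_summary(_maps_from(t1, flag=flag))
        assert df.loc["all", "t1_median"] == 500.0
        assert df.loc["all", "n_voxels"] == 3

    def test_all_nonconverged_rejected(self):
        maps = _maps_from(np.full((2, 2, 1), 1.0),
                          flag=np.full((2, 2, 1), FLAG_OUTSIDE))
        with pytest.raises(ValueError):
            roi_summary(maps)


class TestCorrelationGate:
    def test_linear_normal_selects_pearson(self, rng):
        x = rng.normal(50, 5, 20)
        y = 2.0 * x + 3.0
        res = correlate_with_diameter(x, y)
        assert res.method == "pearson"
        assert res.coefficient == pytest.approx(1.0)

    def test_monotone_nonnormal_selects_spearman(self, rng):
        x = rng.normal(0, 1, 30)
        y = np.exp(4.0 * x)  # heavily skewed, perfectly monotone in x
        res = correlate_with_diameter(x, y)
        assert res.method == "spearman"
        assert res.coefficient == pytest.approx(1.0)

    def test_shuffled_pairs_near_zero(self, rng):
        x = rng.normal(0, 1, 200)
        y = rng.permutation(rng.normal(0, 1, 200))
        res = correlate_with_diameter(x, y)
        assert abs(res.coefficient) < 0.2

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            correlate_with_diameter([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            correlate_with_diameter([1.0, 2.0], [1.0, 2.0])


class TestBiasTable:
    def _reference(self):
        return {1: (600.0, 45.0), 2: (1400.0, 90.0)}

    def _labels(self):
        labels = np.zeros((4, 4, 1), dtype=int)
        labels[:2] = 1
        labels[2:] = 2
        return labels

    def test_perfect_fit_zero_bias(self):
        labels = self._labels()
        t1 = np.where(labels == 1, 600.0, 1400.0)
        t2 = np.where(labels == 1, 45.0, 90.0)
        table = bias_table({"ispgr": _maps_from(t1, t2)}, labels, self._reference())
        assert np.allclose(table["err_t1"], 0.0)
        assert np.allclose(table["err_t2"], 0.0)

    def test_error_is_fitted_minus_reference_and_antisymmetric(self):
        labels = self._labels()
        t1 = np.where(labels == 1, 650.0, 1300.0)
        table = bias_table({"m": _maps_from(t1)}, labels, self._reference())
        err = table.set_index("region")["err_t1"]
        assert err[1] == pytest.approx(50.0)
        assert err[2] == pytest.approx(-100.0)
        # swapping fitted and reference negates the errors
        swapped = bias_table({"m": _maps_from(np.where(labels == 1, 600.0, 1400.0))},
                             labels, {1: (650.0, 50.0), 2: (1300.0, 50.0)})
        assert swapped.set_index("region")["err_t1"][1] == pytest.approx(-50.0)

    def test_single_voxel_region(self):
        labels = np.zeros((3, 1, 1), dtype=int)
        labels[1] = 1
        t1 = np.array([0.0, 777.0, 0.0]).reshape(3, 1, 1)
        table = bias_table({"m": _maps_from(t1)}, labels, {1: (700.0, 50.0)})
        assert table[table.region == 1]["err_t1"].iloc[0] == pytest.approx(77.0)

    def test_grand_mean_row_present(self):
        labels = self._labels()
        t1 = np.where(labels == 1, 650.0, 1300.0)
        table = bias_table({"m": _maps_from(t1)}, labels, self._reference())
        mean_row = table[table.region == "mean"]
        assert mean_row["err_t1"].iloc[0] == pytest.approx(-25.0)


class TestSensitivityAnalysis:
    def test_noiseless_limit_recovers_exactly(self):
        proto = get_protocol("invivo_ispgr")
        smap = sensitivity_analysis(proto, [800.0], [60.0], snr=1e9, n_reps=3, seed=0)
        assert smap.err_t1[0, 0] < 0.1
        assert smap.err_t2[0, 0] < 0.1

    def test_seed_reproducibility(self):
        proto = get_protocol("invivo_ispgr")
        a = sensitivity_analysis(proto, [500.0, 1500.0], [30.0], snr=30,
                                 n_reps=5, seed=42)
        b = sensitivity_analysis(proto, [500.0, 1500.0], [30.0], snr=30,
                                 n_reps=5, seed=42)
        np.testing.assert_array_equal(a.err_t1, b.err_t1)

    def test_more_noise_does_not_help(self):
        proto = get_protocol("invivo_ispgr")
        lo = sensitivity_analysis(proto, [800.0], [50.0], snr=60, n_reps=25, seed=9)
        hi = sensitivity_analysis(proto, [800.0], [50.0], snr=15, n_reps=25, seed=9)
        assert hi.err_t1[0, 0] > lo.err_t1[0, 0]

    def test_invalid_inputs(self):
        proto = get_protocol("invivo_ispgr")
        with pytest.raises(ValueError):
            sensitivity_analysis(proto, [], [50.0], snr=30)
        with pytest.raises(ValueError):
            sensitivity_analysis(proto, [800.0], [50.0], snr=-1)
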