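"""Joint T1/T2/M0 estimation: recovery, equivariance, bias direction, maps."""

import numpy as np
import pytest

from ispgr import (
    FitBounds,
    ISPGRModel,
    NoiseModel,
    TissueParams,
    Vial,
    actual_flip_angle,
    fit_regions,
    fit_volume,
    fit_voxel,
    forward_signals,
    make_phantom,
    model_vector,
    simulate_stack,
    smooth_b1_map,
)
from ispgr.fitting import FLAG_FAILED, FLAG_OUTSIDE

WIDE = FitBounds(t1=(50.0, 4000.0), t2=(5.0, 500.0))


class TestFlipAngleCorrection:
    @pytest.mark.parametrize("nominal,ratio,expected",
                             [(10.0, 1.0, 10.0), (10.0, 0.9, 9.0), (4.0, 1.2, 4.8)])
    def test_linear_scaling(self, nominal, ratio, expected):
        assert actual_flip_angle(nominal, ratio) == pytest.approx(expected)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            actual_flip_angle(10.0, 0.0)


class TestSmoothB1Map:
    def test_constant_map_preserved(self):
        m = np.full((6, 6, 4), 0.93)
        np.testing.assert_allclose(smooth_b1_map(m, 1.5), m)

    def test_impulse_mass_preserved(self):
        m = np.zeros((9, 9, 9))
        m[4, 4, 4] = 1.0
        out = smooth_b1_map(m, 1.0)
        assert out.sum() == pytest.approx(1.0, rel=1e-6)
        assert out.max() < 1.0

    def test_checkerboard_variance_decreases_with_sigma(self):
        idx = np.indices((8, 8, 8)).sum(axis=0)
        m = (idx % 2).astype(float)
        variances = [smooth_b1_map(m, s).var() for s in (0.0, 0.5, 1.0, 2.0)]
        assert np.all(np.diff(variances) < 0)

    def test_sigma_zero_is_identity(self):
        m = np.random.default_rng(0).random((5, 5, 5))
        np.testing.assert_array_equal(smooth_b1_map(m, 0.0), m)


class TestVoxelFit:
    def test_noiseless_self_consistency(self, invivo_protocol):
        s = model_vector(TissueParams(800, 50, 1.0), invivo_protocol)
        res = fit_voxel(s, invivo_protocol)
        assert res.t1 == pytest.approx(800, rel=1e-3)
        assert res.t2 == pytest.approx(50, rel=1e-3)
        assert res.m0 == pytest.approx(1.0, rel=1e-3)
        assert res.converged

    @pytest.mark.parametrize("t1", [300.0, 800.0, 1500.0, 2500.0])
    @pytest.mark.parametrize("t2", [25.0, 60.0, 120.0, 250.0])
    def test_noiseless_identifiability_grid(self, invivo_protocol, t1, t2):
        """The multi-start fit escapes the short-T2 local minima and recovers
        any tissue in the physiological box to better than 0.5%."""
        s = model_vector(TissueParams(t1, t2, 2.0), invivo_protocol)
        res = fit_voxel(s, invivo_protocol)
        assert res.t1 == pytest.approx(t1, rel=5e-3)
        assert res.t2 == pytest.approx(t2, rel=5e-3)
        assert res.m0 == pytest.approx(2.0, rel=5e-3)

    def test_scale_equivariance(self, invivo_protocol, rng):
        s = model_vector(TissueParams(1200, 80, 1.0), invivo_protocol)
        noisy = s * (1 + 0.02 * rng.standard_normal(s.size))
        a = fit_voxel(noisy, invivo_protocol)
        b = fit_voxel(7.0 * noisy, invivo_protocol)
        assert b.t1 == pytest.approx(a.t1, rel=1e-6)
        assert b.t2 == pytest.approx(a.t2, rel=1e-6)
        assert b.m0 == pytest.approx(7.0 * a.m0, rel=1e-6)

    def test_b1_corrected_fit_recovers_truth(self, invivo_protocol):
        s = forward_signals(900.0, 70.0, 1.0, invivo_protocol, alpha_scale=0.85)
        res = fit_voxel(s, invivo_protocol, alpha_scale=0.85)
        assert res.t1 == pytest.approx(900, rel=1e-3)

    def test_spgr_misfit_underestimates_t1(self, invivo_protocol):
        """Fitting prepared-shot data with the plain steady-state model
        gives a negative T1 bias everywhere, much larger in magnitude than
        the prepared-model fit's residual bias."""
        t1s = np.geomspace(236, 2013, 8)
        t2s = np.geomspace(15, 328, 8)
        bias_spgr, bias_ispgr = [], []
        for t1, t2 in zip(t1s, t2s):
            s = model_vector(TissueParams(t1, t2, 1.0), invivo_protocol)
            bias_spgr.append(fit_voxel(s, invivo_protocol, model="spgr",
                                       bounds=WIDE).t1 - t1)
            bias_ispgr.append(fit_voxel(s, invivo_protocol, bounds=WIDE).t1 - t1)
        assert np.all(np.array(bias_spgr) < 0)
        assert abs(np.mean(bias_ispgr)) < abs(np.mean(bias_spgr)) / 5

    def test_all_zero_signals_flagged_failed(self, invivo_protocol):
        res = fit_voxel(np.zeros(6), invivo_protocol)
        assert not res.converged
        assert res.flag == FLAG_FAILED
        assert np.isnan(res.t1)

    def test_true_value_outside_bounds_flagged_at_bound(self, invivo_protocol):
        s = model_vector(TissueParams(800, 350.0, 1.0), invivo_protocol)
        res = fit_voxel(s, invivo_protocol)  # default T2 bound is 300 ms
        assert res.flag == 1
        assert res.t2 == pytest.approx(300.0, abs=0.01)

    def test_validation_errors(self, invivo_protocol):
        with pytest.raises(ValueError, match="finite"):
            ISPGRModel([np.nan] * 6, invivo_protocol)
        with pytest.raises(ValueError, match="one value per measurement"):
            ISPGRModel([1.0, 2.0], invivo_protocol)
        with pytest.raises(ValueError, match="model"):
            ISPGRModel(np.ones(6), invivo_protocol, model="vfa")

    def test_summary_and_bse(self, invivo_protocol, rng):
        s = model_vector(TissueParams(800, 50, 1.0), invivo_protocol)
        noisy = s + rng.normal(0, s.max() / 50, s.size)
        res = fit_voxel(noisy, invivo_protocol)
        text = res.summary()
        assert "T1 (ms)" in text and "converged" in text
        assert np.all(np.isfinite(res.bse))


@pytest.fixture(scope="module")
def two_vial_stack(invivo_protocol):
    ph = make_phantom(vials=[
        Vial((5, 5), 2.2, TissueParams(600, 45, 1.0)),
        Vial((12, 12), 2.2, TissueParams(1400, 90, 1.0)),
    ], shape=(18, 18, 1))
    return ph, simulate_stack(ph, invivo_protocol)


class TestVolumeFit:
    def test_noiseless_closure(self, two_vial_stack, invivo_protocol):
        ph, stack = two_vial_stack
        maps = fit_volume(stack, invivo_protocol, b1_sigma=0.0)
        sel = stack.mask > 0
        np.testing.assert_allclose(maps.t1[sel], ph.t1_map[sel], rtol=1e-3)
        np.testing.assert_allclose(maps.t2[sel], ph.t2_map[sel], rtol=1e-3)

    def test_outside_mask_untouched(self, two_vial_stack, invivo_protocol):
        _, stack = two_vial_stack
        maps = fit_volume(stack, invivo_protocol, b1_sigma=0.0)
        outside = stack.mask == 0
        assert np.all(np.isnan(maps.t1[outside]))
        assert np.all(maps.flag[outside] == FLAG_OUTSIDE)

    def test_single_voxel_mask(self, invivo_protocol):
        ph = make_phantom(vials=[Vial((3, 3), 0.1, TissueParams(800, 60, 1.0))],
                          shape=(6, 6, 1))
        stack = simulate_stack(ph, invivo_protocol)
        assert (stack.mask > 0).sum() == 1
        maps = fit_volume(stack, invivo_protocol, b1_sigma=0.0)
        assert np.isfinite(maps.t1).sum() == 1

    def test_empty_mask_rejected(self, invivo_protocol):
        ph = make_phantom(vials=[Vial((3, 3), 1.5, TissueParams(800, 60, 1.0))],
                          shape=(8, 8, 1))
        stack = simulate_stack(ph, invivo_protocol)
        stack.mask = np.zeros_like(stack.mask)
        with pytest.raises(ValueError, match="mask"):
            fit_volume(stack, invivo_protocol)

    def test_wrong_b1_assumption_biases_t1(self, invivo_protocol):
        """Simulating with a uniform B1+ ratio of 0.8 but fitting at 1.0
        must produce a systematic T1 error."""
        ph = make_phantom(vials=[Vial((5, 5), 2.2, TissueParams(1000, 60, 1.0))],
                          shape=(10, 10, 1))
        stack = simulate_stack(ph, invivo_protocol, b1=0.8)
        stack.b1_ratio = np.ones_like(stack.b1_ratio)  # pretend it was nominal
        maps = fit_volume(stack, invivo_protocol, b1_sigma=0.0)
        sel = stack.mask > 0
        bias = maps.t1[sel].mean() - 1000.0
        assert abs(bias) > 50.0


def test_region_fit_matches_voxel_fit_on_homogeneous_vials(invivo_protocol):
    ph = make_phantom(vials=[Vial((5, 5), 2.2, TissueParams(600, 45, 1.0)),
                             Vial((12, 12), 2.2, TissueParams(1400, 90, 1.0))],
                      shape=(18, 18, 1))
    stack = simulate_stack(ph, invivo_protocol)
    df = fit_regions(stack, invivo_protocol)
    assert df.loc[1, "t1"] == pytest.approx(600, rel=1e-3)
    assert df.loc[2, "t2"] == pytest.approx(90, rel=1e-3)
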