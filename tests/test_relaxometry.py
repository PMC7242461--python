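import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from utemri import (
    CONES_UTE,
    MonoExponentialModel,
    PhantomConfig,
    TissueSpec,
    fit_loglinear,
    generate_phantom,
    ratio_map,
    simulate_series,
    subtraction_image,
    two_point_r2star,
)
from utemri.forward_model import MultiEchoSeries
from utemri.relaxometry import RatioMap, default_signal_floor


def _voxel_series(signals, echo_times=CONES_UTE.echo_times):
    """1x1 'image' series from a list of per-echo signals."""
    data = np.asarray(signals, dtype=float).reshape(1, 1, -1)
    return MultiEchoSeries(data=data, echo_times=echo_times, protocol=CONES_UTE)


class TestFitLoglinear:
    def test_noiseless_monoexponential_is_exact(self):
        te = np.array(CONES_UTE.echo_times)
        s = _voxel_series(100.0 * np.exp(-0.064 * te))
        fit = fit_loglinear(s, 1e-12)
        assert fit.rate[0, 0] == pytest.approx(64.0, abs=1e-9)
        assert fit.r_squared[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept[0, 0] == pytest.approx(np.log(100.0), abs=1e-9)

    def test_constant_signal_fits_rate_zero(self):
        fit = fit_loglinear(_voxel_series([50.0] * 5), 1e-12)
        assert fit.rate[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_biexponential_fitted_rate_between_components(self):
        te = np.array(CONES_UTE.echo_times)
        sig = 100.0 * (0.5 * np.exp(-300.0 * te * 1e-3) + 0.5 * np.exp(-20.0 * te * 1e-3))
        fit = fit_loglinear(_voxel_series(sig), 1e-12)
        # independent OLS oracle on the 5-point log signal
        slope, _ = np.polyfit(te * 1e-3, np.log(sig), 1)
        assert fit.rate[0, 0] == pytest.approx(-slope, rel=1e-9)
        assert 20.0 + 1.0 < fit.rate[0, 0] < 300.0 - 1.0

    def test_voxels_below_floor_marked_invalid(self):
        data = np.zeros((2, 1, 5))
        data[0, 0] = 100.0 * np.exp(-0.05 * np.array(CONES_UTE.echo_times))
        data[1, 0] = 0.5  # below floor at every echo
        s = MultiEchoSeries(data=data, echo_times=CONES_UTE.echo_times, protocol=CONES_UTE)
        fit = fit_loglinear(s, signal_floor=1.0)
        assert fit.valid_mask[0, 0] and not fit.valid_mask[1, 0]
        assert np.isnan(fit.rate[1, 0])

    def test_all_invalid_image_returns_false_mask_not_error(self):
        s = _voxel_series([0.1] * 5)
        fit = fit_loglinear(s, signal_floor=1.0)
        assert not fit.valid_mask.any()

    def test_echoes_below_floor_excluded_from_fit(self):
        # last two echoes corrupted below the floor; fit uses first three only
        te = np.array(CONES_UTE.echo_times)
        sig = 100.0 * np.exp(-0.1 * te)
        sig[3:] = 0.01
        fit = fit_loglinear(_voxel_series(sig), signal_floor=1.0)
        assert fit.rate[0, 0] == pytest.approx(100.0, rel=1e-9)

    def test_signal_floor_must_be_positive(self, cones_noiseless):
        with pytest.raises(ValueError, match="signal_floor"):
            fit_loglinear(cones_noiseless, 0.0)

    def test_negative_rates_retained_not_clipped(self):
        te = np.array(CONES_UTE.echo_times)
        fit = fit_loglinear(_voxel_series(10.0 * np.exp(0.02 * te)), 1e-12)
        assert fit.rate[0, 0] == pytest.approx(-20.0, rel=1e-9)
        assert fit.valid_mask[0, 0]


class TestRatioMap:
    def test_definitional_value(self):
        s = _voxel_series([100.0, 80.0, 60.0, 45.0, 36.79])
        r15 = ratio_map(s, "R15")
        assert r15.value[0, 0] == pytest.approx(0.6321, abs=1e-4)
        assert r15.echo_pair == (0, 4)

    def test_no_signal_loss_gives_zero_ratios(self):
        s = _voxel_series([70.0] * 5)
        for kind in ("R12", "R15", "R25"):
            assert ratio_map(s, kind).value[0, 0] == 0.0

    def test_multiplicative_identity_noiseless(self, cones_noiseless, phantom_spio):
        r12 = ratio_map(cones_noiseless, "R12")
        r15 = ratio_map(cones_noiseless, "R15")
        r25 = ratio_map(cones_noiseless, "R25")
        fg = phantom_spio.label_map > 0
        lhs = 1.0 - r15.value[fg]
        rhs = (1.0 - r12.value[fg]) * (1.0 - r25.value[fg])
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_ratio_bounds_on_noiseless_decay(self, cones_noiseless, phantom_spio):
        fg = phantom_spio.label_map > 0
        for kind in ("R12", "R15", "R25"):
            v = ratio_map(cones_noiseless, kind).value[fg]
            assert np.all(v >= 0.0) and np.all(v < 1.0)

    def test_zero_denominator_masked(self):
        s = _voxel_series([0.0, 0.0, 0.0, 0.0, 0.0])
        r = ratio_map(s, "R15")
        assert not r.valid_mask[0, 0]
        assert np.isnan(r.value[0, 0])

    def test_unknown_kind_rejected(self, cones_noiseless):
        with pytest.raises(ValueError, match="unknown ratio kind"):
            ratio_map(cones_noiseless, "R13")

    def test_needs_five_echoes_for_r15(self):
        s = MultiEchoSeries(
            data=np.ones((1, 1, 3)),
            echo_times=(1.0, 2.0, 3.0),
            protocol=CONES_UTE.__class__(
                name="short", echo_times=(1.0, 2.0, 3.0), tr=50.0,
                flip_angle=10.0, mode="r2star",
            ),
        )
        with pytest.raises(ValueError, match="at least 5 echoes"):
            ratio_map(s, "R15")


class TestTwoPointR2star:
    def test_zero_ratio_gives_zero_rate(self):
        s = _voxel_series([50.0] * 5)
        tp = two_point_r2star(ratio_map(s, "R12"))
        assert tp.rate[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_recovers_rate_from_r12_at_cones_echoes(self):
        te = np.array(CONES_UTE.echo_times)
        s = _voxel_series(100.0 * np.exp(-0.064 * te))
        tp = two_point_r2star(ratio_map(s, "R12"))
        assert tp.rate[0, 0] == pytest.approx(64.0, abs=1e-9)

    def test_unit_definition(self):
        # R = 1 - e^-1 over dTE = 1 s -> rate exactly 1 s^-1
        r = RatioMap(
            value=np.array([[1.0 - np.exp(-1.0)]]),
            echo_pair=(0, 1),
            kind="R12",
            valid_mask=np.array([[True]]),
            echo_times=(0.0, 1000.0),
        )
        tp = two_point_r2star(r)
        assert tp.rate[0, 0] == pytest.approx(1.0, rel=1e-12)

    def test_matches_full_fit_on_noiseless_data(self, cones_noiseless, phantom_spio):
        fit = fit_loglinear(cones_noiseless, 1e-12)
        tp = two_point_r2star(ratio_map(cones_noiseless, "R15"))
        both = fit.valid_mask & tp.valid_mask & (phantom_spio.label_map > 0)
        np.testing.assert_allclose(tp.rate[both], fit.rate[both], atol=1e-9)

    def test_out_of_range_ratio_masked(self):
        r = RatioMap(
            value=np.array([[-0.2, 1.0]]),
            echo_pair=(0, 1),
            kind="R12",
            valid_mask=np.array([[True, True]]),
            echo_times=(0.0, 10.0),
        )
        tp = two_point_r2star(r)
        assert not tp.valid_mask.any()

    def test_degenerate_echo_pair_rejected(self):
        r = RatioMap(
            value=np.array([[0.5]]),
            echo_pair=(0, 1),
            kind="R12",
            valid_mask=np.array([[True]]),
            echo_times=(4.0, 4.0),
        )
        with pytest.raises(ValueError, match="degenerate"):
            two_point_r2star(r)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(rate=st.floats(0.0, 280.0), pd=st.floats(1.0, 500.0))
    def test_inversion_exact_for_any_monoexponential(self, rate, pd):
        te = np.array(CONES_UTE.echo_times)
        s = _voxel_series(pd * np.exp(-rate * te * 1e-3))
        tp = two_point_r2star(ratio_map(s, "R15"))
        assert tp.rate[0, 0] == pytest.approx(rate, abs=1e-6)


class TestSubtractionImage:
    def test_identical_echoes_give_zero(self):
        s = _voxel_series([70.0] * 5)
        assert subtraction_image(s, 0, 1)[0, 0] == 0.0

    def test_fast_decay_brighter_than_slow(self, phantom_spio):
        # equal PD, bone decays faster than muscle -> larger subtraction value
        table = {
            "tibial_bone": TissueSpec("tibial_bone", 80.0, 300.0, 250.0),
            "dorsal_muscle": TissueSpec("dorsal_muscle", 80.0, 35.0, 28.0),
        }
        ph = generate_phantom(PhantomConfig(shape=(64, 64), tissues=table), seed=0)
        s = simulate_series(ph, CONES_UTE, 0.0)
        sub = subtraction_image(s, 0, 1)
        assert sub[ph.roi_mask("tibial_bone")].mean() > sub[ph.roi_mask("dorsal_muscle")].mean()

    def test_defect_vs_bone_ordering_follows_rates(self, phantom_spio, cones_noiseless):
        # default defect rate (50) < bone rate (300): bone brighter in subtraction
        sub = subtraction_image(cones_noiseless, 0, 1)
        bone = sub[phantom_spio.roi_mask("tibial_bone")].mean()
        defect = sub[phantom_spio.roi_mask("defect_region")].mean()
        pd_bone = phantom_spio.tissues[phantom_spio.roi_codes["tibial_bone"]]
        pd_def = phantom_spio.tissues[phantom_spio.roi_codes["defect_region"]]
        # normalise away the PD difference before comparing decay contrast
        assert bone / pd_bone.proton_density > defect / pd_def.proton_density

    def test_out_of_range_indices_rejected(self, cones_noiseless):
        with pytest.raises(IndexError):
            subtraction_image(cones_noiseless, 0, 7)
        with pytest.raises(ValueError, match="i < j"):
            subtraction_image(cones_noiseless, 2, 1)

    def test_may_be_negative_under_noise(self, phantom_small):
        s = simulate_series(phantom_small, CONES_UTE, 5.0, seed=2)
        assert subtraction_image(s, 0, 1).min() < 0


class TestModelResults:
    def test_model_fit_summary(self, cones_noiseless):
        res = MonoExponentialModel(cones_noiseless).fit()
        assert res.valid_fraction > 0.5
        text = res.summary()
        assert "rate median" in text and "r2star" in text

    def test_default_floor_scales_with_noise(self, phantom_small):
        s = simulate_series(phantom_small, CONES_UTE, 2.0, seed=0)
        assert default_signal_floor(s) == pytest.approx(6.0)
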