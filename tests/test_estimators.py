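"""MBF estimators: baseline, maximum upslope, true MBF, Patlak, F=K1/E."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctmpi import (
    ContrastCurve,
    EstimationError,
    InvalidInputError,
    TissueKinetics,
    UpslopeConfig,
    baseline_value,
    flow_from_k1,
    generate_aif,
    max_upslope,
    mbf_upslope,
    patlak_k1,
    peak_enhancement,
    sample_curve,
    tissue_curve,
    true_mbf,
)
from ctmpi.kinetics import AifParameters

CFG = UpslopeConfig()

#: early Patlak window anchored at the true contrast arrival (5 s injection
#: + 4 s transit); short enough that back-flux stays negligible
EARLY_WINDOW = (9.0, 10.5)


class TestBaselineAndPeak:
    def test_constant_curve(self):
        t = np.linspace(0.0, 60.0, 61)
        c = ContrastCurve(t, np.full(61, 40.0), injection_start=5.0)
        assert baseline_value(c, CFG) == 40.0
        assert peak_enhancement(c, CFG) == 0.0

    def test_baseline_is_mean_of_pre_injection_samples(self):
        c = ContrastCurve([1.0, 2.0, 3.0, 10.0], [38.0, 40.0, 42.0, 100.0], 5.0)
        assert baseline_value(c, CFG) == pytest.approx(40.0)

    def test_noise_free_default_aif_baseline_exact(self, default_aif):
        assert baseline_value(default_aif, CFG) == 40.0

    def test_dense_aif_peak_matches_configured_amplitude(self, default_aif):
        assert peak_enhancement(default_aif, CFG) == pytest.approx(250.0, rel=1e-3)

    def test_subsampled_peak_never_exceeds_dense(self, default_aif):
        rng = np.random.default_rng(0)
        dense = peak_enhancement(default_aif, CFG)
        for _ in range(10):
            keep = np.sort(rng.choice(default_aif.times.size, 40, replace=False))
            sub = sample_curve(default_aif, default_aif.times[keep])
            assert peak_enhancement(sub, CFG) <= dense + 1e-9

    def test_no_pre_injection_samples_is_an_error(self):
        c = ContrastCurve([10.0, 11.0, 12.0], [1.0, 2.0, 3.0], 5.0)
        with pytest.raises(EstimationError, match="baseline"):
            baseline_value(c, CFG)


class TestMaxUpslope:
    @pytest.mark.parametrize("window", [2, 3, 5, 17])
    def test_exact_on_linear_ramp(self, window):
        t = np.linspace(0.0, 30.0, 301)
        ramp = ContrastCurve(t, 10.0 * t, injection_start=5.0)
        cfg = UpslopeConfig(slope_window=window)
        assert max_upslope(ramp, cfg) == pytest.approx(10.0, rel=1e-9)

    def test_zero_on_constant(self):
        t = np.linspace(0.0, 30.0, 301)
        flat = ContrastCurve(t, np.full(301, 40.0), injection_start=5.0)
        assert max_upslope(flat, CFG) == pytest.approx(0.0, abs=1e-9)

    def test_recovers_kinetic_identity_on_dense_tac(self, ideal_tac_factory):
        # in the ideal limit the TAC's max slope is k_in * max AIF enhancement
        tac, kin = ideal_tac_factory(2.0)
        assert max_upslope(tac, CFG) == pytest.approx(kin.k_in_per_s * 250.0, rel=0.01)

    def test_too_few_samples(self):
        c = ContrastCurve([0.0, 1.0], [0.0, 1.0], 0.5)
        with pytest.raises(EstimationError):
            max_upslope(c, UpslopeConfig(slope_window=3))

    def test_window_two_vs_three_agree_on_dense_data(self, ideal_tac_factory):
        tac, _ = ideal_tac_factory(2.0)
        s2 = max_upslope(tac, UpslopeConfig(slope_window=2))
        s3 = max_upslope(tac, UpslopeConfig(slope_window=3))
        assert s2 == pytest.approx(s3, rel=0.05)


class TestMbfUpslope:
    def test_arithmetic(self):
        t = np.linspace(0.0, 30.0, 301)
        tac = ContrastCurve(t, 2.0 * np.clip(t - 6.0, 0.0, None), injection_start=5.0)
        peak = np.where(t > 6.0, 120.0, 0.0)
        aif = ContrastCurve(t, peak, injection_start=5.0)
        est = mbf_upslope(tac, aif, CFG, tissue_density=1.0)
        assert est.value == pytest.approx(1.0, rel=1e-6)  # 60*2/120
        est = mbf_upslope(tac, aif, CFG, tissue_density=1.05)
        assert est.value == pytest.approx(60 * 2 / (120 * 1.05), rel=1e-6)

    def test_zero_aif_peak_is_an_error(self):
        t = np.linspace(0.0, 30.0, 301)
        flat = ContrastCurve(t, np.full(301, 40.0), injection_start=5.0)
        with pytest.raises(EstimationError, match="peak"):
            mbf_upslope(flat, flat, CFG)

    @pytest.mark.parametrize("flow", [0.5, 1.0, 2.0, 4.0])
    def test_ideal_limit_recovery(self, default_aif, ideal_tac_factory, flow):
        # dense sampling, E=1, no washout, no noise: within 2% of truth
        tac, _ = ideal_tac_factory(flow)
        est = mbf_upslope(tac, default_aif, CFG, tissue_density=1.05)
        assert est.value == pytest.approx(flow, rel=0.02)

    def test_scale_equivariance(self, default_aif, ideal_tac_factory):
        tac, _ = ideal_tac_factory(2.0)
        base = mbf_upslope(tac, default_aif, CFG).value
        scale = 3.7
        tac2 = tac.replace(values=40.0 + scale * (tac.values - 40.0))
        aif2 = default_aif.replace(values=40.0 + scale * (default_aif.values - 40.0))
        both = mbf_upslope(tac2, aif2, CFG).value
        only_tac = mbf_upslope(tac2, default_aif, CFG).value
        assert both == pytest.approx(base, rel=1e-9)
        assert only_tac == pytest.approx(scale * base, rel=1e-9)

    def test_subsampling_never_raises_noise_free_slope_or_peak(
        self, default_aif, ideal_tac_factory
    ):
        # max over fewer local slopes of a smooth curve cannot exceed the
        # dense maximum, and a sampled maximum cannot exceed the dense peak
        tac, _ = ideal_tac_factory(2.0)
        dense_slope = max_upslope(tac, CFG)
        dense_peak = peak_enhancement(default_aif, CFG)
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = rng.integers(20, 200)
            keep = np.sort(rng.choice(default_aif.times.size, n, replace=False))
            t_sub = default_aif.times[keep]
            assert max_upslope(sample_curve(tac, t_sub), CFG) <= dense_slope + 1e-9
            assert (
                peak_enhancement(sample_curve(default_aif, t_sub), CFG)
                <= dense_peak + 1e-9
            )


class TestTrueMbf:
    def test_examples(self):
        assert true_mbf(300.0, 300.0) == 1.0
        assert true_mbf(0.0, 300.0) == 0.0
        assert true_mbf(1100.0, 500.0) == pytest.approx(2.2)

    def test_invalid_weight(self):
        with pytest.raises(InvalidInputError):
            true_mbf(300.0, 0.0)


class TestPatlak:
    def test_exact_linear_relation(self):
        # C_t = kappa * cumulative integral of c_a => slope kappa exactly
        t = np.arange(0.0, 60.005, 0.01)
        aif = generate_aif(AifParameters(baseline_hu=0.0), t, injection_start=5.0)
        kappa = 0.01
        from scipy.integrate import cumulative_trapezoid

        ct = kappa * cumulative_trapezoid(aif.values, t, initial=0.0)
        tac = ContrastCurve(t, ct, injection_start=5.0)
        est = patlak_k1(tac, aif, CFG, fit_window=(10.0, 30.0), tissue_density=1.0)
        assert est.k1 == pytest.approx(60.0 * kappa, rel=1e-6)

    def test_constant_input_closed_form(self):
        # constant c_a = c, C_t = kappa*c*t: x = t, y = kappa*t, slope kappa
        t = np.arange(0.0, 30.005, 0.01)
        c_a = np.where(t >= 5.0, 100.0, 0.0)
        kappa = 0.02
        ct = kappa * 100.0 * np.clip(t - 5.0, 0.0, None)
        est = patlak_k1(
            ContrastCurve(t, ct, 5.0),
            ContrastCurve(t, c_a, 5.0),
            CFG,
            fit_window=(6.0, 25.0),
            tissue_density=1.0,
        )
        assert est.k1 == pytest.approx(60.0 * kappa, rel=1e-4)

    @pytest.mark.parametrize("extraction", [0.4, 0.6, 0.8, 1.0])
    def test_early_window_recovers_k1_and_flow(self, default_aif, extraction):
        flow = 2.0
        kin = TissueKinetics(flow_f=flow, extraction_e=extraction)
        tac = tissue_curve(default_aif, kin, baseline_hu=40.0)
        est = patlak_k1(tac, default_aif, CFG, fit_window=EARLY_WINDOW)
        assert est.k1 == pytest.approx(kin.k1, rel=0.05)
        assert flow_from_k1(est.k1, extraction) == pytest.approx(flow, rel=0.05)

    def test_degenerate_regressor_is_an_error(self):
        t = np.linspace(0.0, 30.0, 31)
        flat = ContrastCurve(t, np.full(31, 40.0), injection_start=5.0)
        with pytest.raises(EstimationError):
            patlak_k1(flat, flat, CFG, fit_window=(6.0, 25.0))

    def test_mismatched_grids_rejected(self, default_aif):
        short = ContrastCurve([0.0, 1.0, 2.0], [40.0, 41.0, 42.0], 0.5)
        with pytest.raises(InvalidInputError):
            patlak_k1(short, default_aif, CFG, fit_window=(0.0, 2.0))


class TestFlowFromK1:
    def test_examples(self):
        assert flow_from_k1(0.5, 0.5) == 1.0
        assert flow_from_k1(1.2, 1.0) == 1.2

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(k1=st.floats(0.0, 5.0), e=st.floats(0.05, 1.0))
    def test_inverse_of_product(self, k1, e):
        assert flow_from_k1(k1 * e, e) == pytest.approx(k1, rel=1e-12, abs=1e-12)

    def test_domain(self):
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(InvalidInputError):
                flow_from_k1(1.0, bad)
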