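"""Fick-principle metabolic-rate computations and error propagation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from renoximetry import fick


class TestHbToHct:
    @pytest.mark.parametrize(
        "hb, expected",
        [(14.28, 0.42), (0.34, 0.01), (11.56, 0.34)],
    )
    def test_conversion_rule(self, hb, expected):
        assert fick.hb_to_hct(hb) == pytest.approx(expected, abs=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            fick.hb_to_hct(0.0)


class TestKidneyMass:
    def test_density_rule(self):
        assert fick.kidney_mass_from_volume(162.26) == pytest.approx(172.0, abs=0.01)
        assert fick.kidney_mass_from_volume(100.0) == pytest.approx(106.0)

    def test_rejects_nonpositive_volume(self):
        with pytest.raises(ValueError):
            fick.kidney_mass_from_volume(0.0)


class TestUnilateralRate:
    def test_baseline_cohort_means(self):
        # CRBC*Hct*BFR*(SaO2-SvO2)/mass*100 at the baseline cohort means.
        value = fick.unilateral_rmro2(410.0, 0.99, 0.92, 0.42, 172.0)
        assert value == pytest.approx(139.672, abs=1e-3)
        assert fick.round_for_report(value, "rmro2") == 140.0

    def test_moderate_hypoxia_cohort_means(self):
        value = fick.unilateral_rmro2(440.0, 0.84, 0.76, 0.42, 172.0)
        assert value == pytest.approx(171.305, abs=1e-3)
        assert fick.round_for_report(value, "rmro2") == 170.0

    def test_zero_extraction(self):
        assert fick.unilateral_rmro2(410.0, 0.9, 0.9, 0.42, 172.0) == 0.0

    def test_negative_rate_flagged_not_clipped(self):
        with pytest.warns(RuntimeWarning, match="negative"):
            value = fick.unilateral_rmro2(410.0, 0.85, 0.92, 0.42, 172.0)
        assert value < 0

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            fick.unilateral_rmro2(410.0, 0.99, 0.92, 0.42, 0.0)

    @settings(max_examples=50, derandomize=True)
    @given(k=st.floats(0.1, 10.0))
    def test_homogeneity_in_flow(self, k):
        base = fick.unilateral_rmro2(410.0, 0.99, 0.92, 0.42, 172.0)
        scaled = fick.unilateral_rmro2(410.0 * k, 0.99, 0.92, 0.42, 172.0)
        assert scaled == pytest.approx(base * k, rel=1e-12)

    def test_inverse_in_mass(self):
        base = fick.unilateral_rmro2(410.0, 0.99, 0.92, 0.42, 172.0)
        assert fick.unilateral_rmro2(410.0, 0.99, 0.92, 0.42, 344.0) == pytest.approx(
            base / 2.0, rel=1e-12
        )


class TestBilateral:
    def test_mixing_identity_equal_saturations(self):
        for qvs, qvi in [(2420.0, 1390.0), (3000.0, 400.0)]:
            assert fick.bilateral_svo2(qvs, 0.8, qvi, 0.8) == pytest.approx(0.8, rel=1e-14)

    def test_flow_weighted_example(self):
        value = fick.bilateral_svo2(2420.0, 0.83, 1390.0, 0.71)
        assert value == pytest.approx(0.991942, abs=1e-6)

    def test_algebraic_construction(self):
        # qvs = 2*qvi and svo2s = (Y + svo2i)/2 recovers Y.
        y, svo2i, qvi = 0.9, 0.7, 1000.0
        value = fick.bilateral_svo2(2 * qvi, (y + svo2i) / 2.0, qvi, svo2i)
        assert value == pytest.approx(y, rel=1e-12)

    def test_equal_flows_rejected(self):
        with pytest.raises(ZeroDivisionError):
            fick.bilateral_svo2(1000.0, 0.8, 1000.0, 0.7)

    def test_out_of_range_mixture_warned_not_clipped(self):
        with pytest.warns(RuntimeWarning, match="outside"):
            value = fick.bilateral_svo2(2000.0, 0.95, 1800.0, 0.40)
        assert value > 1.0

    def test_difference_and_mixed_forms_agree(self):
        import warnings as _warnings

        rng = np.random.default_rng(0)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            for _ in range(10_000):
                qvi = rng.uniform(500.0, 2500.0)
                qvs = qvi + rng.uniform(100.0, 1800.0)
                svo2s, svo2i = rng.uniform(0.4, 0.95, 2)
                sao2 = rng.uniform(0.8, 1.0)
                hct = rng.uniform(0.3, 0.5)
                mass = rng.uniform(200.0, 450.0)
                a = fick.bilateral_rmro2(qvs, svo2s, qvi, svo2i, sao2, hct, mass,
                                         form="difference")
                b = fick.bilateral_rmro2(qvs, svo2s, qvi, svo2i, sao2, hct, mass,
                                         form="mixed")
                assert a == pytest.approx(b, rel=1e-12, abs=1e-9)

    def test_collapses_to_unilateral_with_equal_saturations(self):
        y = 0.85
        bilateral = fick.bilateral_rmro2(2420.0, y, 1390.0, y, 0.99, 0.42, 331.0)
        unilateral = fick.unilateral_rmro2(2420.0 - 1390.0, 0.99, y, 0.42, 331.0)
        assert bilateral == pytest.approx(unilateral, rel=1e-12)

    def test_negative_bilateral_flagged(self):
        with pytest.warns(RuntimeWarning, match="negative bilateral"):
            value = fick.bilateral_rmro2(2420.0, 0.83, 1390.0, 0.60, 0.99, 0.42, 331.0)
        assert value < 0


class TestUncertainty:
    POINT = dict(bfr=410.0, sao2=0.99, svo2=0.92, hct=0.42, kidney_mass=172.0)

    def test_svo2_only_matches_analytic_partial(self):
        budget = fick.propagate_uncertainty(
            **self.POINT, input_sds={"svo2": 0.02}, method="linear"
        )
        rate = fick.unilateral_rmro2(**self.POINT)
        assert budget.rmro2_sd_linear / rate == pytest.approx(0.02 / 0.07, rel=1e-9)

    def test_zero_sds_give_zero_spread(self):
        budget = fick.propagate_uncertainty(
            **self.POINT, input_sds={}, method="both", n_draws=2000, seed=0
        )
        assert budget.rmro2_sd_linear == 0.0
        assert budget.rmro2_sd_mc == pytest.approx(0.0, abs=1e-9)

    def test_linear_and_monte_carlo_agree_at_small_cv(self):
        sds = {k: 0.02 * v for k, v in self.POINT.items()}
        budget = fick.propagate_uncertainty(
            **self.POINT, input_sds=sds, method="both", n_draws=200_000, seed=1
        )
        assert budget.rmro2_sd_mc == pytest.approx(budget.rmro2_sd_linear, rel=0.05)

    def test_sensitivity_signs(self):
        budget = fick.propagate_uncertainty(**self.POINT, input_sds={}, method="linear")
        assert budget.sensitivity["svo2"] < 0
        assert budget.sensitivity["kidney_mass"] < 0
        assert budget.sensitivity["sao2"] > 0
        assert budget.sensitivity["bfr"] > 0

    def test_rejects_unknown_parameter_and_small_mc(self):
        with pytest.raises(ValueError):
            fick.propagate_uncertainty(**self.POINT, input_sds={"venc": 1.0})
        with pytest.raises(ValueError):
            fick.propagate_uncertainty(
                **self.POINT, input_sds={}, method="monte_carlo", n_draws=10
            )


class TestReportRounding:
    @pytest.mark.parametrize(
        "value, kind, expected",
        [
            (139.7, "rmro2", 140.0),
            (171.3, "rmro2", 170.0),
            (135.0, "bfr", 140.0),  # half away from zero
            (-135.0, "rmro2", -140.0),
            (92.4, "svo2", 92.0),
            (92.5, "svo2", 93.0),
            (158.6, "t2", 159.0),
            (1030.0, "delta_bfr", 1030.0),
        ],
    )
    def test_rounding_rules(self, value, kind, expected):
        assert fick.round_for_report(value, kind) == expected

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            fick.round_for_report(1.0, "venc")
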