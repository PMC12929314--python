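import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmpcea.cea_engine import (
    DEFAULT_LAMBDA_GRID,
    ParameterDistribution,
    PSASpec,
    ceac_from_cloud,
    default_psa_spec,
    deterministic_ce,
    icer,
    incremental,
    nmb,
    per_patient_arm_cost,
    quadrant,
    run_psa,
    sample_parameters,
    tornado_one_way,
)
from nmpcea.params_io import ModelConfig


class TestDeterministicLayer:
    @pytest.mark.parametrize(
        "args,expected",
        [
            ((169, 179, 0.7403, 0.7525), (-10, -0.0122)),
            ((134, 129, 0.7299, 0.7359), (5, -0.0060)),
            ((100, 100, 0.5, 0.5), (0, 0)),
        ],
    )
    def test_incremental(self, args, expected):
        d_cost, d_effect = incremental(*args)
        assert d_cost == pytest.approx(expected[0])
        assert d_effect == pytest.approx(expected[1])

    def test_icer_sw_quadrant_cost_per_qaly_lost(self):
        res = icer(-10, -0.0122)
        assert res.value == pytest.approx(819.67, abs=0.01)
        assert res.quadrant == "SW"
        assert "lost" in res.label

    def test_icer_free_improvement(self):
        assert icer(0, 0.1).value == 0.0

    def test_icer_zero_effect_is_undefined_not_an_error(self):
        res = icer(5, 0)
        assert res.value is None
        assert "undefined" in res.label

    @pytest.mark.parametrize(
        "wtp,dE,dC,expected",
        [(30_000, -0.0122, -10, -356.0), (30_000, 0, 0, 0.0), (0, 0.5, 42, -42.0)],
    )
    def test_nmb(self, wtp, dE, dC, expected):
        assert nmb(wtp, dE, dC) == pytest.approx(expected)

    def test_nmb_rejects_negative_wtp(self):
        with pytest.raises(ValueError):
            nmb(-1, 0, 0)

    @pytest.mark.parametrize(
        "dC,dE,q",
        [
            (-10, -0.0122, "SW"),
            (5, -0.006, "NW"),
            (5, 0.006, "NE"),
            (-5, 0.006, "SE"),
            (0, 0.5, "on-axis"),
            (3, 0, "on-axis"),
        ],
    )
    def test_quadrant(self, dC, dE, q):
        assert quadrant(dC, dE) == q

    @settings(deadline=None, max_examples=200)
    @given(dC=st.floats(-500, 500), dE=st.floats(-0.5, 0.5),
           wtp=st.floats(0, 100_000))
    def test_nmb_icer_quadrant_mutual_consistency(self, dC, dE, wtp):
        """NMB > 0 exactly when wtp x dE > dC; ICER consistent with both."""
        assert (nmb(wtp, dE, dC) > 0) == (wtp * dE > dC)
        res = icer(dC, dE)
        if dE != 0:
            assert res.value == pytest.approx(dC / dE)
        assert res.quadrant == quadrant(dC, dE)

    def test_nmb_linear_in_wtp(self):
        dC, dE = -10.0, -0.0122
        vals = [nmb(lam, dE, dC) for lam in (0, 10_000, 20_000)]
        assert vals[2] - vals[1] == pytest.approx(vals[1] - vals[0])


class TestSampler:
    def test_same_seed_bit_identical(self):
        spec = PSASpec(
            distributions=(
                ParameterDistribution("c", "gamma", 188.0, 72.0),
                ParameterDistribution("p", "beta", 0.3, 0.075),
            ),
            iterations=500, seed=11,
        )
        a, b = sample_parameters(spec), sample_parameters(spec)
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_distribution_draws_the_point(self):
        spec = PSASpec(
            distributions=(ParameterDistribution("x", "fixed", 42.0, 0.0),),
            iterations=100, seed=0,
        )
        assert (sample_parameters(spec)["x"] == 42.0).all()

    def test_gamma_mean_preserved(self):
        spec = PSASpec(
            distributions=(ParameterDistribution("c_referral", "gamma", 188.0, 72.0),),
            iterations=5_000, seed=0,
        )
        draws = sample_parameters(spec)["c_referral"]
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - 188.0) < 2 * se

    def test_beta_draws_stay_in_unit_interval(self):
        spec = PSASpec(
            distributions=(ParameterDistribution("p", "beta", 0.3, 0.075),),
            iterations=2_000, seed=0,
        )
        draws = sample_parameters(spec)["p"]
        assert draws.between(0, 1).all()

    def test_unsupported_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            ParameterDistribution("x", "lognormal", 1.0, 1.0)


class TestCeac:
    def test_counting_oracle(self):
        rng = np.random.default_rng(4)
        dC, dE = rng.normal(0, 100, 400), rng.normal(0, 0.03, 400)
        curve = ceac_from_cloud(dC, dE, [0.0, 20_000.0, 30_000.0])
        for _, row in curve.iterrows():
            brute = sum(
                1 for c, e in zip(dC, dE) if row["wtp"] * e - c > 0
            ) / len(dC)
            assert row["p_cost_effective"] == pytest.approx(brute)

    def test_dominant_cloud_always_cost_effective(self):
        dC = np.full(50, -5.0)
        dE = np.full(50, 0.01)
        curve = ceac_from_cloud(dC, dE, DEFAULT_LAMBDA_GRID)
        assert (curve["p_cost_effective"] == 1.0).all()

    def test_nmb_tie_counts_as_not_cost_effective(self):
        # lambda x dE - dC == 0 exactly: strict rule says not cost-effective
        curve = ceac_from_cloud(np.array([0.0]), np.array([0.0]), [30_000.0])
        assert curve["p_cost_effective"].iloc[0] == 0.0


class TestPsa:
    def test_degenerate_psa_collapses_to_base_case(self, dietitian_fixture):
        config = ModelConfig(psa_iterations=50)
        base = deterministic_ce(dietitian_fixture, config)
        spec = PSASpec(
            distributions=(
                ParameterDistribution("cost_prescriber", "fixed", 169.0, 0.0),
                ParameterDistribution("cost_non_prescriber", "fixed", 179.0, 0.0),
                ParameterDistribution("effect_difference", "fixed", -0.0122, 0.0),
            ),
            iterations=50, seed=0,
        )
        res = run_psa(dietitian_fixture, config, spec)
        assert (res.psa_cloud["delta_cost"] == base.delta_cost).all()
        assert (res.psa_cloud["delta_effect"] == base.delta_effect).all()

    def test_psa_reproducible_under_seed(self, dietitian_fixture):
        config = ModelConfig(psa_iterations=300, rng_seed=9)
        a = run_psa(dietitian_fixture, config)
        b = run_psa(dietitian_fixture, config)
        pd.testing.assert_frame_equal(a.psa_cloud, b.psa_cloud)
        assert a.p_cost_effective == b.p_cost_effective

    def test_quadrant_shares_sum_to_at_most_one(self, tr_fixture):
        res = run_psa(tr_fixture, ModelConfig(
            profession="therapeutic_radiographer", psa_iterations=500))
        assert 0.999 <= sum(res.quadrant_shares.values()) <= 1.0 + 1e-9

    def test_ceac_grid_includes_threshold(self, dietitian_fixture):
        res = run_psa(dietitian_fixture, ModelConfig(psa_iterations=100))
        assert 30_000.0 in set(res.ceac["wtp"])


class TestTornado:
    def test_zero_width_parameter_has_zero_swing_and_ranks_last(
        self, dietitian_fixture, base_config
    ):
        entries = tornado_one_way(dietitian_fixture, base_config)
        fixed = [e for e in entries if e.parameter == "training.taught_days"]
        assert fixed and fixed[0].swing == 0.0
        assert entries[-1].swing == 0.0

    def test_sorted_descending_by_swing(self, dietitian_fixture, base_config):
        swings = [e.swing for e in tornado_one_way(dietitian_fixture, base_config)]
        assert swings == sorted(swings, reverse=True)

    def test_linear_parameter_swing_is_slope_times_width(
        self, dietitian_fixture, base_config
    ):
        """NMB is linear in the non-prescriber referral cost with slope
        p_refer (cost enters the comparator arm), so the swing is exactly
        |slope| x (high - low)."""
        entries = tornado_one_way(dietitian_fixture, base_config)
        e = next(x for x in entries
                 if x.parameter == "activity.non_prescriber.c_referral")
        p_refer = dietitian_fixture.activity["non_prescriber"]["p_refer"].point
        assert e.swing == pytest.approx(p_refer * (e.high - e.low), rel=1e-9)

    def test_influential_parameters_include_referral_terms(
        self, dietitian_fixture, base_config
    ):
        top = {e.parameter for e in tornado_one_way(dietitian_fixture, base_config)[:6]}
        assert any("c_referral" in p for p in top)
        assert any("p_refer" in p for p in top)


class TestDenovoArmCost:
    def test_prescriber_arm_carries_training_cost(self, dietitian_fixture, base_config):
        with_training = per_patient_arm_cost(dietitian_fixture, base_config, "prescriber")
        np_cost = per_patient_arm_cost(dietitian_fixture, base_config, "non_prescriber")
        assert with_training > 0 and np_cost > 0

    def test_non_prescriber_cost_matches_hand_arithmetic(
        self, dietitian_fixture, base_config
    ):
        # c_std + p_refer x c_referral = 123 + 0.30 x 188
        cost = per_patient_arm_cost(dietitian_fixture, base_config, "non_prescriber")
        assert cost == pytest.approx(123 + 0.30 * 188, rel=1e-9)
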