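import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmpcea.effectiveness import (
    ValueSet,
    add_scores,
    adjust_group_means,
    bootstrap_mean_difference,
    scale_likert,
    score_eq5d,
    toy_value_set,
    utility_to_qaly,
)
from nmpcea.synthetic_data import SynthDesign, generate_patients


class TestEq5dScoring:
    def test_perfect_health_anchor(self, value_set):
        assert score_eq5d("11111", value_set) == 1.0

    def test_toy_set_worst_state_is_zero(self, value_set):
        assert score_eq5d("55555", value_set) == pytest.approx(0.0)

    def test_toy_set_single_step(self, value_set):
        assert score_eq5d("21111", value_set) == pytest.approx(0.95)

    @pytest.mark.parametrize("state", ["1111", "111111", "11110", "61111", "1a111"])
    def test_invalid_state_rejected(self, state, value_set):
        with pytest.raises(ValueError):
            score_eq5d(state, value_set)

    def test_missing_state_raises_lookup_error(self):
        partial = ValueSet({"11111": 1.0}, name="partial")
        with pytest.raises(KeyError, match="partial"):
            score_eq5d("21111", partial)

    def test_value_set_must_anchor_full_health(self):
        with pytest.raises(ValueError, match="anchor"):
            ValueSet({"11111": 0.9})

    def test_value_set_roundtrip(self, tmp_path, value_set):
        value_set.to_table(tmp_path / "vs.csv")
        back = ValueSet.from_table(tmp_path / "vs.csv")
        assert back.values == value_set.values

    def test_scoring_is_order_invariant(self, value_set):
        states = ["31245", "11111", "55555", "12345"]
        fwd = [score_eq5d(s, value_set) for s in states]
        rev = [score_eq5d(s, value_set) for s in reversed(states)]
        assert fwd == rev[::-1]


class TestQalyAndLikert:
    @pytest.mark.parametrize(
        "u,dur,expected", [(0.74, 1.0, 0.74), (1.0, 0.5, 0.5), (0.7403, 1.0, 0.7403)]
    )
    def test_qaly_is_utility_times_duration(self, u, dur, expected):
        assert utility_to_qaly(u, dur) == pytest.approx(expected)

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            utility_to_qaly(0.7, -1.0)

    @pytest.mark.parametrize(
        "items,score", [([5, 5, 5], 100.0), ([1, 1], 0.0), ([3, 4], 62.5)]
    )
    def test_likert_linear_rescale(self, items, score):
        assert scale_likert(items) == pytest.approx(score)

    def test_empty_likert_rejected(self):
        with pytest.raises(ValueError):
            scale_likert([])

    @settings(deadline=None, max_examples=50)
    @given(items=st.lists(st.integers(1, 5), min_size=1, max_size=8),
           bump=st.integers(0, 4))
    def test_likert_bounded_and_monotone(self, items, bump):
        s = scale_likert(items)
        assert 0.0 <= s <= 100.0
        raised = items.copy()
        raised[0] = min(5, raised[0] + bump)
        assert scale_likert(raised) >= s


class TestAdjustGroupMeans:
    def test_null_adjustment_recovers_raw_means(self):
        """With no covariate effects and no site variance the adjusted
        means coincide with the raw group means."""
        design = SynthDesign(
            patients_per_site=25, group_utility_effect=-0.05,
            site_random_sd=0.0, age_effect=0.0, gender_effect=0.0,
            general_health_effect=0.0, seed=7,
        )
        scored = add_scores(generate_patients(design))
        eff = adjust_group_means(scored, "qaly")
        raw = scored.groupby("group")["qaly"].mean()
        assert eff.mean_prescriber == pytest.approx(raw["prescriber"], abs=0.01)
        assert eff.mean_non_prescriber == pytest.approx(raw["non_prescriber"], abs=0.01)

    def test_known_effect_recovered_within_bootstrap_ci(self, scored_patients):
        boot = bootstrap_mean_difference(scored_patients, "qaly", n_reps=400, seed=5)
        assert boot.ci_low <= -0.05 <= boot.ci_high

    def test_bias_shrinks_with_sample_size(self):
        """Adjusted-difference bias goes to zero as the cohort grows."""
        errs = {}
        for n_per_site, seeds in ((3, range(5)), (13, range(5)), (50, range(5))):
            e = [
                adjust_group_means(
                    add_scores(generate_patients(SynthDesign(
                        patients_per_site=n_per_site,
                        group_utility_effect=-0.05, seed=100 + s,
                    ))),
                    "qaly",
                ).difference - (-0.05)
                for s in seeds
            ]
            errs[n_per_site] = abs(float(np.mean(e)))
        assert errs[50] < errs[3] + 0.01
        assert errs[50] < 0.02

    def test_single_group_rejected(self, scored_patients):
        only_p = scored_patients[scored_patients["group"] == "prescriber"]
        with pytest.raises(ValueError, match="both arms"):
            adjust_group_means(only_p, "qaly")

    def test_single_site_rejected(self, scored_patients):
        one_site = scored_patients[scored_patients["site"] == "site_1"]
        with pytest.raises(ValueError, match="two sites"):
            adjust_group_means(one_site, "qaly")

    def test_missing_outcome_column(self, scored_patients):
        with pytest.raises(KeyError):
            adjust_group_means(scored_patients, "waiting_time")


class TestBootstrap:
    def test_same_seed_gives_identical_ci(self, scored_patients):
        a = bootstrap_mean_difference(scored_patients, "qaly", n_reps=100, seed=3)
        b = bootstrap_mean_difference(scored_patients, "qaly", n_reps=100, seed=3)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert np.array_equal(a.samples, b.samples)

    def test_constant_outcome_gives_zero_width_ci_at_zero(self, scored_patients):
        flat = scored_patients.copy()
        flat["qaly"] = 0.7
        boot = bootstrap_mean_difference(flat, "qaly", n_reps=50, seed=1)
        assert boot.ci_low == pytest.approx(0.0, abs=1e-10)
        assert boot.ci_high == pytest.approx(0.0, abs=1e-10)

    def test_invalid_rep_count(self, scored_patients):
        with pytest.raises(ValueError):
            bootstrap_mean_difference(scored_patients, "qaly", n_reps=0)


def test_add_scores_attaches_all_outcomes(scored_patients):
    assert {"qaly", "satisfaction", "experience"} <= set(scored_patients.columns)
    assert scored_patients["qaly"].between(0, 1).all()
    assert scored_patients["satisfaction"].between(0, 100).all()
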