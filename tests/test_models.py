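"""Oracles and properties for the pure model mathematics.

Expected values are independent scalar evaluations of the value and choice
equations, frozen here (exp/logistic arithmetic done outside the package).
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cuetd.models import (
    ModelVariant,
    SubjectParams,
    apply_offset,
    choice_probability,
    dataset_pointwise_loglik,
    model_agnostic_td,
    modulated_beta,
    modulated_k,
    subjective_value_ll,
    trial_loglik,
)
from cuetd.task import ChoiceDataset, Trial

OFFSET = ModelVariant("offset")
BASE = ModelVariant("base")
TRIAL_38_14 = Trial(ll_amount=38.0, delay_days=14, i_ero=0, trial_index=0)


class TestModulatedParameters:
    @pytest.mark.parametrize("i_ero,expected", [
        (0, math.exp(-4.2)),           # 0.014995576820477703
        (1, math.exp(-4.05)),          # 0.017422374639493515
    ])
    def test_modulated_k_oracle(self, i_ero, expected):
        assert modulated_k(-4.2, 0.15, i_ero) == pytest.approx(expected, abs=1e-9)

    @given(x=st.floats(-10, 10), s=st.floats(-10, 10))
    def test_indicator_off_ignores_shift(self, x, s):
        assert modulated_k(x, s, 0) == pytest.approx(math.exp(x), rel=1e-12)
        assert modulated_beta(x, s, 0) == x

    def test_modulated_beta_literal_addition(self):
        assert modulated_beta(0.51, 0.02, 1) == pytest.approx(0.53)
        # negative effective beta passes through (with a warning), untruncated
        assert modulated_beta(0.1, -0.3, 1) == pytest.approx(-0.2)

    def test_k_exponent_clipping(self):
        assert np.isfinite(modulated_k(500.0, 500.0, 1))
        assert modulated_k(-500.0, 0.0, 0) > 0


class TestSubjectiveValue:
    def test_hyperbolic_oracle(self):
        # 38 / (1 + 0.0149956 * 14) = 31.40834...
        sv = subjective_value_ll(38.0, 14.0, 0.0149956)
        assert sv == pytest.approx(38.0 / (1 + 0.0149956 * 14), abs=1e-9)
        assert sv == pytest.approx(31.41, abs=0.005)

    @given(a=st.floats(0.1, 1000), k=st.floats(0, 10))
    def test_zero_delay_returns_amount(self, a, k):
        assert subjective_value_ll(a, 0.0, k) == a

    @given(a=st.floats(0.1, 1000), d=st.floats(0, 365))
    def test_zero_rate_returns_amount(self, a, d):
        assert subjective_value_ll(a, d, 0.0) == a

    @given(a=st.floats(1, 100), k=st.floats(0.001, 1),
           d1=st.floats(0, 100), d2=st.floats(0.1, 100))
    def test_monotone_decreasing_in_delay(self, a, k, d1, d2):
        assert (subjective_value_ll(a, d1 + d2, k)
                < subjective_value_ll(a, d1, k))

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            subjective_value_ll(38.0, 14.0, -0.1)


class TestOffset:
    def test_offset_oracle(self):
        assert apply_offset(31.41, 0.8, 0.0, 0) == pytest.approx(25.128)
        assert apply_offset(31.41, 0.8, -0.1, 1) == pytest.approx(21.987)

    @given(sv=st.floats(0.1, 100), i=st.sampled_from([0, 1]))
    def test_unit_offset_is_identity(self, sv, i):
        assert apply_offset(sv, 1.0, 0.0, i) == sv

    @pytest.mark.parametrize("omega,shift,i", [
        (0.5, 0.6, 1),   # effective 1.1 > 1
        (0.5, -0.5, 1),  # effective 0
        (1.2, 0.0, 0),
    ])
    def test_out_of_range_effective_offset_rejected(self, omega, shift, i):
        with pytest.raises(ValueError, match="outside"):
            apply_offset(10.0, omega, shift, i)


class TestChoiceProbability:
    def test_logistic_oracle(self):
        # sigma(0.51 * (31.41 - 20)) = sigma(5.8191)
        p = choice_probability(31.41, 20.0, 0.51)
        assert p == pytest.approx(1 / (1 + math.exp(-0.51 * 11.41)), abs=1e-9)
        assert p == pytest.approx(0.99703, abs=2e-5)

    @given(x=st.floats(-50, 50), beta=st.floats(-5, 5))
    def test_equal_values_give_half(self, x, beta):
        assert choice_probability(x, x, beta) == pytest.approx(0.5)

    @given(a=st.floats(-100, 100), b=st.floats(-100, 100),
           beta=st.floats(-10, 10))
    @settings(max_examples=200)
    def test_probabilities_sum_to_one(self, a, b, beta):
        p = choice_probability(a, b, beta)
        q = choice_probability(b, a, beta)
        assert 0.0 < p < 1.0
        assert p + q == pytest.approx(1.0, abs=1e-12)


class TestTrialLoglik:
    PARAMS = SubjectParams(log_k_neut=-4.2, beta_neut=0.51, omega_neut=1.0)

    def test_zero_beta_is_log_half(self):
        p = SubjectParams(log_k_neut=-4.2, beta_neut=0.0)
        for choice in ("SS", "LL"):
            assert trial_loglik(TRIAL_38_14, choice, p, BASE) == pytest.approx(
                math.log(0.5), abs=1e-12)

    def test_oracle_ll_and_ss(self):
        # k = exp(-4.2): SV_LL = 38/(1 + k*14) = 31.40858; x = 0.51*11.40858
        k = math.exp(-4.2)
        p_ll = 1 / (1 + math.exp(-0.51 * (38 / (1 + 14 * k) - 20)))
        got_ll = trial_loglik(TRIAL_38_14, "LL", self.PARAMS, OFFSET)
        got_ss = trial_loglik(TRIAL_38_14, "SS", self.PARAMS, OFFSET)
        assert got_ll == pytest.approx(math.log(p_ll), abs=1e-9)
        assert got_ss == pytest.approx(math.log(1 - p_ll), abs=1e-9)
        assert got_ll == pytest.approx(-0.002975, abs=5e-6)
        assert got_ss == pytest.approx(-5.8206, abs=2e-3)

    def test_offset_with_unit_omega_equals_base_bitwise(self, design_set1):
        params = SubjectParams(log_k_neut=-3.0, s_ero_k=0.2, beta_neut=0.4,
                               s_ero_beta=-0.05, omega_neut=1.0,
                               s_ero_omega=0.0)
        for t in design_set1[::7]:
            for choice in ("SS", "LL"):
                assert (trial_loglik(t, choice, params, OFFSET)
                        == trial_loglik(t, choice, params, BASE))

    @given(logk=st.floats(-8, 0), beta=st.floats(-2, 5),
           omega=st.floats(0.05, 1), choice=st.sampled_from(["SS", "LL"]))
    @settings(max_examples=150)
    def test_loglik_nonpositive_and_finite(self, logk, beta, omega, choice):
        p = SubjectParams(log_k_neut=logk, beta_neut=beta, omega_neut=omega)
        ll = trial_loglik(TRIAL_38_14, choice, p, OFFSET)
        assert ll <= 0.0
        assert np.isfinite(ll)

    def test_invalid_choice_rejected(self):
        with pytest.raises(ValueError):
            trial_loglik(TRIAL_38_14, "INVALID", self.PARAMS, BASE)


class TestDatasetLoglik:
    def test_length_and_additivity(self, design_set1, typical_params):
        choices = ["LL" if i % 3 else "SS" for i in range(128)]
        ds = ChoiceDataset("s0", design_set1, choices, "neutral")
        pw = dataset_pointwise_loglik(ds, typical_params, OFFSET)
        assert pw.shape == (128,)
        total = sum(trial_loglik(t, c, typical_params, OFFSET)
                    for t, c in zip(design_set1, choices))
        assert pw.sum() == pytest.approx(total, rel=1e-12)

    def test_invalid_trials_excluded(self, design_set1, typical_params):
        choices = ["INVALID"] * 10 + ["LL"] * 118
        ds = ChoiceDataset("s0", design_set1, choices, "neutral")
        assert dataset_pointwise_loglik(ds, typical_params, OFFSET).shape == (118,)

    def test_near_deterministic_correct_predictions(self, design_set1):
        p = SubjectParams(log_k_neut=-30.0, beta_neut=50.0)
        ds = ChoiceDataset("s0", design_set1, ["LL"] * 128, "neutral")
        pw = dataset_pointwise_loglik(ds, p, BASE)
        assert np.all(pw > -1e-3)

    def test_empty_valid_set_is_error(self, design_set1, typical_params):
        ds = ChoiceDataset("s0", design_set1, ["INVALID"] * 128, "neutral")
        with pytest.raises(ValueError, match="no valid trials"):
            dataset_pointwise_loglik(ds, typical_params, OFFSET)


class TestModelAgnosticTd:
    @pytest.mark.parametrize("ss,ll,expected", [
        (40, 0, 1.0), (0, 40, 0.0), (10, 30, 0.25)])
    def test_proportions(self, design_set1, ss, ll, expected):
        choices = ["SS"] * ss + ["LL"] * ll + ["INVALID"] * (128 - ss - ll)
        summary = model_agnostic_td(
            ChoiceDataset("s0", design_set1, choices, "neutral"))
        assert summary.td_model_agnostic == pytest.approx(expected)
        assert summary.ss_count == ss and summary.ll_count == ll

    def test_all_invalid_is_error(self, design_set1):
        ds = ChoiceDataset("s0", design_set1, ["INVALID"] * 128, "neutral")
        with pytest.raises(ValueError):
            model_agnostic_td(ds)
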