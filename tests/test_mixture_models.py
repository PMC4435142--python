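import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from odorvector import (
    ComponentExposure,
    ConfigurationError,
    DomainError,
    InteractionMatrix,
    MixtureSample,
    Odorant,
    PsychophysicalLaw,
    ValidationError,
    cos_alpha_from_pair,
    modified_vector_model,
    predict_sample,
    strongest_component_model,
    summation_model,
    vector_model,
)

# ---------------------------------------------------------------------------
# literal transcriptions of the published binary/ternary/quaternary formulas,
# kept independent of the generalized implementation they check
# ---------------------------------------------------------------------------


def mvm_binary_literal(a, b):
    return 1.07 * math.sqrt(a**2 + b**2 - 0.258 * a * b)


def mvm_ternary_literal(a, b, c):
    return 1.07 * math.sqrt(
        a**2 + b**2 + c**2 - 0.258 * a * b - 0.258 * a * c - 0.258 * b * c
    )


def mvm_quaternary_literal(a, b, c, d):
    return 1.07 * math.sqrt(
        a**2 + b**2 + c**2 + d**2
        - 0.258 * a * b - 0.258 * a * c - 0.258 * a * d
        - 0.258 * b * c - 0.258 * b * d - 0.258 * c * d
    )


LITERAL = {2: mvm_binary_literal, 3: mvm_ternary_literal, 4: mvm_quaternary_literal}


@pytest.mark.parametrize("n", [2, 3, 4])
def test_generalized_form_matches_literal_expansions(n):
    """The shared-coefficient quadratic form equals the explicit n=2,3,4
    expansions on random supra-threshold inputs."""
    rng = np.random.default_rng(20150309 + n)
    for _ in range(100):
        xs = rng.uniform(0.1, 5.0, n)
        expected = LITERAL[n](*xs)
        got = modified_vector_model(list(xs), k=1.07, cos_alpha=-0.129)
        assert abs(got - expected) < 1e-12


class TestVectorModel:
    def test_collinear_vectors_add(self):
        assert vector_model([3, 3], 1.0) == pytest.approx(6.0)

    def test_opposed_vectors_cancel(self):
        assert vector_model([3, 3], -1.0) == pytest.approx(0.0, abs=1e-9)

    def test_counteracting_pair(self):
        # sqrt(9 + 9 - 0.258*9) by hand
        assert vector_model([3, 3], -0.129) == pytest.approx(
            math.sqrt(18 - 0.258 * 9), abs=1e-12
        )

    def test_per_pair_matrix(self):
        m = InteractionMatrix({("a", "b"): 1.0, ("a", "c"): 0.0, ("b", "c"): 0.0})
        # a and b collinear, c orthogonal to both
        value = vector_model([3, 3, 4], m, labels=["a", "b", "c"])
        assert value == pytest.approx(math.sqrt(36 + 16))

    def test_missing_pair_is_configuration_error(self):
        m = InteractionMatrix({("a", "b"): 0.5})
        with pytest.raises(ConfigurationError, match="pair"):
            vector_model([1, 1, 1], m, labels=["a", "b", "c"])

    def test_negative_oi_rejected(self):
        with pytest.raises(DomainError):
            vector_model([-1, 2], 0.0)

    def test_matrix_rejects_out_of_range_cosine(self):
        with pytest.raises(ConfigurationError):
            InteractionMatrix({("a", "b"): 1.5})


class TestModifiedVectorModel:
    @pytest.mark.parametrize("xs,printed", [
        ([3.36, 3.54], 4.9),        # binary, toluene + ethylbenzene
        ([2.34, 3.54, 2.80], 4.7),  # ternary, toluene + ethylbenzene + m-xylene
    ])
    def test_reference_rows_at_one_decimal(self, xs, printed):
        assert round(modified_vector_model(xs), 1) == printed

    def test_quaternary_direct_evaluation(self):
        # direct evaluation of the four-component formula; the originally
        # tabulated 5.5 carries an intermediate rounding (docs/methods.md)
        assert modified_vector_model([4.24, 2.20, 3.83, 2.15]) == pytest.approx(
            5.63, abs=0.005
        )

    def test_single_component_reduces_to_individual_law(self):
        for x in (0.5, 1.0, 3.83):
            assert modified_vector_model([x]) == pytest.approx(1.07 * x, abs=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(DomainError):
            modified_vector_model([])

    def test_cos_alpha_outside_unit_interval_rejected(self):
        with pytest.raises(ConfigurationError):
            modified_vector_model([1, 2], cos_alpha=-1.5)

    def test_subthreshold_components_dropped_by_default(self):
        full = modified_vector_model([3.0, 2.0])
        assert modified_vector_model([3.0, 2.0, -0.5]) == pytest.approx(full)

    def test_subthreshold_error_policy(self):
        with pytest.raises(DomainError, match="sub-threshold"):
            modified_vector_model([3.0, -0.5], subthreshold="error")

    def test_subthreshold_keep_policy_uses_negative_values(self):
        kept = modified_vector_model([3.0, -0.5], subthreshold="keep")
        dropped = modified_vector_model([3.0, -0.5], subthreshold="drop")
        assert kept != pytest.approx(dropped)

    def test_all_subthreshold_gives_zero(self):
        assert modified_vector_model([-1.0, -0.2]) == 0.0

    def test_radicand_positive_up_to_eight_equal_components(self):
        """n + 2*cosa*C(n,2) > 0 iff n <= 8 at cos(alpha) = -0.129."""
        for n in range(2, 9):
            assert modified_vector_model([2.0] * n) > 0.0
        with pytest.warns(UserWarning, match="clamp"):
            assert modified_vector_model([2.0] * 9) == 0.0

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(min_value=0.1, max_value=5.0), min_size=2, max_size=6),
           st.randoms(use_true_random=False))
    def test_permutation_invariance(self, xs, rnd):
        shuffled = list(xs)
        rnd.shuffle(shuffled)
        assert modified_vector_model(shuffled) == pytest.approx(
            modified_vector_model(xs), rel=1e-12
        )

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(min_value=0.1, max_value=5.0), min_size=2, max_size=6))
    def test_counteraction_keeps_mixture_below_summation(self, xs):
        """With cos(alpha) < 1 the mixture is strictly less intense than the
        additivity baseline."""
        assert modified_vector_model(xs) < summation_model(xs)

    @pytest.mark.parametrize("beta", [0.1 * i for i in range(1, 11)])
    def test_equal_binary_round_trip_with_beta(self, beta):
        """For equal components, cos(alpha) = 2 beta^2 - 1 makes the mixture
        exactly beta times the intensity sum."""
        k, x = 1.07, 2.5
        cos_alpha = 2 * beta**2 - 1
        assert modified_vector_model([x, x], k, cos_alpha) == pytest.approx(
            beta * 2 * k * x, abs=1e-9
        )


class TestBaselines:
    def test_scm_worked_example(self):
        # strongest of {3.54, 2.20, 3.83} is 3.83; 1.07 * 3.83 = 4.1
        assert round(strongest_component_model([3.54, 2.20, 3.83]), 1) == 4.1

    def test_scm_reference_binary_row(self):
        assert round(strongest_component_model([3.36, 3.54]), 1) == 3.8

    def test_scm_single_component(self):
        assert strongest_component_model([2.0]) == pytest.approx(2.14)

    def test_scm_clamps_negative_max(self):
        assert strongest_component_model([-1.0, -2.0], subthreshold="keep") == 0.0

    def test_summation_examples(self):
        assert summation_model([3, 3], k=1.0) == pytest.approx(6.0)
        assert summation_model([0.0]) == 0.0
        assert summation_model([3.36, 3.54]) == pytest.approx(1.07 * 6.90, abs=1e-9)

    def test_summation_ignores_subthreshold_contributions(self):
        assert summation_model([3.0, -1.0], k=1.0) == pytest.approx(3.0)

    def test_empty_lists_rejected(self):
        with pytest.raises(DomainError):
            strongest_component_model([])
        with pytest.raises(DomainError):
            summation_model([])

    def test_single_component_reduction_agrees_across_models(self):
        for x in (0.3, 1.7, 4.2):
            mvm = modified_vector_model([x])
            assert strongest_component_model([x]) == pytest.approx(mvm, abs=1e-12)
            assert summation_model([x]) == pytest.approx(mvm, abs=1e-12)


class TestCosAlphaFromPair:
    def test_inverts_vector_model(self):
        for c in (-0.8, -0.129, 0.0, 0.5, 1.0):
            oi_ab = vector_model([2.0, 3.0], c)
            assert cos_alpha_from_pair(oi_ab, 2.0, 3.0) == pytest.approx(c, abs=1e-12)

    def test_requires_positive_component_intensities(self):
        with pytest.raises(DomainError):
            cos_alpha_from_pair(3.0, 0.0, 2.0)


TOLUENE = Odorant("Toluene", "T", "108-88-3", 1.43)
ETHYLBENZENE = Odorant("Ethylbenzene", "E", "100-41-4", 0.45)


def _sample(components, sample_id="X", measured=None):
    return MixtureSample(sample_id=sample_id, components=tuple(components),
                         measured_oi=measured)


class TestPredictSample:
    def test_reference_binary_row_under_mvm(self):
        sample = _sample([
            ComponentExposure(odorant=TOLUENE, ln_oav=3.36),
            ComponentExposure(odorant=ETHYLBENZENE, ln_oav=3.54),
        ])
        result = predict_sample(sample, "mvm")
        assert round(result.predicted_oi, 1) == 4.9
        assert not result.clamped

    def test_component_at_threshold_has_zero_intensity(self):
        sample = _sample([ComponentExposure(odorant=TOLUENE, concentration=1.43)])
        assert predict_sample(sample, "mvm").predicted_oi == pytest.approx(0.0)

    def test_matches_brute_force_binary_expansion(self):
        sample = _sample([
            ComponentExposure(odorant=TOLUENE, ln_oav=1.0),
            ComponentExposure(odorant=ETHYLBENZENE, ln_oav=1.0),
        ])
        result = predict_sample(sample, "mvm")
        assert abs(result.predicted_oi - mvm_binary_literal(1.0, 1.0)) < 1e-12

    def test_concentration_and_lnoav_encodings_agree(self):
        x_t, x_e = 2.1, 1.3
        by_lnoav = _sample([
            ComponentExposure(odorant=TOLUENE, ln_oav=x_t),
            ComponentExposure(odorant=ETHYLBENZENE, ln_oav=x_e),
        ])
        by_conc = _sample([
            ComponentExposure(odorant=TOLUENE, concentration=1.43 * math.exp(x_t)),
            ComponentExposure(odorant=ETHYLBENZENE, concentration=0.45 * math.exp(x_e)),
        ])
        for model in ("mvm", "vm", "scm", "sum"):
            a = predict_sample(by_lnoav, model).predicted_oi
            b = predict_sample(by_conc, model).predicted_oi
            assert a == pytest.approx(b, rel=1e-9)

    def test_zero_concentration_component_dropped_with_warning(self):
        sample = _sample([
            ComponentExposure(odorant=TOLUENE, ln_oav=2.0),
            ComponentExposure(odorant=ETHYLBENZENE, concentration=0.0),
        ])
        result = predict_sample(sample, "mvm")
        assert result.predicted_oi == pytest.approx(1.07 * 2.0)
        assert any("zero concentration" in w for w in result.warnings)

    def test_all_components_dropped_yields_zero_with_warning(self):
        sample = _sample([ComponentExposure(odorant=TOLUENE, concentration=0.0)])
        result = predict_sample(sample, "scm")
        assert result.predicted_oi == 0.0
        assert result.warnings

    def test_clamped_flag_propagates(self):
        comps = [
            ComponentExposure(odorant=Odorant(f"O{i}", chr(65 + i), "", 1.0),
                              ln_oav=2.0)
            for i in range(9)
        ]
        with pytest.warns(UserWarning):
            result = predict_sample(_sample(comps), "mvm")
        assert result.predicted_oi == 0.0
        assert result.clamped

    def test_unknown_model_rejected(self):
        sample = _sample([ComponentExposure(odorant=TOLUENE, ln_oav=2.0)])
        with pytest.raises(ConfigurationError):
            predict_sample(sample, "umodel")

    def test_vm_with_uniform_matrix_matches_mvm(self):
        sample = _sample([
            ComponentExposure(odorant=TOLUENE, ln_oav=3.36),
            ComponentExposure(odorant=ETHYLBENZENE, ln_oav=3.54),
        ])
        m = InteractionMatrix.uniform(["T", "E"], -0.129)
        vm = predict_sample(sample, "vm", interactions=m).predicted_oi
        mvm = predict_sample(sample, "mvm").predicted_oi
        assert vm == pytest.approx(mvm, rel=1e-12)


def test_duplicate_component_odorants_rejected():
    with pytest.raises(ValidationError, match="duplicate"):
        _sample([
            ComponentExposure(odorant=TOLUENE, ln_oav=1.0),
            ComponentExposure(odorant=TOLUENE, ln_oav=2.0),
        ])
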