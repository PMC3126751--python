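import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from moietydeconv import (
    ConfigurationError,
    MoietyStateSpace,
    ParameterSet,
    SubunitStateSet,
    ValidationError,
    enumerate_isotopomers,
    free_parameter_count,
    mass_support,
    predict_profile,
)

from conftest import brute_force_profile, random_params


def two_state(name, prefix, carbons, hi):
    return SubunitStateSet(
        name=name,
        carbon_count=carbons,
        allowed_labels=(0, hi),
        parameter_names=(f"{prefix}0", f"{prefix}{hi}"),
    )


# ---------------------------------------------------------------- structure


class TestSubunitStateSet:
    def test_labels_must_be_sorted_distinct(self):
        with pytest.raises(ConfigurationError):
            SubunitStateSet("x", 4, (2, 0), ("a", "b"))
        with pytest.raises(ConfigurationError):
            SubunitStateSet("x", 4, (0, 0), ("a", "b"))

    def test_labels_within_carbon_count(self):
        with pytest.raises(ConfigurationError):
            SubunitStateSet("x", 2, (0, 3), ("a", "b"))
        with pytest.raises(ConfigurationError):
            SubunitStateSet("x", 2, (-1, 2), ("a", "b"))

    def test_one_name_per_state(self):
        with pytest.raises(ConfigurationError):
            SubunitStateSet("x", 4, (0, 2), ("a",))

    def test_carbon_count_positive(self):
        with pytest.raises(ConfigurationError):
            SubunitStateSet("x", 0, (0,), ("a",))


class TestStateSpace:
    def test_default_structure(self, space):
        assert [s.carbon_count for s in space.subunits] == [6, 5, 2, 4]
        assert [s.allowed_labels for s in space.subunits] == [
            (0, 6), (0, 5), (0, 2), (0, 1, 2, 3)]
        assert space.metabolite_carbons == 17

    def test_empty_space_rejected(self):
        with pytest.raises(ConfigurationError):
            MoietyStateSpace(subunits=())

    def test_duplicate_parameter_names_rejected(self):
        a = two_state("a", "p", 2, 2)
        b = two_state("b", "p", 2, 2)
        with pytest.raises(ConfigurationError):
            MoietyStateSpace(subunits=(a, b))

    def test_json_round_trip(self, space, tmp_path):
        import json
        p = tmp_path / "model.json"
        p.write_text(json.dumps(space.to_dict()))
        assert MoietyStateSpace.from_json(p) == space


# ------------------------------------------------------------- enumeration


class TestEnumeration:
    def test_default_space_has_32_isotopomers(self, space):
        assert len(enumerate_isotopomers(space)) == 32

    def test_degenerate_single_state(self):
        sp = MoietyStateSpace((SubunitStateSet("x", 3, (0,), ("x0",)),))
        isos = enumerate_isotopomers(sp)
        assert len(isos) == 1
        assert isos[0].mass_shift == 0

    def test_two_subunit_enumeration(self):
        # hand enumeration: {0,1} x {0,2} -> shifts 0,1,2,3
        a = SubunitStateSet("a", 1, (0, 1), ("a0", "a1"))
        b = SubunitStateSet("b", 2, (0, 2), ("b0", "b2"))
        isos = enumerate_isotopomers(MoietyStateSpace((a, b)))
        assert len(isos) == 4
        assert sorted(i.mass_shift for i in isos) == [0, 1, 2, 3]

    def test_isotopomer_carries_parameter_product(self, space):
        isos = enumerate_isotopomers(space)
        names = {iso.parameter_names for iso in isos}
        assert ("g0", "r0", "a0", "u0") in names
        assert ("g6", "r5", "a2", "u3") in names
        assert all(len(iso.parameter_names) == 4 for iso in isos)


class TestMassSupport:
    def test_default_support_is_0_to_16(self, space):
        assert mass_support(space) == tuple(range(17))

    def test_all_unlabeled_support(self):
        sp = MoietyStateSpace((SubunitStateSet("x", 3, (0,), ("x0",)),))
        assert mass_support(sp) == (0,)

    def test_glucose_ribose_support(self):
        sp = MoietyStateSpace((two_state("g", "g", 6, 6), two_state("r", "r", 5, 5)))
        assert mass_support(sp) == (0, 5, 6, 11)


class TestFreeParameterCount:
    def test_default_is_6(self, space):
        assert free_parameter_count(space) == 6

    def test_single_state_subunit_contributes_zero(self):
        sp = MoietyStateSpace((SubunitStateSet("x", 3, (0,), ("x0",)),))
        assert free_parameter_count(sp) == 0

    def test_expanded_acetyl_gives_7(self, space):
        subs = list(space.subunits)
        subs[2] = SubunitStateSet("acetyl", 2, (0, 1, 2), ("a0", "a1", "a2"))
        assert free_parameter_count(MoietyStateSpace(tuple(subs))) == 7


# ------------------------------------------------------------ forward model


class TestPredictProfile:
    def test_all_unlabeled_is_delta_at_m0(self, space):
        params = ParameterSet.from_free(
            space, {"g0": 1, "r0": 1, "a0": 1, "u0": 1, "u1": 0, "u2": 0})
        prof = predict_profile(space, params)
        expected = np.zeros(17)
        expected[0] = 1.0
        np.testing.assert_allclose(prof.fractions, expected, atol=1e-15)

    def test_hand_convolution_two_two_state_subunits(self, space):
        # g0=r0=0.5, a0=u0=1 -> quarters at masses 0, 5, 6, 11
        params = ParameterSet.from_free(
            space, {"g0": 0.5, "r0": 0.5, "a0": 1, "u0": 1, "u1": 0, "u2": 0})
        prof = predict_profile(space, params).fractions
        expected = np.zeros(17)
        expected[[0, 5, 6, 11]] = 0.25
        np.testing.assert_allclose(prof, expected, atol=1e-15)

    def test_printed_48h_set_matches_brute_force_oracle(self, space, printed_48h_params):
        prof = predict_profile(space, printed_48h_params).fractions
        oracle = brute_force_profile(space, printed_48h_params)
        np.testing.assert_allclose(prof, oracle, atol=1e-12)
        assert abs(prof.sum() - 1.0) < 1e-12

    def test_closure_violation_rejected(self, space):
        bad = ParameterSet({
            "g0": 0.5, "g6": 0.4, "r0": 0, "r5": 1, "a0": 0, "a2": 1,
            "u0": 1, "u1": 0, "u2": 0, "u3": 0})
        with pytest.raises(ValidationError):
            predict_profile(space, bad)

    def test_closure_within_tolerance_renormalized(self, space):
        eps = 1e-10
        p = ParameterSet({
            "g0": 0.5 + eps, "g6": 0.5, "r0": 0, "r5": 1, "a0": 0, "a2": 1,
            "u0": 1, "u1": 0, "u2": 0, "u3": 0})
        prof = predict_profile(space, p)
        assert abs(prof.fractions.sum() - 1.0) < 1e-12


# ----------------------------------------------------------- property tests


@st.composite
def small_spaces(draw):
    n_subunits = draw(st.integers(1, 5))
    subunits = []
    for i in range(n_subunits):
        n_states = draw(st.integers(1, 4))
        carbons = draw(st.integers(max(n_states - 1, 1), 6))
        labels = tuple(sorted(draw(st.sets(
            st.integers(0, carbons), min_size=n_states, max_size=n_states))))
        subunits.append(SubunitStateSet(
            name=f"s{i}", carbon_count=carbons, allowed_labels=labels,
            parameter_names=tuple(f"s{i}_{l}" for l in labels)))
    return MoietyStateSpace(tuple(subunits))


@settings(max_examples=50, deadline=None)
@given(sp=small_spaces(), seed=st.integers(0, 2**32 - 1))
def test_oracle_equivalence_random_spaces(sp, seed):
    rng = np.random.default_rng(seed)
    params = random_params(sp, rng)
    prof = predict_profile(sp, params).fractions
    np.testing.assert_allclose(prof, brute_force_profile(sp, params), atol=1e-12)


@settings(max_examples=50, deadline=None)
@given(seed=st.integers(0, 2**32 - 1))
def test_profile_sums_to_one(space, seed):
    rng = np.random.default_rng(seed)
    params = random_params(space, rng)
    assert abs(predict_profile(space, params).fractions.sum() - 1.0) < 1e-12


@settings(max_examples=30, deadline=None)
@given(sp=small_spaces(), seed=st.integers(0, 2**32 - 1), perm_seed=st.integers(0, 999))
def test_subunit_order_invariance(sp, seed, perm_seed):
    rng = np.random.default_rng(seed)
    params = random_params(sp, rng)
    order = np.random.default_rng(perm_seed).permutation(len(sp.subunits))
    shuffled = MoietyStateSpace(tuple(sp.subunits[i] for i in order))
    np.testing.assert_allclose(
        predict_profile(sp, params).fractions,
        predict_profile(shuffled, params).fractions,
        atol=1e-12,
    )


@settings(max_examples=30, deadline=None)
@given(seed=st.integers(0, 2**32 - 1), delta=st.floats(0.01, 0.3))
def test_mean_mass_shift_increases_with_g6(space, seed, delta):
    rng = np.random.default_rng(seed)
    params = random_params(space, rng)
    f = dict(params.fractions)
    shift = min(delta, f["g0"])
    if shift < 1e-6:
        return
    bumped = dict(f)
    bumped["g6"] = f["g6"] + shift
    bumped["g0"] = f["g0"] - shift
    base = predict_profile(space, ParameterSet(f)).mean_mass_shift
    more = predict_profile(space, ParameterSet(bumped)).mean_mass_shift
    assert more > base
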