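"""Rate-law evaluation, model validation and the curated model's census."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stingnet import (
    Compartment,
    ModelDefinitionError,
    RateLaw,
    Reaction,
    ReactionModel,
    Species,
    evaluate_rate,
    hill,
    mass_action,
    michaelis_menten,
    validate_model,
)
from stingnet.core import rate_parameter_gradient, rate_state_gradient


def rx(law, reactants=(("A", 1),), products=(("B", 1),), modifiers=()):
    return Reaction(
        "r", "r", list(reactants), list(products), law, modifiers=list(modifiers)
    )


class TestEvaluateRate:
    def test_mass_action_product_of_reactants(self):
        r = rx(mass_action(2.0), reactants=[("A", 1), ("B", 1)], products=[("C", 1)])
        assert evaluate_rate(r, {"A": 3.0, "B": 4.0}) == pytest.approx(24.0)

    def test_mass_action_stoichiometric_powers(self):
        r = rx(mass_action(1.0), reactants=[("A", 2)])
        assert evaluate_rate(r, {"A": 5.0}) == pytest.approx(25.0)

    def test_michaelis_menten_half_saturation(self):
        r = rx(michaelis_menten(10.0, 7.0))
        assert evaluate_rate(r, {"A": 7.0}) == pytest.approx(5.0)

    def test_hill_with_unit_exponent_reduces_to_michaelis_menten(self):
        mm = rx(michaelis_menten(8.0, 123.0))
        h = rx(hill(8.0, 123.0, 1.0))
        for s in np.logspace(-2, 6, 40):
            assert evaluate_rate(h, {"A": s}) == pytest.approx(
                evaluate_rate(mm, {"A": s}), rel=1e-12
            )

    def test_hill_driven_by_modifier_when_no_reactant(self):
        r = rx(hill(10.0, 100.0, 2.0), reactants=[], modifiers=["TF"])
        v = evaluate_rate(r, {"TF": 100.0, "B": 0.0})
        assert v == pytest.approx(5.0)

    def test_ambiguous_driver_raises(self):
        r = rx(michaelis_menten(1.0, 1.0), reactants=[("A", 1), ("B", 1)])
        with pytest.raises(ModelDefinitionError):
            evaluate_rate(r, {"A": 1.0, "B": 1.0})

    def test_unknown_rate_law_kind_raises(self):
        r = rx(mass_action(1.0))
        r.rate_law.kind = "exotic"  # bypass enum coercion
        with pytest.raises(ModelDefinitionError):
            evaluate_rate(r, {"A": 1.0})

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        s=st.floats(min_value=0.0, max_value=1e8),
        vmax=st.floats(min_value=1e-6, max_value=1e6),
        k=st.floats(min_value=1e-6, max_value=1e6),
        n=st.floats(min_value=0.5, max_value=4.0),
    )
    def test_rates_nonnegative_and_finite(self, s, vmax, k, n):
        state = {"A": s}
        for law in (mass_action(k), michaelis_menten(vmax, k), hill(vmax, k, n)):
            v = evaluate_rate(rx(law), state)
            assert math.isfinite(v) and v >= 0.0


class TestGradients:
    def test_mass_action_gradient_at_zero_state(self):
        r = rx(mass_action(3.0), reactants=[("A", 1), ("B", 1)])
        g = rate_state_gradient(r, {"A": 0.0, "B": 4.0})
        assert g["A"] == pytest.approx(12.0)
        assert g["B"] == pytest.approx(0.0)

    def test_parameter_gradients_match_finite_differences(self):
        r = rx(hill(5.0, 200.0, 2.0))
        state = {"A": 321.0}
        g = rate_parameter_gradient(r, state)
        for pname, dv in g.items():
            h = 1e-6 * r.rate_law.parameters[pname]
            up, dn = dict(r.rate_law.parameters), dict(r.rate_law.parameters)
            up[pname] += h
            dn[pname] -= h
            v_up = evaluate_rate(rx(RateLaw("hill", up)), state)
            v_dn = evaluate_rate(rx(RateLaw("hill", dn)), state)
            assert dv == pytest.approx((v_up - v_dn) / (2 * h), rel=1e-5)


class TestValidateModel:
    def test_curated_model_has_no_errors(self, nsclc_model):
        assert [f for f in validate_model(nsclc_model) if f.severity == "error"] == []

    def test_out_of_band_initial_amount_warns(self, decay_model):
        decay_model.species[0].initial_amount = 100.0  # below 10^3
        findings = validate_model(decay_model)
        warnings = [f for f in findings if f.severity == "warning"]
        assert any("band" in w.message for w in warnings)

    def test_missing_species_reference_is_an_error(self, decay_model):
        decay_model.reactions[0].products.append(("ghost", 1))
        errors = [f for f in validate_model(decay_model) if f.severity == "error"]
        assert len(errors) == 1 and "ghost" in errors[0].message

    def test_nonpositive_parameter_is_an_error(self, decay_model):
        decay_model.reactions[0].rate_law.parameters["k"] = 0.0
        errors = [f for f in validate_model(decay_model) if f.severity == "error"]
        assert errors


class TestCuratedCensus:
    def test_compartment_species_reaction_counts(self, nsclc_model):
        assert nsclc_model.n_compartments == 6
        assert nsclc_model.n_species == 72
        assert nsclc_model.n_reactions == 83

    def test_published_reaction_names_present(self, nsclc_model):
        names = {r.name for r in nsclc_model.reactions}
        assert "LC3/ATG12/5/16L -> Autophagosome" in names
        assert "Phagophore -> Autophagosome" in names
        assert "recruited cGAS -> dsDNAcGAScomplex" in names

    def test_dynamic_initial_amounts_in_band(self, nsclc_model):
        for s in nsclc_model.species:
            if not s.is_boundary:
                assert 1e3 <= s.initial_amount <= 1e6

    def test_parameter_roundtrip(self, nsclc_model):
        pid = nsclc_model.parameter_ids()[0]
        old = nsclc_model.get_parameter(pid)
        m = nsclc_model.copy()
        m.set_parameter(pid, old * 2)
        assert m.get_parameter(pid) == pytest.approx(old * 2)
        assert nsclc_model.get_parameter(pid) == pytest.approx(old)
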