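"""Reaction-scheme construction, mass-action integration and eigenrate oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pnaokin import (KineticScheme, Reaction, SchemeError, build_pnao_scheme,
                     eigenrates, integrate, linear_solution)

UM = 1e-6


def two_step_chain(k1, k2):
    return KineticScheme(
        species=("A", "B", "C"),
        reactions=(Reaction(("A",), ("B",), k1), Reaction(("B",), ("C",), k2)),
        enzyme_states=("A", "B", "C"))


class TestBuild:
    def test_cycn_scheme_has_two_bimolecular_steps_three_states(self, params):
        s = build_pnao_scheme(params, "oxidation_cycn")
        assert len(s.reactions) == 2
        assert all(r.order == 2 for r in s.reactions)
        assert len(s.enzyme_states) == 3

    def test_unknown_experiment_rejected(self, params):
        with pytest.raises(SchemeError, match="unknown experiment"):
            build_pnao_scheme(params, "sideways")

    def test_flavin_conservation_enforced_on_construction(self):
        # a reaction destroying an enzyme state (no enzyme-state product)
        with pytest.raises(SchemeError, match="enzyme state"):
            KineticScheme(species=("A", "B"), reactions=(
                Reaction(("A",), ("B",), 1.0),), enzyme_states=("A",))
        # a reaction consuming two enzyme states at once
        with pytest.raises(SchemeError, match="enzyme state"):
            KineticScheme(species=("A", "B", "C"), reactions=(
                Reaction(("A", "B"), ("C",), 1.0),),
                enzyme_states=("A", "B", "C"))


class TestEigenrates:
    def test_reductive_rates_follow_saturation_law(self, params):
        # k_red*[S]/(Kd+[S]) at 500 uM plus the release rate
        s = build_pnao_scheme(params, "reductive")
        rates = eigenrates(s, {"S": 500 * UM})
        expected = 74.0 * 500 / (64 + 500)
        assert rates == pytest.approx([expected, 6.3], rel=1e-9)

    def test_zero_substrate_leaves_only_release(self, params):
        s = build_pnao_scheme(params, "reductive")
        assert eigenrates(s, {"S": 0.0}) == pytest.approx([6.3])

    def test_cycn_rates_are_pseudo_first_order_products(self, params):
        s = build_pnao_scheme(params, "oxidation_cycn")
        assert eigenrates(s, {"CycN_ox": 50 * UM}) == pytest.approx(
            [7.0, 1.6], rel=1e-9)

    def test_single_step_scheme_returns_its_rate(self, params):
        s = build_pnao_scheme(params, "oxidation_o2")
        assert eigenrates(s, {"O2": 600 * UM}) == pytest.approx([0.36])

    def test_nonlinear_scheme_rejected(self, params):
        s = build_pnao_scheme(params, "oxidation_cycn")
        free = KineticScheme(s.species, s.reactions, s.enzyme_states,
                             frozenset())
        with pytest.raises(SchemeError, match="nonlinear"):
            eigenrates(free, {"CycN_ox": 50 * UM})


class TestIntegrate:
    def test_all_rates_zero_is_constant(self, params):
        p = params.replace(k_red=0.0, k_rel=0.0)
        s = build_pnao_scheme(p, "reductive")
        grid = np.linspace(0.0, 1.0, 50)[1:]
        ser = integrate(s, {"E_ox": 17.5 * UM, "S": 500 * UM}, grid)
        assert np.allclose(ser["E_ox"], 17.5 * UM, rtol=1e-9)
        assert np.allclose(ser["E_red"], 0.0, atol=1e-15)

    def test_zero_substrate_state_is_constant(self, params):
        s = build_pnao_scheme(params, "reductive")
        grid = np.linspace(0.0, 1.0, 50)[1:]
        ser = integrate(s, {"E_ox": 17.5 * UM, "S": 0.0}, grid)
        assert np.allclose(ser["E_ox"], 17.5 * UM, rtol=1e-9)

    def test_sequential_chain_matches_closed_form(self):
        k1, k2 = 5.0, 1.0
        s = two_step_chain(k1, k2)
        grid = np.linspace(0.0, 6.0, 200)[1:]
        ser = integrate(s, {"A": 1.0}, grid)
        c_exact = 1.0 - (k2 * np.exp(-k1 * grid) - k1 * np.exp(-k2 * grid)) \
            / (k2 - k1)
        assert np.max(np.abs(ser["C"] - c_exact)) <= 1e-6

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(k1=st.floats(0.1, 100.0), k2=st.floats(0.1, 100.0))
    def test_integrator_agrees_with_matrix_exponential(self, k1, k2):
        s = two_step_chain(k1, k2)
        t_end = 5.0 / min(k1, k2)
        grid = np.geomspace(t_end * 1e-4, t_end, 60)
        ser = integrate(s, {"A": 1.0}, grid)
        lin = linear_solution(s, {"A": 1.0}, {}, grid)
        assert np.max(np.abs(ser.concentrations - lin.concentrations)) <= 1e-6

    def test_enzyme_and_cycn_conservation(self, params):
        s = build_pnao_scheme(params, "oxidation_cycn")
        free = KineticScheme(s.species, s.reactions, s.enzyme_states,
                             frozenset())  # CycN not clamped
        grid = np.geomspace(1e-4, 5.0, 200)
        ser = integrate(free, {"E_red": 17.5 * UM, "CycN_ox": 200 * UM}, grid)
        enz = ser["E_red"] + ser["E_sq"] + ser["E_ox"]
        cyc = ser["CycN_ox"] + ser["CycN_red"]
        assert np.max(np.abs(enz / (17.5 * UM) - 1)) <= 1e-6
        assert np.max(np.abs(cyc / (200 * UM) - 1)) <= 1e-6

    def test_cycn_two_electron_stoichiometry(self, params):
        # 17.5 uM of two-electron-reduced enzyme delivers 35 uM of electrons
        s = build_pnao_scheme(params, "oxidation_cycn")
        free = KineticScheme(s.species, s.reactions, s.enzyme_states,
                             frozenset())
        grid = np.geomspace(1e-4, 30.0, 300)
        ser = integrate(free, {"E_red": 17.5 * UM, "CycN_ox": 200 * UM}, grid)
        assert ser["CycN_red"][-1] == pytest.approx(35 * UM, rel=1e-4)
        assert np.all(np.diff(ser["CycN_red"]) >= -1e-12)  # monotone rise

    def test_negative_initial_concentration_rejected(self, params):
        s = build_pnao_scheme(params, "reductive")
        with pytest.raises(ValueError, match="negative"):
            integrate(s, {"E_ox": -1e-6}, np.linspace(0, 1, 10)[1:])

    def test_non_monotone_grid_rejected(self, params):
        s = build_pnao_scheme(params, "reductive")
        with pytest.raises(ValueError, match="increasing"):
            integrate(s, {"E_ox": 1e-6}, np.array([0.0, 0.2, 0.1]))


class TestExplicitBinding:
    def test_slow_eigenrates_approach_rapid_equilibrium_limit(self, params):
        # with diffusion-limited binding the two slowest eigenrates approach
        # the lumped saturating-step rates
        s = build_pnao_scheme(params, "reductive", explicit_binding=True)
        rates = eigenrates(s, {"S": 500 * UM})
        lumped = eigenrates(build_pnao_scheme(params, "reductive"),
                            {"S": 500 * UM})
        assert rates.size == 3
        assert sorted(rates)[:2] == pytest.approx(sorted(lumped), rel=0.05)
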