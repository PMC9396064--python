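"""Synthetic-data generators: seeding, noise model, and kinetic fidelity."""

import json

import numpy as np
import pytest
from scipy import stats

from pnaokin import (InstrumentModel, cycle_flux, fit_exponentials,
                     generate_oxidation_cycn, generate_oxidation_o2,
                     generate_reductive, generate_steady_state,
                     generate_titration)

UM = 1e-6


class TestReproducibility:
    def test_identical_seeds_give_bit_identical_traces(self, params):
        a = generate_reductive(params, instrument=InstrumentModel(seed=11))
        b = generate_reductive(params, instrument=InstrumentModel(seed=11))
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.absorbance, tb.absorbance)
        c = generate_reductive(params, instrument=InstrumentModel(seed=12))
        assert not np.array_equal(a[0].absorbance, c[0].absorbance)

    def test_steady_state_and_titration_seeded(self, params):
        d1 = generate_steady_state(params, seed=3)
        d2 = generate_steady_state(params, seed=3)
        assert np.array_equal(d1.velocities, d2.velocities)
        t1 = generate_titration(params, noise_sd=0.005, seed=3)
        t2 = generate_titration(params, noise_sd=0.005, seed=3)
        assert np.array_equal(t1.frac_red_enzyme, t2.frac_red_enzyme)


def test_noise_residuals_are_gaussian_with_configured_sd(params):
    sd = 0.002
    quiet = InstrumentModel(noise_sd=0.0, n_points=600)
    noisy = InstrumentModel(noise_sd=sd, n_points=600, seed=5)
    resid = np.concatenate([
        n.absorbance - q.absorbance
        for q, n in zip(generate_reductive(params, instrument=quiet),
                        generate_reductive(params, instrument=noisy))])
    assert resid.size >= 1000
    assert np.std(resid) == pytest.approx(sd, rel=0.1)
    assert stats.normaltest(resid).pvalue > 1e-3


class TestReductive:
    def test_noiseless_trace_is_biexponential_at_scheme_eigenrates(
            self, params, quiet_instrument):
        tr = generate_reductive(params, [500 * UM], quiet_instrument)[0]
        fit = fit_exponentials(tr, 2)
        assert fit.rates == pytest.approx([65.60283688, 6.3], rel=1e-4)

    def test_fast_product_release_collapses_to_single_phase(
            self, params, quiet_instrument):
        p = params.replace(k_rel=1e6)
        tr = generate_reductive(p, [500 * UM], quiet_instrument)[0]
        fit = fit_exponentials(tr, 1)
        assert fit.rates[0] == pytest.approx(65.60283688, rel=1e-3)
        assert fit.residual_sd < 1e-6

    def test_reaction_complete_within_0p8_s_at_high_pon(self, params):
        inst = InstrumentModel(noise_sd=0.0, t_end=2.0)
        for tr in generate_reductive(params, [250 * UM, 500 * UM], inst):
            a = tr.absorbance
            total = abs(a[-1] - a[0])
            a_08 = np.interp(0.8, tr.time, a)
            assert abs(a_08 - a[-1]) <= 0.01 * total

    def test_empty_concentration_list_rejected(self, params):
        with pytest.raises(ValueError, match="empty"):
            generate_reductive(params, [])


class TestOxidationO2:
    def test_monoexponential_rate_is_bimolecular_product(
            self, params, quiet_instrument):
        tr = generate_oxidation_o2(params, [600 * UM], quiet_instrument)[0]
        fit = fit_exponentials(tr, 1)
        assert fit.rates[0] == pytest.approx(0.36, rel=1e-4)

    def test_recovery_timescale_consistent_with_20s_window(
            self, params, quiet_instrument):
        # 95% recovery in 3/k_obs ~ 8.3 s at 600 uM O2
        tr = generate_oxidation_o2(params, [600 * UM], quiet_instrument)[0]
        a = tr.absorbance
        total = a[-1] - a[0]
        t95 = tr.time[np.argmax(a - a[0] >= 0.95 * total)]
        assert t95 == pytest.approx(3.0 / 0.36, rel=0.05)

    def test_out_of_span_concentration_rejected(self, params):
        with pytest.raises(ValueError, match="O2"):
            generate_oxidation_o2(params, [2e-3])


class TestOxidationCycn:
    def test_noiseless_biexponential_rates_and_amplitude(self, params,
                                                         quiet_instrument):
        p = params.replace(frac_art=0.0)
        tr = generate_oxidation_cycn(p, [50 * UM], quiet_instrument)[0]
        fit = fit_exponentials(tr, 2)
        assert fit.rates == pytest.approx([7.0, 1.6], rel=1e-4)
        # full amplitude = 2 electrons * delta-eps * [E]
        expected = 2 * 21_000.0 * 5 * UM
        assert fit.total_amplitude == pytest.approx(expected, rel=1e-3)

    def test_minor_phase_appears_as_5pct_amplitude_at_half_per_s(
            self, params, quiet_instrument):
        tr = generate_oxidation_cycn(params, [160 * UM], quiet_instrument)[0]
        fit = fit_exponentials(tr, 3)
        assert fit.rates[2] == pytest.approx(0.5, rel=0.05)
        frac = abs(fit.amplitudes[2]) / fit.total_amplitude
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_zero_enzyme_gives_flat_trace(self, params, quiet_instrument):
        p = params.replace(frac_art=0.0)
        tr = generate_oxidation_cycn(p, [50 * UM], quiet_instrument,
                                     enzyme_conc=0.0)[0]
        assert np.all(tr.absorbance == 0.0)

    def test_substoichiometric_oxidant_rejected(self, params):
        with pytest.raises(ValueError, match="2\\*\\[E\\]"):
            generate_oxidation_cycn(params, [5 * UM], enzyme_conc=5 * UM)

    def test_cycn_reduction_signal_is_monotone(self, params, quiet_instrument):
        for tr in generate_oxidation_cycn(params, instrument=quiet_instrument):
            assert np.all(np.diff(tr.absorbance) >= -1e-12)


class TestSteadyState:
    def test_half_saturation_and_saturation_limits(self, params):
        d = generate_steady_state(params, [params.Km_cyc_emp, 0.1], cv=0.0)
        assert d.velocities[0] == pytest.approx(params.kcat_emp / 2)
        assert d.velocities[1] == pytest.approx(params.kcat_emp, rel=1e-3)

    def test_mechanistic_velocities_match_reciprocal_wait_closed_form(
            self, params):
        d = generate_steady_state(params, mode="mechanistic")
        expected = np.array([cycle_flux(params, c) for c in d.cycn_concs])
        assert np.max(np.abs(d.velocities / expected - 1)) <= 0.02

    def test_replicates_below_one_rejected(self, params):
        with pytest.raises(ValueError, match="replicates"):
            generate_steady_state(params, replicates=0)

    def test_csv_round_trip(self, params, tmp_path):
        d = generate_steady_state(params, seed=2)
        d.to_csv(tmp_path / "ss.csv")
        from pnaokin import SteadyStateDataset
        back = SteadyStateDataset.from_csv(tmp_path / "ss.csv")
        assert np.allclose(back.velocities, d.velocities)
        assert back.mode == "empirical"


class TestTitration:
    def test_electron_conservation_at_every_step(self, params):
        ser = generate_titration(params, steps=40)
        held = (params.n_enz * ser.enzyme_total * ser.frac_red_enzyme
                + params.n_dye * ser.dye_total * ser.frac_red_dye)
        assert np.max(np.abs(held - ser.delivered)) <= 1e-9

    def test_solution_potential_strictly_decreasing(self, params):
        ser = generate_titration(params, steps=40)
        assert np.all(np.diff(ser.potential) < 0)

    def test_too_few_steps_rejected(self, params):
        with pytest.raises(ValueError, match="steps"):
            generate_titration(params, steps=5)

    def test_csv_round_trip(self, params, tmp_path):
        ser = generate_titration(params, steps=12)
        ser.to_csv(tmp_path / "tit.csv")
        from pnaokin import TitrationSeries
        back = TitrationSeries.from_csv(tmp_path / "tit.csv")
        assert np.allclose(back.frac_red_dye, ser.frac_red_dye)
        assert back.em_dye == ser.em_dye
        assert back.n_dye == ser.n_dye
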