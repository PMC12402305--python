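"""Mechanistic core: derivatives, conservation laws, equilibrium oracle."""

import numpy as np
import pytest

from bsabqsp import vpop
from bsabqsp.kinetics import (EquilibriumError, PatientModel,
                              average_drug_concentration, cytokine_peaks,
                              drug_mass_balance_error, derivatives,
                              effective_binding_ratio, logistic_tumor,
                              receptor_conservation_error, simulate_patient,
                              ternary_equilibrium_oracle,
                              untreated_doubling_time)
from bsabqsp.params import (IDX, NSTATE, InitialState, InvalidParameterError,
                            PatientParameters, assemble_state,
                            derive_consistent_rates)
from bsabqsp.regimens import preset_regimen, two_step_priming
from bsabqsp import units


def explicit_params(**kw) -> PatientParameters:
    """Parameters with the back-solved rates pinned to explicit values."""
    base = dict(k_M=1e-13, k_F=1e-11, k_cl_S=0.5)
    base.update(kw)
    return PatientParameters(**base)


# ---------------------------------------------------------------------------
# derivatives
# ---------------------------------------------------------------------------

class TestDerivatives:
    def test_zero_drug_limit(self):
        """Without drug all drug-species derivatives vanish and the tumor
        follows pure logistic growth."""
        params = explicit_params()
        init = InitialState()
        y = assemble_state(derive_consistent_rates(params, init), init)
        dy = derivatives(y, 0.0, params)
        for name in ("depot_nmol", "drug_central", "drug_peripheral",
                     "drug_bm", "bcma_dimer", "cd3_dimer", "trimer",
                     "sbcma_dimer_central", "sbcma_dimer_bm",
                     "soluble_trimer", "drug_eliminated"):
            assert dy[IDX[name]] == 0.0, name
        N = y[IDX["tumor_cells"]]
        expected = params.g * N * (1 - N / params.N_max)
        assert dy[IDX["tumor_cells"]] == pytest.approx(expected, rel=1e-12)

    def test_empty_biology_limit(self):
        """With no cells and drug present, only PK transfer/elimination
        terms are nonzero."""
        params = explicit_params()
        y = np.zeros(NSTATE)
        y[IDX["depot_nmol"]] = 100.0
        y[IDX["drug_central"]] = 50.0
        y[IDX["drug_peripheral"]] = 10.0
        y[IDX["drug_bm"]] = 20.0
        dy = derivatives(y, 0.0, params)
        p = params
        assert dy[IDX["depot_nmol"]] == pytest.approx(-p.ka * 100.0)
        assert dy[IDX["drug_central"]] == pytest.approx(
            p.ka * 100 / p.Vc - p.CL / p.Vc * 50
            - p.Q / p.Vc * (50 - 10) - p.q_BM / p.Vc * (50 - 20))
        assert dy[IDX["drug_peripheral"]] == pytest.approx(p.Q / p.Vp * 40)
        assert dy[IDX["drug_bm"]] == pytest.approx(p.q_BM / p.V_bm * 30)
        assert dy[IDX["drug_eliminated"]] == pytest.approx(p.CL * 50)
        for name in ("bcma_free", "trimer", "tumor_cells", "il6",
                     "mprotein"):
            assert dy[IDX[name]] == 0.0, name

    def test_hand_computed_binding_fluxes(self):
        """Each binding term at a constructed unit-concentration state
        matches an explicit hand evaluation."""
        p = explicit_params(alpha_resis=0.0)
        y = np.zeros(NSTATE)
        for name in ("drug_central", "drug_bm", "bcma_free", "bcma_dimer",
                     "cd3_free", "cd3_dimer", "trimer", "sbcma_central",
                     "sbcma_bm", "sbcma_dimer_central", "sbcma_dimer_bm",
                     "soluble_trimer"):
            y[IDX[name]] = 1.0
        y[IDX["tumor_cells"]] = 1e9
        y[IDX["tcell_bm"]] = 1e9
        y[IDX["tcell_central"]] = 1e9
        y[IDX["il6_pool"]] = 1.0
        dy = derivatives(y, 0.0, p, dose_input=0.0)

        theta = 1.0 / 3.0
        k_kill = (p.k_max * theta ** p.n_kill
                  / (p.alpha_kill ** p.n_kill + theta ** p.n_kill)
                  * (1 - p.N_min / 1e9))
        # trimer: both closure routes minus both arm dissociations minus death
        f_T1 = p.chi * p.kon_C * 1.0 * 1.0 - p.koff_C * 1.0
        f_T2 = p.chi * p.kon_B * 1.0 * 1.0 - p.koff_B * 1.0
        assert dy[IDX["trimer"]] == pytest.approx(
            f_T1 + f_T2 - k_kill * 1.0, rel=1e-12)
        # BCMA dimer: association minus dissociation minus closure minus death
        f_DB = p.kon_B * 1.0 * 1.0 - p.koff_B * 1.0
        assert dy[IDX["bcma_dimer"]] == pytest.approx(
            f_DB - f_T1 - k_kill, rel=1e-12)
        # tumor: logistic growth minus Hill kill
        growth = p.g * 1e9 * (1 - 1e9 / p.N_max)
        assert dy[IDX["tumor_cells"]] == pytest.approx(
            growth - k_kill * 1e9, rel=1e-12)
        # IL-6: release from full pool minus degradation
        assert dy[IDX["il6"]] == pytest.approx(p.k_rel * 1.0 * 1.0 - 0.0)

    def test_nonfinite_state_rejected(self):
        y = np.full(NSTATE, np.nan)
        with pytest.raises(InvalidParameterError):
            derivatives(y, 0.0, explicit_params())


# ---------------------------------------------------------------------------
# simulation invariants
# ---------------------------------------------------------------------------

class TestSimulationInvariants:
    def test_untreated_matches_logistic_closed_form(self):
        params = PatientParameters(g=0.01)
        init = InitialState(N0=1e12)
        res = simulate_patient(params, init, regimen=None, horizon=400.0)
        expected = logistic_tumor(res.t, 0.01, 1e12, params.N_max)
        assert np.allclose(res.tumor_cells, expected, rtol=1e-4)

    def test_untreated_integrated_paraprotein_never_shrinks(self):
        res = simulate_patient(PatientParameters(), InitialState(),
                               regimen=None, horizon=112.0)
        marker, series = res.integrated_paraprotein()
        assessments = res.values_at(marker, [28, 56, 84, 112])
        assert np.all(assessments >= res.init.M0 * (1 - 1e-9))

    def test_drug_mass_balance_six_cycles(self, primed_result):
        assert drug_mass_balance_error(primed_result) < 1e-5

    def test_receptor_conservation_identities(self, primed_result):
        assert receptor_conservation_error(primed_result) < 1e-6

    def test_rerun_is_bit_identical(self, default_model, primed_result):
        again = default_model.simulate(two_step_priming(), horizon=168.0)
        assert np.array_equal(again.t, primed_result.t)
        assert np.array_equal(again.y, primed_result.y)

    def test_nonnegative_states_random_draws(self):
        cand = vpop.sample_trial_patients(200, seed=42)
        for _, row in cand.iterrows():
            params, init = vpop.build_patient(row)
            res = simulate_patient(params, init, two_step_priming(),
                                   horizon=56.0, check_conservation=False)
            assert res.y.min() >= 0.0, row.name

    def test_dose_outside_horizon_rejected(self, default_model):
        with pytest.raises(ValueError, match="outside"):
            default_model.simulate([(500.0, 76.0)], horizon=100.0)

    def test_deep_response_under_registrational_regimen(self, primed_result):
        """A drug-sensitive patient nearly clears integrated paraprotein by
        day ~100 under 76 mg QW with two-step priming."""
        marker, _ = primed_result.integrated_paraprotein()
        v100 = primed_result.values_at(marker, [100.0])[0]
        base = primed_result.init.M0
        assert (v100 / base - 1.0) * 100.0 <= -85.0


# ---------------------------------------------------------------------------
# effective binding ratio
# ---------------------------------------------------------------------------

class TestEffectiveBindingRatio:
    def test_drug_free_is_zero(self):
        res = simulate_patient(PatientParameters(), InitialState(),
                               regimen=None, horizon=28.0)
        assert effective_binding_ratio(res, (0, 28)) == 0.0

    def test_saturated_state_is_one(self, primed_result):
        res = primed_result
        y = res.y.copy()
        y[IDX["bcma_free"]] = 0.0
        y[IDX["bcma_dimer"]] = 0.0
        y[IDX["trimer"]] = 1.0
        import dataclasses
        sat = dataclasses.replace(res, y=y)
        assert effective_binding_ratio(sat, (0, 28)) == pytest.approx(1.0)

    def test_empty_window_errors(self, primed_result):
        with pytest.raises(ValueError):
            effective_binding_ratio(primed_result, (28.0, 28.0))
        with pytest.raises(ValueError):
            effective_binding_ratio(primed_result, (0.0, 1e5))

    def test_sbcma_sink_monotonicity(self):
        """Raising baseline sBCMA (all else fixed) never increases the
        cycle-1 average effective binding ratio in the drug-limited regime.

        The clearance is pinned so only the baseline level varies, killing
        is disabled so the tumor compartment stays intact, and a low flat
        dose keeps exposure below the trimer optimum (past the bell peak a
        sink can legitimately raise the ratio)."""
        thetas = []
        params = PatientParameters(k_cl_S=0.5, k_max=1e-12)
        for s0 in (20.0, 60.0, 150.0, 400.0, 1000.0):
            res = simulate_patient(params, InitialState(sbcma0=s0),
                                   preset_regimen("flat_16_qw"),
                                   horizon=28.0, check_conservation=False)
            thetas.append(effective_binding_ratio(res, (0, 28)))
        assert np.all(np.diff(thetas) <= 1e-6 * max(thetas)), thetas


# ---------------------------------------------------------------------------
# ternary equilibrium oracle and ODE cross-check
# ---------------------------------------------------------------------------

class TestTernaryEquilibrium:
    def test_no_drug_no_complexes(self):
        eq = ternary_equilibrium_oracle(0.0, 5.0, 2.0, 1.0)
        for key in ("DB", "DC", "TRI", "DS", "NT"):
            assert eq[key] == 0.0

    def test_one_site_closed_form(self):
        """With the CD3 arm absent the drug:BCMA dimer satisfies the
        single-site binding isotherm exactly."""
        Dt, Bt, K = 10.0, 5.0, 40.0 / 2.0   # K = koff_B / kon_B
        eq = ternary_equilibrium_oracle(Dt, Bt, 0.0, 0.0)
        disc = (Dt + Bt + K) ** 2 - 4 * Dt * Bt
        expected = ((Dt + Bt + K) - np.sqrt(disc)) / 2
        assert eq["DB"] == pytest.approx(expected, rel=1e-10)

    def test_bell_shape_over_six_decades(self):
        thetas = [ternary_equilibrium_oracle(D, 1.0, 2.0, 0.0)["theta"]
                  for D in np.logspace(-2, 4, 31)]
        th = np.array(thetas)
        peak = int(np.argmax(th))
        assert 0 < peak < th.size - 1
        assert np.all(np.diff(th[:peak + 1]) > 0)
        assert np.all(np.diff(th[peak:]) < 0)

    def test_conservation_residuals(self):
        eq = ternary_equilibrium_oracle(3.0, 1.0, 2.0, 4.0)
        assert eq["D"] + eq["DB"] + eq["DC"] + eq["TRI"] + eq["DS"] + eq["NT"] \
            == pytest.approx(3.0, abs=1e-9)
        assert eq["B"] + eq["DB"] + eq["TRI"] == pytest.approx(1.0, abs=1e-9)
        assert eq["C"] + eq["DC"] + eq["TRI"] + eq["NT"] == pytest.approx(
            2.0, abs=1e-9)
        assert eq["S"] + eq["DS"] + eq["NT"] == pytest.approx(4.0, abs=1e-9)

    def test_ode_clamp_matches_oracle(self):
        """Long-time trimer level under a clamped BM drug concentration
        agrees with the independent algebraic equilibrium."""
        tiny = 1e-12
        params = PatientParameters(k_max=tiny, g=tiny, k_shed=tiny,
                                   k_in=tiny, k_out=tiny, k_rel=tiny,
                                   alpha_resis=0.0)
        init = InitialState(sbcma0=1e-9)
        model = PatientModel(params, init,
                             solver_opts={"rtol": 1e-10, "atol": 1e-12})
        clamp = 5.0
        res = model.simulate(None, horizon=30.0, clamp_drug_bm=clamp,
                             check_conservation=False)
        B0 = (res.state("bcma_free")[0] + res.state("bcma_dimer")[0]
              + res.state("trimer")[0])
        C0 = (res.state("cd3_free")[0] + res.state("cd3_dimer")[0]
              + res.state("trimer")[0] + res.state("soluble_trimer")[0])
        eq = ternary_equilibrium_oracle(0.0, B0, C0, 0.0,
                                        fixed_free_drug=clamp)
        assert res.state("trimer")[-1] == pytest.approx(eq["TRI"], rel=1e-4)
        # the equilibrium binding-ratio matches the oracle trimer fraction
        theta_end = res.effective_binding_ratio_series[-1]
        assert theta_end == pytest.approx(eq["theta"], rel=1e-4)

    def test_negative_totals_rejected(self):
        with pytest.raises(ValueError):
            ternary_equilibrium_oracle(-1.0, 1.0, 1.0, 0.0)


# ---------------------------------------------------------------------------
# doubling times
# ---------------------------------------------------------------------------

class TestDoublingTimes:
    def test_exponential_limit(self):
        params = PatientParameters(g=np.log(2) / 100, N_max=1e16)
        t_dt, _ = untreated_doubling_time(params, InitialState(N0=1e9))
        assert t_dt == pytest.approx(100.0, rel=0.01)

    def test_carrying_capacity_never_doubles(self):
        params = PatientParameters(g=0.01, N_max=2e11)
        t_dt, m_dt = untreated_doubling_time(params, InitialState(N0=2e11))
        assert np.isinf(t_dt) and np.isinf(m_dt)

    def test_mprotein_doubling_lags_tumor(self):
        """Serum M-protein production lags the tumor, so its doubling time
        is never shorter (checked on 20 random draws)."""
        cand = vpop.sample_trial_patients(20, seed=3)
        for _, row in cand.iterrows():
            params, init = vpop.build_patient(row)
            t_dt, m_dt = untreated_doubling_time(params, init)
            if np.isfinite(t_dt):
                assert m_dt >= t_dt - 1e-6


# ---------------------------------------------------------------------------
# cytokine peaks
# ---------------------------------------------------------------------------

class TestCytokinePeaks:
    def test_equal_repeated_doses_attenuate(self, default_model):
        res = default_model.simulate(preset_regimen("flat_76_qw"),
                                     horizon=56.0)
        peaks = cytokine_peaks(res)
        assert len(peaks) == 8
        tol = 1e-6 * max(peaks)
        assert all(b <= a + tol for a, b in zip(peaks, peaks[1:])), peaks

    def test_zero_dose_empty(self, default_model):
        res = default_model.simulate(None, horizon=28.0)
        assert cytokine_peaks(res) == []

    def test_single_dose_single_global_peak(self, default_model):
        res = default_model.simulate([(1.0, 76.0)], horizon=56.0)
        peaks = cytokine_peaks(res)
        il6 = res.state("il6")[res.t >= 1.0]
        assert len(peaks) == 1
        assert peaks[0] == pytest.approx(il6.max())


# ---------------------------------------------------------------------------
# per-patient dose-grid curve regularity
# ---------------------------------------------------------------------------

def test_binding_ratio_curves_monotone_or_single_peaked(small_pool):
    """Across the 5-dose weekly grid the average effective binding ratio is
    monotone or single-peaked for every tested patient."""
    from bsabqsp.experiments import classify_curve_shape
    from bsabqsp.regimens import primed
    for i in range(5):
        row = small_pool.candidates.iloc[i]
        params, init = vpop.build_patient(row)
        model = PatientModel(params, init)
        ratios = []
        for dose in (16, 28, 44, 76, 152):
            res = model.simulate(primed(dose), horizon=84.0,
                                 check_conservation=False)
            ratios.append(effective_binding_ratio(res, (0, 84)))
        label, ok = classify_curve_shape(ratios)
        assert ok, (row.name, label, ratios)
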