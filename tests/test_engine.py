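"""Full-model assembly, equilibration and scenario integration."""

import numpy as np
import pytest

import glucoflow as gf
from glucoflow.engine import (
    IX,
    IX_LUMEN,
    NSTATE,
    SL_GLC,
    SL_GLN,
    SL_GLP,
    SL_INS,
    SL_VOL,
    build_rhs,
    initial_state,
)
from glucoflow.errors import ConfigurationError, IntegrationError


class TestAssembleDerivatives:
    def test_fasting_equilibrium_has_tiny_derivative(self, fasting_state):
        dy = gf.assemble_derivatives(0.0, fasting_state, gf.Scenario(), gf.ModelParameters())
        rel = np.abs(dy) / (np.abs(fasting_state) + 1e-9)
        assert rel.max() < 1e-6

    def test_gavage_source_term_in_window(self, fasting_state):
        sc = gf.Scenario()
        during = gf.assemble_derivatives(110.0, fasting_state, sc, gf.ModelParameters())
        before = gf.assemble_derivatives(50.0, fasting_state, sc, gf.ModelParameters())
        extra = during[IX_LUMEN] - before[IX_LUMEN]
        assert extra == pytest.approx(sc.gavage.rate_mmol_min)

    def test_volume_derivatives_sum_to_zero_without_fluid_exchange(self):
        """Closed circuit: with an empty lumen (no water co-absorption) the
        volume derivatives cancel exactly."""
        y = initial_state(gf.ModelParameters())
        dy = gf.assemble_derivatives(50.0, y, gf.Scenario(), gf.ModelParameters())
        assert dy[SL_VOL].sum() == pytest.approx(0.0, abs=1e-10)

    def test_nonfinite_state_raises_with_location(self, fasting_state):
        y = fasting_state.copy()
        y[12] = np.nan
        with pytest.raises(IntegrationError, match="non-finite"):
            gf.assemble_derivatives(0.0, y, gf.Scenario(), gf.ModelParameters())

    def test_unknown_override_path_rejected(self):
        sc = gf.Scenario(overrides=(("nonsense.key", 1.0),))
        with pytest.raises(ConfigurationError, match="nonsense.key"):
            gf.run_scenario(sc)


class TestEquilibrate:
    def test_cardiac_output_5p5_l_min(self, default_network, fasting_state):
        glp_sc = (
            1000.0 * fasting_state[SL_GLP][IX["sm_cap"]]
            / (3.0 * fasting_state[SL_VOL][IX["sm_cap"]])
        )
        state = default_network.pressure_state(fasting_state[SL_VOL], glp_sc)
        co = state.segment_flows["left_heart"] * 60.0 / 1000.0  # L/min
        assert co == pytest.approx(5.5, rel=0.10)

    def test_aortic_pressure_105(self, default_network, fasting_state):
        p = default_network.pressures(fasting_state[SL_VOL])
        assert p[IX["sys_art"]] == pytest.approx(105.0, rel=0.10)

    def test_fasting_glucose_near_5_mm(self, fasting_state):
        glc = 1000.0 * fasting_state[SL_GLC] / (3.0 * fasting_state[SL_VOL])
        assert glc[IX["sys_art"]] == pytest.approx(5.0, rel=0.15)

    def test_two_start_uniqueness(self):
        """Equilibrating from a perturbed initial state (same total volume)
        recovers the same fasting state to within 1e-6."""
        y_ref = gf.equilibrate(gf.Scenario(), use_cache=False)
        y0 = initial_state(gf.ModelParameters())
        shuffle = np.array([30.0, -20.0, 15.0, -10.0, 20.0, -25.0, -5.0, -5.0])
        y0[SL_VOL] += shuffle  # sums to zero: total blood volume preserved
        y0[SL_GLC] *= 1.3
        y0[SL_INS] *= 0.5
        y_alt = gf.equilibrate(gf.Scenario(), y0=y0)
        rel = np.abs(y_ref - y_alt) / (np.abs(y_ref) + 1e-9)
        assert rel.max() < 1e-6


class TestRunScenario:
    def test_systemic_glucose_peaks_then_returns(self, normal_run):
        """Systemic arterial glucose rises to a mid-single-digit-mM peak and
        returns to ~5 mM within 40-60 min of gavage onset."""
        t = normal_run.time
        glc = normal_run.series("glc_sys_art")
        fast = glc[np.argmin(np.abs(t - 95.0))]
        assert fast == pytest.approx(5.0, abs=0.8)
        assert 6.0 < glc[t >= 100].max() < 9.5
        g160 = glc[np.argmin(np.abs(t - 160.0))]
        assert g160 == pytest.approx(5.0, abs=1.2)

    def test_sma_flow_rises_from_500_during_absorption(self, normal_run):
        t = normal_run.time
        q = normal_run.series("Q_sma")
        fast = q[np.argmin(np.abs(t - 95.0))]
        assert fast == pytest.approx(500.0, rel=0.15)
        assert q[t >= 100].max() > 2 * fast

    def test_hepatic_artery_buffer_response(self, normal_run):
        """HA flow falls while PV flow rises post-gavage, with no explicit
        coupling programmed (emergent Kirchhoff compensation)."""
        t = normal_run.time
        window = (t >= 100) & (t <= 130)
        ha, pv = normal_run.series("Q_hep_a"), normal_run.series("Q_portal_v")
        i_pk = np.argmax(pv[window])
        fast = np.argmin(np.abs(t - 95.0))
        assert pv[window][i_pk] > pv[fast]
        assert ha[window][i_pk] < ha[fast]

    def test_zero_dose_run_stays_flat(self):
        res = gf.run_scenario(gf.Scenario(gavage=gf.GavageProtocol(dose_g=0.0)))
        for q in ("glc_sys_art", "Q_sma", "P_sm_cap", "ins_sys_art"):
            s = res.series(q)
            assert np.abs(s - s[0]).max() < 1e-3 * max(abs(s[0]), 1.0)

    def test_no_absorption_pathway_matches_fasting(self):
        """With SGLT1 and the paracellular leak disabled, the gavage never
        reaches the blood: splanchnic glucose equals the fasting run."""
        blocked = gf.Scenario(
            p_gl=0.0, overrides=(("absorption.sglt1_vmax", 0.0),)
        )
        res = gf.run_scenario(blocked)
        glc_sc = res.series("glc_sm_cap")
        assert np.abs(glc_sc - glc_sc[0]).max() < 1e-3

    def test_all_species_amounts_nonnegative(self, normal_run, open_shunt_run):
        for res in (normal_run, open_shunt_run):
            amounts = res.states[:, SL_GLC.start : SL_GLP.stop]
            assert amounts.min() >= 0.0
            assert res.states[:, IX_LUMEN].min() >= -1e-9

    def test_splanchnic_hormones_exceed_systemic_everywhere(self, normal_run, no_shunt_run):
        """Serial degradation: hormones secreted into the splanchnic bed are
        more concentrated there than arterially at every time point."""
        for res in (normal_run, no_shunt_run):
            for h in ("ins", "gln", "glp1"):
                sc = res.series(f"{h}_sm_cap")
                art = res.series(f"{h}_sys_art")
                assert np.all(sc >= art - 1e-9)

    def test_volume_conservation_fasting_run(self):
        res = gf.run_scenario(gf.Scenario(gavage=gf.GavageProtocol(dose_g=0.0)))
        tv = res.series("total_blood_volume")
        assert np.abs(tv - tv[0]).max() / tv[0] < 1e-6

    def test_volume_accounting_with_fluid_absorption(self, normal_run):
        """With the gavage, blood volume rises by the co-absorbed water and
        decays by renal relief; the instantaneous balance d(sum V)/dt =
        water_in - urine_out holds at every sampled state."""
        rhs = build_rhs(normal_run.scenario, normal_run.params)
        prm = normal_run.params.absorption
        for i in range(0, len(normal_run.time), 240):
            t, y = normal_run.time[i], normal_run.states[i]
            dv = rhs(t, y)[SL_VOL].sum()
            water = prm.water_per_mmol * max(normal_run.frame["absorption_rate"].iloc[i], 0.0)
            from glucoflow.engine import TOTAL_BLOOD_VOLUME, VOLUME_RELIEF_TAU

            urine = max(y[SL_VOL].sum() - TOTAL_BLOOD_VOLUME, 0.0) / VOLUME_RELIEF_TAU
            assert dv == pytest.approx(water - urine, abs=1e-8)

    def test_glucose_mass_balance_identity(self, normal_run):
        """d/dt(total glucose incl. lumen) = gavage input - hepatic net uptake
        - peripheral metabolism - renal excretion; advection cancels."""
        rhs = build_rhs(normal_run.scenario, normal_run.params)
        t_all, states = normal_run.time, normal_run.states
        frame = normal_run.frame
        for i in range(0, len(t_all), 120):
            t, y = t_all[i], states[i]
            dy = rhs(t, y)
            lhs = dy[SL_GLC].sum() + dy[IX_LUMEN]
            gav = normal_run.scenario.gavage
            source = gav.rate_mmol_min if gav.start_time <= t < gav.start_time + gav.duration else 0.0
            row = frame.iloc[i]
            sinks = row["NHGU"] + row["periph_insulin_dep"] + row["periph_insulin_indep"] + row["renal_excretion"]
            assert lhs == pytest.approx(source - sinks, rel=1e-9, abs=1e-9)

    def test_determinism_bitwise(self, normal_run):
        repeat = gf.run_scenario(gf.Scenario())
        for col in normal_run.frame.columns:
            assert np.array_equal(
                normal_run.frame[col].to_numpy(), repeat.frame[col].to_numpy(), equal_nan=True
            ), col

    def test_solver_refinement_stability(self, normal_run):
        """Halving the relative tolerance changes every reported peak < 0.1%."""
        from dataclasses import replace

        tight = replace(gf.SolverSettings(), rtol=gf.SolverSettings().rtol / 2)
        res2 = gf.run_scenario(gf.Scenario(), settings=tight)
        t = normal_run.time
        for q in ("glc_sys_art", "Q_sma", "NHGU", "P_sm_cap", "glcflow_portal_v"):
            a = normal_run.series(q)[t >= 100].max()
            b = res2.series(q)[t >= 100].max()
            assert abs(a - b) / abs(b) < 1e-3, q

    def test_output_cadence_and_monotone_time(self, normal_run):
        t = normal_run.time
        assert np.all(np.diff(t) > 0)
        assert np.allclose(np.diff(t), 1.0 / 12.0, atol=1e-9)
        assert t[0] == 0.0


class TestRunSweep:
    def test_single_point_equals_run_scenario(self, normal_run):
        out = gf.run_sweep(gf.Scenario(), ("p_gl", [0.15]))
        res = out[(0.15,)]
        assert np.array_equal(
            res.series("glc_sys_art"), normal_run.series("glc_sys_art")
        )

    def test_glp1_concentration_scales_strongly_with_sensitivity(self):
        """Sweeping the GLP-1 glucose sensitivity over 0.1 -> 100 raises the
        peak splanchnic GLP-1 concentration by more than an order of magnitude,
        monotonically."""
        out = gf.run_sweep(gf.Scenario(), ("glp1_glucose_sensitivity", [0.1, 10.0, 100.0]))
        peaks = [
            out[(s,)].series("glp1_sm_cap")[out[(s,)].time >= 100].max()
            for s in (0.1, 10.0, 100.0)
        ]
        assert peaks[0] < peaks[1] < peaks[2]
        assert peaks[2] / peaks[0] > 10.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            gf.run_sweep(gf.Scenario(), ("p_gl", []))

    def test_per_point_failure_captured(self):
        out = gf.run_sweep(gf.Scenario(), ("nonsense.key", [1.0, 2.0]))
        assert all(isinstance(v, Exception) for v in out.values())


class TestScenarioValidation:
    @pytest.mark.parametrize(
        "kwargs", [dict(pss_resistance=0.0), dict(presinusoidal_resistance=-1.0),
                   dict(glp1_glucose_sensitivity=-1.0)]
    )
    def test_invalid_scenarios_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            gf.Scenario(**kwargs)

    def test_gavage_dose_mmol(self):
        assert gf.GavageProtocol(dose_g=50.0).dose_mmol == pytest.approx(277.5, rel=0.01)

    def test_state_vector_layout(self, fasting_state):
        assert fasting_state.shape == (NSTATE,)
        assert fasting_state[SL_VOL].sum() == pytest.approx(5000.0, rel=1e-6)
        assert np.all(fasting_state[SL_INS] > 0)
        assert np.all(fasting_state[SL_GLN] > 0)
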