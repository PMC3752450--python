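"""Tests of the perturbation protocols, observable assembly and the
nasal-PD time-course simulation."""

import numpy as np
import pytest

from nasotrans import CL, NA, find_steady_state, reference_state
from nasotrans.simulate import (
    OBSERVABLE_NAMES,
    ObservableVector,
    apply_amiloride,
    apply_low_chloride,
    cftr_knockout_delta_vt,
    driving_force,
    evaluate_observables,
    knockout_batch,
    observables_batch,
    run_nasal_pd_protocol,
)


class TestAmiloride:
    def test_complete_block_zeroes_enac(self, params_nonCF):
        blocked = apply_amiloride(params_nonCF)
        assert blocked.P_Na_ap == 0.0
        assert blocked.P_Cl_ap == params_nonCF.P_Cl_ap
        assert blocked.rho_NaK == params_nonCF.rho_NaK

    def test_idempotent(self, params_nonCF):
        once = apply_amiloride(params_nonCF)
        assert apply_amiloride(once) == once

    def test_partial_block_factor(self, params_nonCF):
        half = apply_amiloride(params_nonCF, block=0.5)
        assert half.P_Na_ap == pytest.approx(0.5 * params_nonCF.P_Na_ap)
        with pytest.raises(ValueError):
            apply_amiloride(params_nonCF, block=1.5)


class TestLowChloride:
    def test_substitution_arithmetic(self, baths):
        low = apply_low_chloride(baths)
        assert low.lumen.Cl == 3.0
        assert low.lumen.imp == pytest.approx(baths.lumen.imp + baths.lumen.Cl - 3.0)
        assert low.lumen.osmolarity == pytest.approx(baths.lumen.osmolarity)
        assert low.lumen.Na == baths.lumen.Na and low.lumen.K == baths.lumen.K

    def test_serosal_side_untouched(self, baths):
        assert apply_low_chloride(baths).serosa == baths.serosa

    def test_cannot_raise_chloride(self, baths):
        with pytest.raises(ValueError):
            apply_low_chloride(baths, target_cl=500.0)


class TestDrivingForce:
    def test_zero_at_nernst_equilibrium(self, baths, params_nonCF, init_state):
        from nasotrans import DEFAULT_CONSTANTS

        res = find_steady_state(params_nonCF, baths, init_state, method="root")
        # construct an artificial converged result with Na+ at equilibrium
        na_i = baths.lumen.Na * np.exp(-res.state.V_a / DEFAULT_CONSTANTS.RT_F_mV)
        state_eq = res.state.replace(N_Na=na_i * 1e-6 * res.state.W_i)
        import dataclasses

        res_eq = dataclasses.replace(res, state=state_eq)
        assert driving_force(res_eq, NA, "apical", baths) == pytest.approx(0.0, abs=1e-9)

    def test_requires_converged_result(self, baths, params_nonCF, init_state):
        res = find_steady_state(params_nonCF, baths, init_state, method="root")
        import dataclasses

        bad = dataclasses.replace(res, converged=False)
        with pytest.raises(RuntimeError):
            driving_force(bad, CL, "apical", baths)


class TestObservables:
    def test_deterministic(self, baths, params_nonCF):
        a = evaluate_observables(params_nonCF, baths)
        b = evaluate_observables(params_nonCF, baths)
        assert a == b  # bit-identical dataclasses

    def test_degenerate_parameters_flagged(self, baths, params_nonCF):
        dead = params_nonCF.replace(P_Na_ap=0.0, P_Cl_ap=0.0, P_K_bl=0.0,
                                    P_Cl_bl=0.0, rho_NaK=0.0, rho_NKCC=0.0, P_pa=0.0)
        obs = evaluate_observables(dead, baths)
        assert not obs.physiological
        assert np.isnan(obs.V_t)

    def test_batch_matches_single(self, baths, params_nonCF, params_CF, init_state):
        free = np.array([params_nonCF.free_vector(), params_CF.free_vector()])
        batch, ok = observables_batch(free, params_nonCF, baths, init_state)
        assert ok.all()
        for row, p in zip(batch, (params_nonCF, params_CF)):
            single = evaluate_observables(p, baths, init_state)
            assert single.physiological
            np.testing.assert_allclose(row, single.to_array(), rtol=1e-4, atol=1e-5)

    def test_delta_metrics_reference_basal(self, baths, params_nonCF):
        obs = evaluate_observables(params_nonCF, baths)
        amil = find_steady_state(apply_amiloride(params_nonCF), baths,
                                 reference_state(baths), method="hybrid")
        basal = find_steady_state(params_nonCF, baths, reference_state(baths), method="hybrid")
        assert obs.dVt_amil == pytest.approx(amil.V_t - basal.V_t, abs=1e-5)

    def test_amiloride_depolarises_vt_for_absorbing_fixtures(self, baths, params_nonCF, params_CF):
        """Blocking an absorptive Na+ current must depolarise the
        lumen-negative V_t whenever the basal Na+ driving force is inward."""
        for p in (params_nonCF, params_CF):
            obs = evaluate_observables(p, baths)
            res = find_steady_state(p, baths, reference_state(baths), method="root")
            if driving_force(res, NA, "apical", baths) < 0:
                assert obs.dVt_amil >= 0


class TestKnockout:
    def test_zero_when_cftr_already_absent(self, baths, params_nonCF):
        p0 = params_nonCF.replace(P_Cl_ap=0.0)
        assert cftr_knockout_delta_vt(p0, baths) == pytest.approx(0.0, abs=1e-7)

    def test_batch_matches_single(self, baths, params_nonCF, init_state):
        dvt, ok = knockout_batch(np.array([params_nonCF.free_vector()]),
                                 params_nonCF, baths, init_state)
        assert ok[0]
        assert dvt[0] == pytest.approx(cftr_knockout_delta_vt(params_nonCF, baths), abs=1e-5)


class TestNasalPD:
    @pytest.fixture(scope="class")
    def trace(self, params_nonCF, baths):
        return run_nasal_pd_protocol(params_nonCF, baths, variant="nonCF",
                                     t_end_min=16.0, samples_per_min=20)

    def test_causal_before_first_event(self, trace):
        pre = trace.V_t[trace.time_min < 5.0]
        assert np.all(np.abs(pre - pre[0]) < 1e-3)

    def test_events_ordered_and_recorded(self, trace):
        events = dict(trace.events)
        assert events["amiloride"] < events["low_chloride"]

    def test_summary_matches_trace_endpoints(self, trace):
        s = trace.summary()
        assert s["V_t_basal"] == pytest.approx(trace.V_t[0], abs=1e-3)
        assert s["dVt_amiloride"] == pytest.approx(
            trace.V_t[trace.time_min < 10.0][-1] - trace.V_t[0], abs=1e-6
        )

    def test_invalid_variant_rejected(self, params_nonCF, baths):
        with pytest.raises(ValueError):
            run_nasal_pd_protocol(params_nonCF, baths, variant="nope")

    def test_tidy_frame_layout(self, trace):
        df = trace.to_frame()
        assert set(df.columns) == {"time_min", "variable", "value"}
        assert set(df["variable"]) == {"V_t", "V_a", "V_b", "Na_i", "Cl_i"}


class TestProtocolVariants:
    def test_reduced_cftr_barely_hyperpolarises_basal_vt(self, baths, params_nonCF, init_state):
        """Dropping CFTR to 5% of its healthy level changes basal V_t by only
        a few millivolts — far short of the tens of millivolts seen in CF."""
        basal = find_steady_state(params_nonCF, baths, init_state, method="root")
        low = find_steady_state(params_nonCF.replace(P_Cl_ap=0.05 * params_nonCF.P_Cl_ap),
                                baths, basal.state, method="root")
        assert abs(low.V_t - basal.V_t) < 5.0

    def test_restoring_cftr_does_not_normalise_cf_vt(self, baths, params_CF, params_nonCF,
                                                     init_state):
        """Restoring healthy CFTR levels in a CF cell leaves basal V_t
        hyperpolarised at a typical CF level."""
        from nasotrans.params import load_filter_bounds_table

        restored = params_CF.replace(P_Cl_ap=params_nonCF.P_Cl_ap)
        res = find_steady_state(restored, baths, init_state, method="root")
        lo, hi = load_filter_bounds_table("CF")["V_t"]
        assert lo <= res.V_t <= hi
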