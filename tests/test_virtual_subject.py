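"""Ground-truth simulator: blood chemistry, HPV/iNO maps, breath dynamics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capnolung import (
    SubjectParameters,
    VentilationPattern,
    alveolar_pco2,
    co2_content,
    hpv_response,
    run_protocol,
    step_breath,
    update_venous,
)
from capnolung.virtual_subject import (
    PhysiologicalState,
    SimulationInstabilityError,
    capillary_content_slope,
    default_protocol,
    initial_state,
    molar_balance_residuals,
    run_stream,
)


class TestCO2Content:
    def test_hand_evaluated_reference_point(self):
        """Published dissociation formula evaluated independently.

        pK' = 6.086 + (38−37)·0.00472 = 6.09072; solubility 0.0307
        mmol/(L·mmHg); plasma content 0.0307·39.978·(1+10^(7.4−6.09072))
        = 26.2448 mmol/L; whole-blood factor for Hb 12 g/dL, SO2 1.0:
        1 − 0.0289·12/((3.352−0.456)·(8.142−7.4)) = 0.838610; times the
        CO2 molar volume 22.263 L/mol -> 0.4900 L_gas/L_blood.
        """
        assert co2_content(5.33, 120.0, 1.0, 7.40, 37.0) == pytest.approx(
            0.4900, rel=5e-4
        )

    def test_zero_hemoglobin_gives_plasma_content(self):
        assert co2_content(5.33, 0.0) == pytest.approx(0.58429, rel=1e-4)

    @given(pco2=st.floats(1.0, 25.0))
    @settings(max_examples=30, deadline=None)
    def test_monotone_increasing_in_pco2(self, pco2):
        assert co2_content(pco2 + 0.1, 100.0) > co2_content(pco2, 100.0)

    def test_haldane_effect(self):
        """Desaturated blood carries more CO2 at the same PCO2."""
        assert co2_content(5.33, 120.0, so2=0.7) > co2_content(5.33, 120.0, so2=1.0)

    @pytest.mark.parametrize("kw", [
        dict(pco2=-1.0), dict(pco2=31.0), dict(ph=6.5), dict(ph=8.0),
    ])
    def test_non_physiologic_inputs_rejected(self, kw):
        pco2 = kw.pop("pco2", 5.33)
        with pytest.raises(ValueError):
            co2_content(pco2, 120.0, **kw)


class TestAlveolarPCO2:
    def test_direct_product_and_linearity(self):
        assert alveolar_pco2(0.0) == 0.0
        assert alveolar_pco2(0.05) == pytest.approx(4.7515, abs=1e-9)
        assert alveolar_pco2(0.10) == pytest.approx(2 * alveolar_pco2(0.05))

    def test_water_vapor_above_barometric_rejected(self):
        with pytest.raises(ValueError):
            alveolar_pco2(0.05, pbaro_kpa=5.0, ph2o_kpa=6.0)


class TestHPVResponse:
    def test_pvr_calibration_anchors(self, params):
        """Group-mean PVR at hyperoxia and maximal hypoxia, by construction."""
        assert hpv_response(1.0, 0.0, params)[1] == pytest.approx(2.4, abs=1e-9)
        assert hpv_response(0.16, 0.0, params)[1] == pytest.approx(6.8, abs=1e-9)

    def test_pao2_anchors(self, params):
        for fio2, pao2 in [(1.0, 63.2), (0.5, 29.8), (0.21, 10.9), (0.16, 6.5)]:
            assert hpv_response(fio2, 0.0, params)[0] == pytest.approx(pao2)

    def test_ino_anchor_and_full_efficacy_limit(self, params):
        assert hpv_response(0.16, 20.0, params)[1] == pytest.approx(4.1, abs=1e-9)
        full = SubjectParameters(ino_efficacy=1.0)
        for fio2 in (0.16, 0.21, 0.5):
            assert hpv_response(fio2, 20.0, full)[1] == pytest.approx(full.pvr0)

    def test_flow_falls_as_pvr_rises(self, params):
        epbfs = [hpv_response(f, 0.0, params)[2] for f in (1.0, 0.5, 0.21, 0.16)]
        assert all(a > b for a, b in zip(epbfs, epbfs[1:]))

    def test_fio2_range_checked(self, params):
        with pytest.raises(ValueError):
            hpv_response(0.05, 0.0, params)


class TestBreathDynamics:
    def test_molar_balance_hand_example(self, params, pattern):
        """Solving the balance for (cv − cc) = 0.02, Δt 0.1 min, EELV 0.5 L,
        EPBF 2, VTCO2 0.003 L must land on FACO2 = 0.052."""
        p = SubjectParameters(eelv_true=0.5, eelv_anatomic=0.4)
        pat = VentilationPattern(tidal_volume=0.11, airway_dead_space=0.05)
        kappa = capillary_content_slope(p)
        # choose cv so that capillary content at the *solution* leaves a
        # venous-capillary gap of exactly 0.02
        cv = 0.02 + kappa * 0.052
        state = PhysiologicalState(
            faco2=0.05, cvco2=cv, epbf=2.0, pvr=2.4, pao2=63.2, fio2=1.0
        )
        new, rec, cc = step_breath(state, 0.1, 2.0, 4.0, "normal", pat, p)
        assert rec.vtco2_l == pytest.approx(0.003, rel=1e-12)
        assert new.faco2 == pytest.approx(0.052, rel=1e-9)
        assert cv - cc == pytest.approx(0.02, rel=1e-9)

    def test_no_flux_leaves_faco2_unchanged(self, params):
        pat = VentilationPattern(tidal_volume=0.051, airway_dead_space=0.0509999)
        state = PhysiologicalState(
            faco2=0.05, cvco2=0.55, epbf=1e-12, pvr=2.4, pao2=63.2, fio2=1.0
        )
        new, rec, _ = step_breath(state, 0.05, 1.0, 2.0, "normal", pat, params)
        assert new.faco2 == pytest.approx(0.05, rel=1e-5)

    def test_emitted_triples_satisfy_balance_exactly(self, params, pattern):
        sim = run_protocol(params, seed=11, noise=False)
        res = molar_balance_residuals(sim.breaths, sim.breath_truth, params)
        assert np.nanmax(np.abs(res)) < 1e-12

    def test_steady_state_elimination_matches_metabolism(self, params, pattern):
        """Mass balance: mean VTCO2 per minute equals metabolic VCO2."""
        state = initial_state(params, pattern, 1.0)
        _, truth, _ = run_stream(params, pattern, 270, state)
        tail = pd.DataFrame(truth).tail(90)
        vco2 = tail["vtco2_l"].sum() / tail["dt_min"].sum()
        assert vco2 == pytest.approx(params.vco2_met, rel=0.01)

    def test_instability_error_names_breath(self, params, pattern):
        state = PhysiologicalState(
            faco2=0.149, cvco2=5.0, epbf=30.0, pvr=1.0, pao2=63.2, fio2=1.0
        )
        with pytest.raises(SimulationInstabilityError) as exc:
            run_stream(params, pattern, 5, state, venous_dynamics=False,
                       start_index=41)
        assert exc.value.breath_index >= 41


class TestVenousStore:
    def test_fixed_point(self, params):
        state = PhysiologicalState(
            faco2=0.06, cvco2=0.0, epbf=3.0, pvr=2.4, pao2=63.2, fio2=1.0
        )
        state.cvco2 = state.ccco2(params) + params.vco2_met / state.epbf
        assert update_venous(state, params, 0.05) == pytest.approx(
            state.cvco2, rel=1e-12
        )

    def test_halving_flow_doubles_venous_gap(self, params):
        """Fixed-point algebra: (cv − cc) = VCO2/EPBF."""
        def gap(epbf):
            state = PhysiologicalState(
                faco2=0.06, cvco2=1.0, epbf=epbf, pvr=2.4, pao2=63.2, fio2=1.0
            )
            cc = state.ccco2(params)
            # iterate Euler updates to convergence
            for _ in range(20000):
                state.cvco2 = update_venous(state, params, 0.05)
            return state.cvco2 - cc

        assert gap(1.5) == pytest.approx(2 * gap(3.0), rel=1e-6)

    def test_relaxation_without_metabolism(self):
        p = SubjectParameters(vco2_met=1e-15)
        state = PhysiologicalState(
            faco2=0.06, cvco2=0.9, epbf=3.0, pvr=2.4, pao2=63.2, fio2=1.0
        )
        cc = state.ccco2(p)
        prev = state.cvco2
        for _ in range(50):
            state.cvco2 = update_venous(state, p, 0.05)
            assert cc - 1e-12 <= state.cvco2 < prev
            prev = state.cvco2

    def test_cv_stays_above_cc_in_protocol(self, params):
        sim = run_protocol(params, seed=5, noise=False)
        t = sim.breath_truth
        assert (t["cvco2"] >= t["ccco2"] - 1e-12).all()


class TestProtocol:
    def test_same_seed_bit_identical(self, params):
        a = run_protocol(params, seed=42)
        b = run_protocol(params, seed=42)
        pd.testing.assert_frame_equal(a.breaths, b.breaths)
        pd.testing.assert_frame_equal(a.step_truth, b.step_truth)

    def test_doubling_condition(self, params):
        sim = run_protocol(params, seed=0, noise=False)
        s = sim.step_truth.set_index("step_id")["pvr_woods"]
        assert s[4] >= 2 * s[1]

    def test_pattern_and_protocol_invariants(self, pattern):
        assert pattern.cycle_length == 9
        assert 2.0 <= pattern.pause_s <= 3.0
        steps = default_protocol()
        assert [s.step_id for s in steps] == list(range(1, 8))
        assert [s.fio2 for s in steps] == [1.0, 0.5, 0.21, 0.16, 0.16, 0.21, 1.0]
        assert [s.ino_ppm > 0 for s in steps] == [False] * 4 + [True] * 3

    def test_empty_protocol_rejected(self, params):
        with pytest.raises(ValueError):
            run_protocol(params, protocol=[])
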