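"""Capnodynamic estimator: system construction, solving, sliding windows."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from capnolung import (
    CapnodynamicEstimator,
    EstimatorConfig,
    SubjectParameters,
    VentilationPattern,
    build_system,
    run_estimator,
    solve_window,
)
from capnolung.capnodynamic import summarize_step
from capnolung.virtual_subject import initial_state, run_stream

from conftest import stream_frame


def steady_window(k=9, dt=0.05, fa=0.06, vt=0.011):
    """Stationary breaths with identical timing: unidentifiable by design."""
    return pd.DataFrame({
        "breath_index": np.arange(k),
        "dt_min": np.full(k, dt),
        "vtco2_l": np.full(k, vt),
        "faco2": np.full(k, fa),
    })


class TestBuildSystem:
    def test_shape_contract(self, est_config):
        A, b = build_system(steady_window(9), est_config)
        assert A.shape == (8, 3) and b.shape == (8,)

    def test_steady_state_rank_deficient(self, est_config):
        A, _ = build_system(steady_window(), est_config)
        assert np.linalg.matrix_rank(A) < 3

    def test_noiseless_window_consistent_with_truth(
        self, constant_physiology_stream, params, est_config
    ):
        """Rows evaluated on simulated breaths satisfy A x_true = b exactly."""
        records, truth, state = constant_physiology_stream
        df = stream_frame(records)
        A, b = build_system(df.iloc[9:18], est_config)
        x_true = np.array([
            params.eelv_true, state.epbf, state.epbf * state.cvco2,
        ])
        assert np.allclose(A @ x_true, b, rtol=0, atol=1e-14)

    def test_non_consecutive_indices_rejected(self, est_config):
        w = steady_window()
        w.loc[4, "breath_index"] = 99
        with pytest.raises(ValueError):
            build_system(w, est_config)


class TestSolveWindow:
    def test_noiseless_recovery_to_1e9(self, est_config):
        """Forward-generated 9-breath window with EELV 0.50 L, EPBF 2.0,
        CvCO2 0.55 is recovered essentially exactly."""
        p = SubjectParameters(eelv_true=0.5, eelv_anatomic=0.4, hb=est_config.hb)
        pat = VentilationPattern.for_weight(24.0)
        state = initial_state(p, pat, 1.0)
        state.epbf = 2.0
        state.cvco2 = 0.55
        records, _, _ = run_stream(p, pat, 40, state, venous_dynamics=False)
        A, b = build_system(stream_frame(records).iloc[-10:], est_config)
        est = solve_window(A, b, est_config)
        assert est.valid
        assert est.eelv_co2 == pytest.approx(0.5, rel=1e-9)
        assert est.epbf == pytest.approx(2.0, rel=1e-9)
        assert est.cvco2 == pytest.approx(0.55, rel=1e-9)

    def test_solution_homogeneity(self, est_config):
        """Scaling (VTCO2, EELV-row) consistently scales the solution."""
        rng = np.random.default_rng(0)
        A = rng.normal(size=(8, 3))
        x = np.array([0.5, 2.0, 1.1])
        b = A @ x
        c = 3.7
        est1 = solve_window(A, b, est_config)
        est2 = solve_window(A, c * b, est_config)
        assert est2.eelv_co2 == pytest.approx(c * est1.eelv_co2, rel=1e-9)
        assert est2.cvco2 == pytest.approx(est1.cvco2, rel=1e-9)  # ratio invariant

    def test_steady_window_flagged_unidentifiable(self, est_config):
        A, b = build_system(steady_window(), est_config)
        est = solve_window(A, b, est_config)
        assert not est.valid
        assert est.reason in ("unidentifiable", "ill-conditioned")


class TestSlidingEstimator:
    def test_stationary_noiseless_stream_recovers_truth(
        self, constant_physiology_stream, params, est_config
    ):
        records, _, state = constant_physiology_stream
        est = est_config.make_estimator().fit(records)
        e = est.estimates_
        assert e["valid"].all()
        for col, truth in [
            ("eelv_co2_l", params.eelv_true),
            ("epbf_lmin", state.epbf),
            ("cvco2", state.cvco2),
        ]:
            assert np.allclose(e[col], truth, rtol=1e-9)

    def test_window_count_contract(self, constant_physiology_stream, est_config):
        records, _, _ = constant_physiology_stream
        e = run_estimator(stream_frame(records), est_config)
        assert len(e) == len(records) - est_config.window_breaths + 1

    def test_stream_shorter_than_window_rejected(self, est_config):
        with pytest.raises(ValueError):
            est_config.make_estimator().fit(steady_window(5))

    def test_estimates_invariant_to_index_shift(
        self, constant_physiology_stream, est_config
    ):
        records, _, _ = constant_physiology_stream
        df = stream_frame(records)
        shifted = df.assign(breath_index=df["breath_index"] + 1000)
        a = est_config.make_estimator().fit(df).estimates_
        b = est_config.make_estimator().fit(shifted).estimates_
        assert np.allclose(a["eelv_co2_l"], b["eelv_co2_l"])

    def test_noisy_stream_mean_recovery_and_window_scaling(
        self, params, pattern, est_config
    ):
        """2 per-mille noise: mean EELV within 5 % of truth; doubling the
        window shrinks the dispersion (fixed seed Monte-Carlo)."""
        rng = np.random.default_rng(123)
        state = initial_state(params, pattern, 1.0)
        records, _, _ = run_stream(params, pattern, 225, state,
                                   venous_dynamics=False)
        df = stream_frame(records)
        cv = 0.002
        sigma = np.sqrt(np.log1p(cv * cv))
        for col in ("faco2", "vtco2_l"):
            df[col] = df[col] * rng.lognormal(-sigma**2 / 2, sigma, len(df))
        e9 = est_config.make_estimator().fit(df).estimates_
        e9 = e9[e9["valid"]]
        assert e9["eelv_co2_l"].mean() == pytest.approx(params.eelv_true, rel=0.05)
        wide = EstimatorConfig(**{**est_config.__dict__, "window_breaths": 18})
        e18 = wide.make_estimator().fit(df).estimates_
        e18 = e18[e18["valid"]]
        assert e18["eelv_co2_l"].std() < e9["eelv_co2_l"].std()

    def test_carry_forward_flags_invalid_windows(self, est_config):
        good = SubjectParameters(hb=est_config.hb)
        pat = VentilationPattern.for_weight(24.0)
        state = initial_state(good, pat, 1.0)
        records, _, _ = run_stream(good, pat, 27, state, venous_dynamics=False)
        df = stream_frame(records)
        flat = steady_window(18, fa=float(df["faco2"].iloc[-1]))
        flat["breath_index"] = np.arange(27, 45)
        both = pd.concat([df, flat], ignore_index=True)
        e = est_config.make_estimator().fit(both).estimates_
        bad = e[~e["valid"]]
        assert len(bad) > 0
        last_good = e[e["valid"]].iloc[-1]
        # flagged rows carry the last valid value
        assert np.allclose(bad["eelv_co2_l"].iloc[-1], last_good["eelv_co2_l"])

    def test_reconvergence_after_transient(self, params, pattern, est_config):
        """After a step change in EPBF with venous drift, per-cycle
        summaries deviate transiently and re-converge within 5 cycles."""
        state = initial_state(params, pattern, 1.0)
        rec1, _, state = run_stream(params, pattern, 54, state)
        state.epbf *= 0.6  # abrupt flow drop
        rec2, _, _ = run_stream(params, pattern, 90, state, start_index=54,
                                cycle_phase=54)
        df = stream_frame(rec1 + rec2)
        df["step_id"] = [1] * 54 + [2] * 90
        e = est_config.make_estimator().fit(df).estimates_
        summary = summarize_step(e, df, 2)
        assert summary["eelv_co2_l"] == pytest.approx(params.eelv_true, rel=0.05)


class TestSklearnInterface:
    def test_get_set_params_and_clone(self, est_config):
        est = CapnodynamicEstimator(window_breaths=12, hb=90.0)
        assert est.get_params()["window_breaths"] == 12
        est2 = clone(est).set_params(hb=110.0)
        assert est2.hb == 110.0 and est2.window_breaths == 12

    def test_fitted_attributes(self, constant_physiology_stream, params):
        records, _, _ = constant_physiology_stream
        est = CapnodynamicEstimator(hb=params.hb).fit(records)
        assert est.eelv_co2_ == pytest.approx(params.eelv_true, rel=1e-9)
        assert est.n_valid_ == est.n_windows_

    def test_array_input_accepted(self, constant_physiology_stream, params):
        records, _, _ = constant_physiology_stream
        X = np.column_stack([
            [r.dt_min for r in records],
            [r.vtco2_l for r in records],
            [r.faco2 for r in records],
        ])
        pred = CapnodynamicEstimator(hb=params.hb).predict(X)
        assert pred.shape == (len(records) - 8, 3)
        assert np.allclose(pred[:, 0], params.eelv_true, rtol=1e-9)
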