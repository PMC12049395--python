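"""Capnodynamic estimation of EELV-CO2, EPBF and mixed-venous CO2 content.

The tested method.  Over a sliding window of consecutive breaths the
per-breath CO2 molar balance

    EELV · (FAⁿ − FAⁿ⁻¹) = EPBF · Δtⁿ · (CvCO2 − CcCO2ⁿ) − VTCO2ⁿ

is linear in (EELV, EPBF, EPBF·CvCO2) once the capillary content CcCO2ⁿ
is computed from the measured alveolar fraction and hemoglobin via the
CO2 dissociation model.  Ordinary least squares over one full cycle of
the forced 6+3 ventilation pattern (which perturbs Δt and hence the
alveolar CO2 excursion) identifies all three unknowns; without the
pattern the system is rank deficient.

Windows that are unidentifiable, ill-conditioned, non-physical
(non-positive volume or flow) or poorly fit are flagged — never
discarded silently — and carry the last valid values forward.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .virtual_subject import alveolar_pco2, co2_content

_BREATH_COLUMNS = ("dt_min", "vtco2_l", "faco2")


@dataclass
class EstimatorConfig:
    """Estimator settings; mirrors :class:`CapnodynamicEstimator` parameters."""

    window_breaths: int = 9
    advance: int = 1
    hb: float = 100.0
    pbaro: float = 101.3
    ph2o: float = 6.27
    so2: float = 1.0
    ph: float = 7.40
    temp_c: float = 37.0
    min_faco2_excursion: float = 1e-4
    max_relative_residual: float = 0.25
    max_condition: float = 1e8
    cc_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.window_breaths < 4:
            raise ValueError("window_breaths must be >= 4 (3 unknowns + 1)")
        if self.advance < 1:
            raise ValueError("advance must be >= 1")
        for name in ("min_faco2_excursion", "max_relative_residual", "max_condition"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def make_estimator(self) -> "CapnodynamicEstimator":
        return CapnodynamicEstimator(**asdict(self))


@dataclass(frozen=True)
class CapnodynamicEstimate:
    """One windowed solution."""

    eelv_co2: float        # L
    epbf: float            # L·min⁻¹
    cvco2: float           # L_gas·L_blood⁻¹
    window_end_index: int
    residual_norm: float   # relative
    condition: float
    valid: bool
    reason: str = ""


def _as_breath_frame(X) -> pd.DataFrame:
    """Accept a breath-table DataFrame, a BreathRecord list, or an (n, 3) array."""
    if isinstance(X, pd.DataFrame):
        missing = [c for c in _BREATH_COLUMNS if c not in X.columns]
        if missing:
            raise ValueError(f"breath table missing columns {missing}")
        df = X.reset_index(drop=True).copy()
        if "breath_index" not in df.columns:
            df["breath_index"] = np.arange(len(df))
        return df
    if isinstance(X, (list, tuple)) and X and hasattr(X[0], "vtco2_l"):
        return pd.DataFrame(
            {
                "breath_index": [r.index for r in X],
                "dt_min": [r.dt_min for r in X],
                "vtco2_l": [r.vtco2_l for r in X],
                "faco2": [r.faco2 for r in X],
            }
        )
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(
            "expected a DataFrame with columns "
            f"{_BREATH_COLUMNS}, a list of BreathRecord, or an (n, 3) array "
            "of [dt_min, vtco2_l, faco2]"
        )
    return pd.DataFrame(
        {
            "breath_index": np.arange(arr.shape[0]),
            "dt_min": arr[:, 0],
            "vtco2_l": arr[:, 1],
            "faco2": arr[:, 2],
        }
    )


def build_system(window: pd.DataFrame, cfg: EstimatorConfig | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Linear system (A, b) for one window of consecutive breaths.

    The first breath of the window only supplies the lagged alveolar
    fraction; each later breath n contributes one row

        [FAⁿ − FAⁿ⁻¹,  Δtⁿ·CcCO2ⁿ,  −Δtⁿ] · (EELV, EPBF, EPBF·CvCO2)ᵀ = −VTCO2ⁿ

    with CcCO2ⁿ evaluated from breath n's own end-expiratory fraction —
    the same convention the molar balance is integrated with, so
    noiseless simulated windows satisfy the system exactly.
    """
    cfg = cfg or EstimatorConfig()
    window = _as_breath_frame(window)
    if len(window) < 2:
        raise ValueError("window must contain at least 2 breaths")
    idx = window["breath_index"].to_numpy()
    if np.any(np.diff(idx) != 1):
        raise ValueError("window breaths must have consecutive indices")
    fa = window["faco2"].to_numpy(dtype=float)
    dt = window["dt_min"].to_numpy(dtype=float)
    vt = window["vtco2_l"].to_numpy(dtype=float)
    cc = co2_content(
        alveolar_pco2(fa[1:], cfg.pbaro, cfg.ph2o),
        cfg.hb, cfg.so2, cfg.ph, cfg.temp_c,
    ) * cfg.cc_scale
    A = np.column_stack([fa[1:] - fa[:-1], dt[1:] * cc, -dt[1:]])
    b = -vt[1:]
    return A, b


def solve_window(A: np.ndarray, b: np.ndarray,
                 cfg: EstimatorConfig | None = None,
                 window_end_index: int = -1) -> CapnodynamicEstimate:
    """Ordinary least squares for (EELV, EPBF, EPBF·CvCO2) with quality flags.

    Rank deficiency yields an invalid estimate with reason
    ``"unidentifiable"`` rather than an exception.
    """
    cfg = cfg or EstimatorConfig()
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    x, _, rank, sv = np.linalg.lstsq(A, b, rcond=None)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    resid = float(np.linalg.norm(A @ x - b) / max(np.linalg.norm(b), 1e-300))

    reason = ""
    if rank < A.shape[1]:
        reason = "unidentifiable"
    elif cond > cfg.max_condition:
        reason = "ill-conditioned"
    elif resid > cfg.max_relative_residual:
        reason = "high-residual"
    elif x[0] <= 0:
        reason = "nonpositive-eelv"
    elif x[1] <= 0:
        reason = "nonpositive-epbf"

    cvco2 = x[2] / x[1] if x[1] > 0 else np.nan
    return CapnodynamicEstimate(
        eelv_co2=float(x[0]), epbf=float(x[1]), cvco2=float(cvco2),
        window_end_index=int(window_end_index), residual_norm=resid,
        condition=cond, valid=reason == "", reason=reason,
    )


class CapnodynamicEstimator(BaseEstimator):
    """Sliding-window capnodynamic estimator.

    scikit-learn style: construct with hyperparameters, call :meth:`fit`
    on a breath stream, read the fitted attributes.

    Parameters
    ----------
    window_breaths : int
        Breaths per window; default 9, one full cycle of the forced
        6+3 ventilation pattern.
    advance : int
        Breaths the window slides between estimates.
    hb : float
        Hemoglobin (g·L⁻¹) entering the CO2 dissociation model.
    pbaro, ph2o : float
        Barometric and water-vapor pressure, kPa.
    so2, ph, temp_c : float
        Blood-gas inputs of the dissociation model.
    min_faco2_excursion : float
        Windows whose alveolar-fraction range falls below this are
        flagged unidentifiable without solving.
    max_relative_residual : float
        Relative residual above which a window is flagged.
    max_condition : float
        Condition-number cap for a window to count as valid.
    cc_scale : float
        Multiplier on the capillary-content model (1.0 = the simulator's
        own dissociation curve; other values deliberately mismatch the
        model to study dissociation-slope sensitivity).

    Attributes
    ----------
    estimates_ : pandas.DataFrame
        One row per window: ``window_end_index, eelv_co2_l, epbf_lmin,
        cvco2, residual, condition, valid, reason``.  Invalid windows
        carry the last valid values forward and are flagged.
    eelv_co2_, epbf_, cvco2_ : float
        Values of the last valid window (NaN if none).
    n_windows_, n_valid_ : int
    """

    def __init__(self, window_breaths: int = 9, advance: int = 1,
                 hb: float = 100.0, pbaro: float = 101.3, ph2o: float = 6.27,
                 so2: float = 1.0, ph: float = 7.40, temp_c: float = 37.0,
                 min_faco2_excursion: float = 1e-4,
                 max_relative_residual: float = 0.25,
                 max_condition: float = 1e8, cc_scale: float = 1.0):
        self.window_breaths = window_breaths
        self.advance = advance
        self.hb = hb
        self.pbaro = pbaro
        self.ph2o = ph2o
        self.so2 = so2
        self.ph = ph
        self.temp_c = temp_c
        self.min_faco2_excursion = min_faco2_excursion
        self.max_relative_residual = max_relative_residual
        self.max_condition = max_condition
        self.cc_scale = cc_scale

    def _config(self) -> EstimatorConfig:
        return EstimatorConfig(**self.get_params())

    def fit(self, X, y=None) -> "CapnodynamicEstimator":
        """Estimate (EELV-CO2, EPBF, CvCO2) over sliding windows of ``X``.

        ``X``: breath table DataFrame (columns ``dt_min, vtco2_l, faco2``
        and optionally ``breath_index``), list of BreathRecord, or an
        (n, 3) array ``[dt_min, vtco2_l, faco2]``.
        """
        cfg = self._config()
        df = _as_breath_frame(X)
        w = cfg.window_breaths
        if len(df) < w:
            raise ValueError(
                f"stream of {len(df)} breaths shorter than one window ({w})"
            )
        fa = df["faco2"].to_numpy(dtype=float)
        rows = []
        last_valid: CapnodynamicEstimate | None = None
        for start in range(0, len(df) - w + 1, cfg.advance):
            sub = df.iloc[start : start + w]
            end_index = int(sub["breath_index"].iloc[-1])
            excursion = float(np.ptp(fa[start : start + w]))
            if excursion < cfg.min_faco2_excursion:
                est = CapnodynamicEstimate(
                    eelv_co2=np.nan, epbf=np.nan, cvco2=np.nan,
                    window_end_index=end_index, residual_norm=np.nan,
                    condition=np.inf, valid=False, reason="unidentifiable",
                )
            else:
                A, b = build_system(sub, cfg)
                est = solve_window(A, b, cfg, window_end_index=end_index)
            if est.valid:
                last_valid = est
                rows.append(est.__dict__ | {})
            else:
                carried = last_valid
                rows.append({
                    "eelv_co2": carried.eelv_co2 if carried else np.nan,
                    "epbf": carried.epbf if carried else np.nan,
                    "cvco2": carried.cvco2 if carried else np.nan,
                    "window_end_index": est.window_end_index,
                    "residual_norm": est.residual_norm,
                    "condition": est.condition,
                    "valid": False,
                    "reason": est.reason,
                })
        out = pd.DataFrame(rows).rename(columns={
            "eelv_co2": "eelv_co2_l", "epbf": "epbf_lmin",
            "residual_norm": "residual",
        })
        self.estimates_ = out[[
            "window_end_index", "eelv_co2_l", "epbf_lmin", "cvco2",
            "residual", "condition", "valid", "reason",
        ]]
        self.n_windows_ = len(out)
        self.n_valid_ = int(out["valid"].sum())
        if last_valid is not None:
            self.eelv_co2_ = last_valid.eelv_co2
            self.epbf_ = last_valid.epbf
            self.cvco2_ = last_valid.cvco2
        else:
            self.eelv_co2_ = self.epbf_ = self.cvco2_ = np.nan
        return self

    def predict(self, X) -> np.ndarray:
        """Fit ``X`` and return the per-window (EELV, EPBF, CvCO2) array."""
        self.fit(X)
        return self.estimates_[["eelv_co2_l", "epbf_lmin", "cvco2"]].to_numpy()


def run_estimator(breaths, cfg: EstimatorConfig | None = None) -> pd.DataFrame:
    """Functional wrapper: sliding-window estimates for a breath stream."""
    cfg = cfg or EstimatorConfig()
    return cfg.make_estimator().fit(breaths).estimates_


def summarize_step(estimates: pd.DataFrame, breaths: pd.DataFrame,
                   step_id: int, cycle: int = 9) -> dict:
    """Per-step summary: mean of valid estimates over the step's final cycle."""
    step_idx = breaths.loc[breaths["step_id"] == step_id, "breath_index"]
    if step_idx.empty:
        raise ValueError(f"no breaths for step {step_id}")
    last = step_idx.to_numpy()[-cycle:]
    sel = estimates[estimates["window_end_index"].isin(last)]
    valid = sel[sel["valid"]]
    use = valid if len(valid) else sel
    return {
        "step_id": step_id,
        "eelv_co2_l": float(use["eelv_co2_l"].mean()),
        "epbf_lmin": float(use["epbf_lmin"].mean()),
        "cvco2": float(use["cvco2"].mean()),
        "n_windows": int(len(sel)),
        "n_valid": int(len(valid)),
    }
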