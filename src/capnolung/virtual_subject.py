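"""Ground-truth porcine lung/circulation simulator.

A single well-mixed alveolar compartment of CO2-containing volume
``eelv_true`` exchanges CO2 with effective pulmonary blood flow (EPBF)
and a one-compartment venous CO2 store, and is ventilated with the
forced 6+3 breath pattern (six normal I:E 1:2 breaths followed by three
breaths with a 2–3 s expiratory pause).  The per-breath molar balance is

    EELV · (FACO2ⁿ − FACO2ⁿ⁻¹) = EPBF · Δtⁿ · (CvCO2 − CcCO2ⁿ) − VTCO2ⁿ

with VTCO2ⁿ = (VT − VD)·FACO2ⁿ⁻¹ and CcCO2ⁿ evaluated at the *current*
end-expiratory fraction FACO2ⁿ.  Because the dissociation model is
linear in PCO2 this implicit update has an exact closed form; it is
unconditionally stable (the explicit previous-breath variant diverges
at physiologic parameters, where EPBF·Δt·dCc/dFA + VT_alv exceeds
2·EELV) and the emitted (Δt, VTCO2, FACO2) triples satisfy the balance
*exactly* with the subject's true parameters — noiseless streams are
identifiable by construction, not up to a discretization error.

Hypoxic pulmonary vasoconstriction (HPV) and its reversal by inhaled
nitric oxide (iNO) are parametric maps anchored to group-mean PaO2 and
PVR values measured in the in-vivo porcine validation study this
simulator emulates; between anchors PaO2 is piecewise-linear in FiO2 and
the hypoxic stimulus piecewise-linear in PaO2.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .waveforms import BreathRecord, FACO2_MAX

MMHG_PER_KPA = 7.50062
#: molar volume of CO2 at standard temperature/pressure (dry), L·mol⁻¹
CO2_MOLAR_VOLUME_L = 22.263

DEFAULT_PBARO_KPA = 101.3
DEFAULT_PH2O_KPA = 6.27


class SimulationInstabilityError(RuntimeError):
    """Alveolar CO2 fraction left (0, 0.15); names the offending breath."""

    def __init__(self, breath_index: int, faco2: float):
        super().__init__(
            f"breath {breath_index}: alveolar CO2 fraction {faco2:.4g} outside (0, 0.15)"
        )
        self.breath_index = breath_index


# ---------------------------------------------------------------------------
# blood CO2 chemistry
# ---------------------------------------------------------------------------

def co2_content(pco2_kpa, hb_gl, so2: float = 1.0, ph: float = 7.40,
                temp_c: float = 37.0):
    """Whole-blood CO2 content, L_gas·L_blood⁻¹ (Douglas et al. 1988 model).

    Plasma content from CO2 solubility and apparent pK' (both functions
    of pH and temperature), corrected to whole blood as a function of
    hemoglobin and oxygen saturation (Haldane effect: content falls as
    SO2 rises).  Strictly increasing in PCO2.

    Parameters
    ----------
    pco2_kpa : float or ndarray
        CO2 partial pressure, kPa (0 < pco2 <= 30).
    hb_gl : float
        Hemoglobin, g·L⁻¹.
    so2 : float
        Hemoglobin O2 saturation, fraction in (0, 1].
    """
    pco2_kpa = np.asarray(pco2_kpa, dtype=float)
    if np.any(pco2_kpa <= 0) or np.any(pco2_kpa > 30.0):
        raise ValueError("pco2 outside physiologic range (0, 30] kPa")
    if not 6.8 <= ph <= 7.8:
        raise ValueError("ph outside 6.8-7.8")
    if not 0 < so2 <= 1:
        raise ValueError("so2 must be in (0, 1]")
    if hb_gl < 0:
        raise ValueError("hb must be non-negative")

    pk = 6.086 + 0.042 * (7.4 - ph) + (38.0 - temp_c) * (
        0.00472 + 0.00139 * (7.4 - ph)
    )
    # plasma CO2 solubility, mmol·L⁻¹·mmHg⁻¹
    sol = 0.0307 + 0.00057 * (37.0 - temp_c) + 0.00002 * (37.0 - temp_c) ** 2
    c_plasma = sol * pco2_kpa * MMHG_PER_KPA * (1.0 + 10.0 ** (ph - pk))
    hb_gdl = hb_gl / 10.0
    blood_frac = 1.0 - (0.0289 * hb_gdl) / (
        (3.352 - 0.456 * so2) * (8.142 - ph)
    )
    content = c_plasma * blood_frac * CO2_MOLAR_VOLUME_L / 1000.0
    return content if content.ndim else float(content)


def alveolar_pco2(faco2, pbaro_kpa: float = DEFAULT_PBARO_KPA,
                  ph2o_kpa: float = DEFAULT_PH2O_KPA):
    """Alveolar CO2 partial pressure from its dry-gas fraction: FACO2·(Pbaro − PH2O)."""
    faco2 = np.asarray(faco2, dtype=float)
    if np.any(faco2 < 0) or np.any(faco2 >= 1):
        raise ValueError("faco2 must be in [0, 1)")
    if ph2o_kpa >= pbaro_kpa:
        raise ValueError("ph2o must be below pbaro")
    out = faco2 * (pbaro_kpa - ph2o_kpa)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# hypoxic pulmonary vasoconstriction / iNO maps
# ---------------------------------------------------------------------------

#: group-mean PaO2 (kPa) by FiO2 — calibration anchors from the in-vivo study
PAO2_ANCHORS = ((0.16, 6.5), (0.21, 10.9), (0.5, 29.8), (1.0, 63.2))

#: group-mean PVR (Woods units) by FiO2 without iNO — calibration anchors
PVR_ANCHORS = ((0.16, 6.8), (0.21, 4.3), (0.5, 2.6), (1.0, 2.4))

#: PaO2 above which the hypoxic stimulus is zero, kPa
PAO2_HPV_THRESHOLD_KPA = 45.0

_PVR0_REF = 2.4
#: hypoxic stimulus s(PaO2) = PVR/PVR0 − 1 at the anchors, saturating below
#: the lowest anchor and zero above the threshold
_STIM_PAO2 = np.array([6.5, 10.9, 29.8, PAO2_HPV_THRESHOLD_KPA])
_STIM_VALUES = np.array([6.8, 4.3, 2.6, _PVR0_REF]) / _PVR0_REF - 1.0

#: fraction of the hypoxic PVR excess removed by 20 ppm iNO, calibrated to
#: the iNO-at-PVRmax anchor (PVR 6.8 -> 4.1 Woods at FiO2 0.16)
INO_EFFICACY = 1.0 - (4.1 / _PVR0_REF - 1.0) / (6.8 / _PVR0_REF - 1.0)


def hypoxic_stimulus(pao2_kpa: float) -> float:
    """Saturating dimensionless HPV stimulus; zero above the PaO2 threshold."""
    return float(np.interp(pao2_kpa, _STIM_PAO2, _STIM_VALUES))


@dataclass
class SubjectParameters:
    """Ground-truth physiology of one virtual piglet.

    Volumes in liters, flows in L·min⁻¹, pressures as noted.  ``None``
    defaults scale with body weight: eelv_true 24 ml·kg⁻¹, the
    SF6-visible anatomical volume sits ``delta`` = 5.5 ml·kg⁻¹ below it
    (airway volume up to the CO2 sensor plus tissue-dissolved CO2 lumped
    into eelv_true), metabolic CO2 production 7.5 ml·kg⁻¹·min⁻¹.
    """

    weight: float = 24.0                 # kg
    hb: float = 100.0                    # g·L⁻¹
    eelv_true: float | None = None       # L, CO2-containing end-expiratory volume
    eelv_anatomic: float | None = None   # L, SF6-visible volume
    epbf0: float = 3.0                   # L·min⁻¹ baseline effective pulmonary blood flow
    vco2_met: float | None = None        # L·min⁻¹ metabolic CO2 production
    v_store: float = 20.0                # L, effective venous/tissue CO2 storage volume
    pvr0: float = 2.4                    # Woods units, baseline PVR
    dp0: float | None = None             # mmHg, baseline pulmonary driving pressure
    shunt0: float = 0.10                 # baseline shunt fraction
    hpv_gain: float = 1.0                # per-subject scaling of the hypoxic stimulus
    ino_efficacy: float = INO_EFFICACY
    noise_cv_faco2: float = 0.0016
    noise_cv_vtco2: float = 0.0016
    ph: float = 7.40
    so2: float = 1.0
    temp_c: float = 37.0
    pbaro: float = DEFAULT_PBARO_KPA
    ph2o: float = DEFAULT_PH2O_KPA

    def __post_init__(self) -> None:
        if self.eelv_true is None:
            self.eelv_true = 0.024 * self.weight
        if self.eelv_anatomic is None:
            self.eelv_anatomic = self.eelv_true - 0.0055 * self.weight
        if self.vco2_met is None:
            self.vco2_met = 0.0075 * self.weight
        if self.dp0 is None:
            self.dp0 = self.epbf0 * self.pvr0 / (1.0 - self.shunt0)
        for name in ("weight", "hb", "eelv_true", "eelv_anatomic", "epbf0",
                     "vco2_met", "v_store", "pvr0", "dp0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 <= self.shunt0 < 0.5:
            raise ValueError("shunt0 must be in [0, 0.5)")
        for name in ("noise_cv_faco2", "noise_cv_vtco2"):
            if not 0 <= getattr(self, name) <= 0.2:
                raise ValueError(f"{name} must be in [0, 0.2]")


@dataclass
class PhysiologicalState:
    """Evolving hidden state between breaths."""

    faco2: float
    cvco2: float        # mixed-venous CO2 content, L_gas·L_blood⁻¹
    epbf: float         # L·min⁻¹
    pvr: float          # Woods units
    pao2: float         # kPa
    fio2: float
    ino_ppm: float = 0.0

    def ccco2(self, p: SubjectParameters) -> float:
        """Lung-capillary CO2 content at the current alveolar fraction."""
        return co2_content(
            alveolar_pco2(self.faco2, p.pbaro, p.ph2o),
            p.hb, p.so2, p.ph, p.temp_c,
        )


@dataclass(frozen=True)
class ProtocolStep:
    step_id: int
    fio2: float
    ino_ppm: float
    n_breaths: int
    #: breaths over which the hemodynamic effect of the new inspired gas
    #: settles (linear ramp of PaO2/PVR/EPBF); gas mixing and drug wash-in
    #: are fast but not instantaneous
    ramp_breaths: int = 9
    #: CV of breath-to-breath pulmonary blood flow fluctuation during the
    #: step (AR(1) vasomotor variability); largest right after iNO abruptly
    #: releases active hypoxic vasoconstriction
    flow_instability_cv: float = 0.0


def default_protocol(cycle: int = 9) -> list[ProtocolStep]:
    """The 7-step FiO2/iNO protocol.

    Step durations reflect the in-vivo timeline: PVRmax (step 4) was
    approached by successive FiO2 reductions roughly every 10 minutes,
    so it is longer than the other titration steps, whereas the iNO
    reversal acts immediately and its paired recording followed directly
    — step 5 therefore spans a single pattern cycle, so the estimator's
    windows still straddle the abrupt rise in pulmonary blood flow when
    the recording is made.
    """
    n = 11 * cycle
    return [
        ProtocolStep(1, 1.00, 0.0, n, 0, 0.010),
        ProtocolStep(2, 0.50, 0.0, n, 9, 0.020),
        ProtocolStep(3, 0.21, 0.0, n, 9, 0.035),
        ProtocolStep(4, 0.16, 0.0, 18 * cycle, 9, 0.050),
        ProtocolStep(5, 0.16, 20.0, 2 * cycle, 9, 0.120),
        ProtocolStep(6, 0.21, 20.0, n, 9, 0.035),
        ProtocolStep(7, 1.00, 20.0, n, 9, 0.020),
    ]


@dataclass
class VentilationPattern:
    """Forced 6+3 ventilation pattern.

    Six normal breaths at I:E 1:2 followed by ``n_extended`` breaths with
    an expiratory pause of ``pause_s`` (2–3 s).  Tidal volume defaults to
    10 ml·kg⁻¹ through :meth:`for_weight`.
    """

    tidal_volume: float = 0.24       # L
    airway_dead_space: float = 0.05  # L
    rr_normal: float = 20.0          # breaths·min⁻¹ for normal breaths
    pause_s: float = 2.5             # expiratory pause of extended breaths
    n_normal: int = 6
    n_extended: int = 3

    def __post_init__(self) -> None:
        if not self.tidal_volume > self.airway_dead_space > 0:
            raise ValueError("need tidal_volume > airway_dead_space > 0")
        if not 2.0 <= self.pause_s <= 3.0:
            raise ValueError("pause_s must be within [2, 3] s")
        if self.n_normal + self.n_extended < 2:
            raise ValueError("pattern cycle too short")

    @classmethod
    def for_weight(cls, weight_kg: float, *, vt_mlkg: float = 10.0,
                   dead_space_mlkg: float = 2.1, **kw) -> "VentilationPattern":
        return cls(
            tidal_volume=vt_mlkg * weight_kg / 1000.0,
            airway_dead_space=dead_space_mlkg * weight_kg / 1000.0,
            **kw,
        )

    @property
    def cycle_length(self) -> int:
        return self.n_normal + self.n_extended

    def breath_timing(self, i: int) -> tuple[float, float, float, str]:
        """(dt_min, insp_s, exp_s, phase) for breath ``i`` of a cycle."""
        period = 60.0 / self.rr_normal
        insp = period / 3.0          # I:E 1:2
        exp = period - insp
        if i % self.cycle_length < self.n_normal:
            return period / 60.0, insp, exp, "normal"
        exp_ext = exp + self.pause_s
        return (insp + exp_ext) / 60.0, insp, exp_ext, "extended"

    def alveolar_tidal_volume(self) -> float:
        return self.tidal_volume - self.airway_dead_space

    def mean_dt_min(self) -> float:
        return float(
            np.mean([self.breath_timing(i)[0] for i in range(self.cycle_length)])
        )


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def hpv_response(fio2: float, ino_ppm: float, p: SubjectParameters
                 ) -> tuple[float, float, float]:
    """(PaO2 kPa, PVR Woods, EPBF L·min⁻¹) for an inspired gas setting.

    PaO2 interpolates the FiO2 anchors (linearly extrapolated below
    FiO2 0.16); PVR = pvr0·(1 + k·g·s(PaO2)) with the iNO factor
    k = 1 − η·min(iNO/20, 1); EPBF = dp0/PVR·(1 − shunt0), so flow falls
    as PVR rises under a constant driving pressure.
    """
    if not 0.1 <= fio2 <= 1.0:
        raise ValueError("fio2 outside [0.1, 1.0]")
    if ino_ppm < 0:
        raise ValueError("ino_ppm must be non-negative")
    xp = [a[0] for a in PAO2_ANCHORS]
    fp = [a[1] for a in PAO2_ANCHORS]
    if fio2 >= xp[0]:
        pao2 = float(np.interp(fio2, xp, fp))
    else:
        slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
        pao2 = max(fp[0] - slope * (xp[0] - fio2), 1.0)
    ino_factor = 1.0 - p.ino_efficacy * min(ino_ppm / 20.0, 1.0)
    pvr = p.pvr0 * (1.0 + ino_factor * p.hpv_gain * hypoxic_stimulus(pao2))
    epbf = p.dp0 / pvr * (1.0 - p.shunt0)
    return pao2, pvr, epbf


def capillary_content_slope(p: SubjectParameters) -> float:
    """dCcCO2/dFACO2 — exact, since blood content is linear in PCO2."""
    ref = 0.05
    return co2_content(
        alveolar_pco2(ref, p.pbaro, p.ph2o), p.hb, p.so2, p.ph, p.temp_c
    ) / ref


def step_breath(state: PhysiologicalState, dt_min: float, insp_s: float,
                exp_s: float, phase: str, pattern: VentilationPattern,
                p: SubjectParameters, index: int = 0
                ) -> tuple[PhysiologicalState, BreathRecord, float]:
    """Advance the alveolar compartment by one breath.

    VTCO2ⁿ = (VT − VD)·FACO2ⁿ⁻¹; the molar balance is solved for FACO2ⁿ
    with CcCO2ⁿ = κ·FACO2ⁿ (κ the exact dissociation slope), i.e. the
    implicit update

        FACO2ⁿ = (EELV·FACO2ⁿ⁻¹ + EPBF·Δtⁿ·CvCO2 − VTCO2ⁿ) / (EELV + EPBF·Δtⁿ·κ)

    which satisfies the balance exactly and is unconditionally stable.
    Returns the new state, the noiseless BreathRecord, and the CcCO2ⁿ
    used (for truth bookkeeping).
    """
    fa_prev = state.faco2
    vtco2 = pattern.alveolar_tidal_volume() * fa_prev
    kappa = capillary_content_slope(p)
    fa_next = (
        p.eelv_true * fa_prev + state.epbf * dt_min * state.cvco2 - vtco2
    ) / (p.eelv_true + state.epbf * dt_min * kappa)
    cc = kappa * fa_next
    if not 0.0 < fa_next < FACO2_MAX:
        raise SimulationInstabilityError(index, fa_next)
    new_state = replace(state, faco2=fa_next)
    rec = BreathRecord(
        index=index, dt_min=dt_min, insp_s=insp_s, exp_s=exp_s,
        vtco2_l=vtco2, faco2=fa_next, phase=phase,
    )
    return new_state, rec, cc


def update_venous(state: PhysiologicalState, p: SubjectParameters,
                  dt_min: float) -> float:
    """One explicit-Euler step of the venous CO2 store; returns new CvCO2.

    dCv/dt = [VCO2_met − EPBF·(Cv − Cc)] / V_store; the fixed point is
    Cv = Cc + VCO2_met/EPBF (the Fick relation).
    """
    if dt_min <= 0:
        raise ValueError("dt_min must be positive")
    if p.v_store <= 0:
        raise ValueError("v_store must be positive")
    cc = state.ccco2(p)
    return state.cvco2 + dt_min * (
        p.vco2_met - state.epbf * (state.cvco2 - cc)
    ) / p.v_store


def steady_state_faco2(p: SubjectParameters, pattern: VentilationPattern) -> float:
    """Alveolar fraction at which mean elimination equals metabolic production."""
    per_cycle_dt = pattern.mean_dt_min() * pattern.cycle_length
    return p.vco2_met * per_cycle_dt / (
        pattern.alveolar_tidal_volume() * pattern.cycle_length
    )


def initial_state(p: SubjectParameters, pattern: VentilationPattern,
                  fio2: float, ino_ppm: float = 0.0) -> PhysiologicalState:
    """Approximate steady state for the given inspired gas (burn-in refines it)."""
    pao2, pvr, epbf = hpv_response(fio2, ino_ppm, p)
    fa0 = steady_state_faco2(p, pattern)
    state = PhysiologicalState(
        faco2=fa0, cvco2=0.0, epbf=epbf, pvr=pvr, pao2=pao2,
        fio2=fio2, ino_ppm=ino_ppm,
    )
    state.cvco2 = state.ccco2(p) + p.vco2_met / epbf
    return state


def run_stream(p: SubjectParameters, pattern: VentilationPattern,
               n_breaths: int, state: PhysiologicalState, *,
               venous_dynamics: bool = True, start_index: int = 0,
               cycle_phase: int = 0, epbf_path=None
               ) -> tuple[list[BreathRecord], list[dict], PhysiologicalState]:
    """Run ``n_breaths`` of the forced pattern from ``state``.

    With ``venous_dynamics=False`` the mixed-venous content is held
    constant ("constant physiology"), which makes the noiseless stream
    exactly identifiable by the capnodynamic estimator.  ``epbf_path``
    optionally prescribes the true pulmonary blood flow breath by breath
    (transition ramps, vasomotor fluctuation).
    """
    records: list[BreathRecord] = []
    truth: list[dict] = []
    for k in range(n_breaths):
        if epbf_path is not None:
            state = replace(state, epbf=float(epbf_path[k]))
        dt_min, insp_s, exp_s, phase = pattern.breath_timing(cycle_phase + k)
        cv_used = state.cvco2
        state, rec, cc = step_breath(
            state, dt_min, insp_s, exp_s, phase, pattern, p,
            index=start_index + k,
        )
        if venous_dynamics:
            state.cvco2 = update_venous(state, p, dt_min)
        records.append(rec)
        truth.append({
            "breath_index": rec.index,
            "faco2": rec.faco2,
            "vtco2_l": rec.vtco2_l,
            "dt_min": dt_min,
            "cvco2": cv_used,
            "ccco2": cc,
            "epbf_lmin": state.epbf,  # constant within the breath
            "eelv_true_l": p.eelv_true,
        })
    return records, truth, state


def _mean_one_lognormal(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size)


@dataclass
class SimulationResult:
    """Per-subject protocol simulation output."""

    breaths: pd.DataFrame       # measured (noisy) breath table
    breath_truth: pd.DataFrame  # hidden per-breath truth
    step_truth: pd.DataFrame    # per-step hidden truth summary


def run_protocol(p: SubjectParameters,
                 protocol: list[ProtocolStep] | None = None,
                 pattern: VentilationPattern | None = None,
                 seed: int | np.random.SeedSequence = 0, *,
                 noise: bool = True, burn_in_breaths: int = 54,
                 subject_id: int = 1) -> SimulationResult:
    """Run the full FiO2/iNO protocol for one subject.

    Burn-in breaths at step-1 conditions are emitted with ``step_id`` 0
    so downstream sliding windows are warm at the first protocol breath.
    Multiplicative mean-one lognormal measurement noise (configured CVs,
    independent across breaths) is applied to the emitted FACO2 and
    VTCO2 only — it never feeds back into the hidden state.
    """
    if protocol is None:
        protocol = default_protocol()
    if not protocol:
        raise ValueError("protocol must be non-empty")
    if pattern is None:
        pattern = VentilationPattern.for_weight(p.weight)
    rng = np.random.default_rng(seed)

    state = initial_state(p, pattern, protocol[0].fio2, protocol[0].ino_ppm)
    all_rows: list[dict] = []
    truth_rows: list[dict] = []
    step_rows: list[dict] = []
    idx = 0

    def emit(records, truth, step_id):
        nonlocal idx
        n = len(records)
        f_fa = _mean_one_lognormal(rng, p.noise_cv_faco2 if noise else 0.0, n)
        f_vt = _mean_one_lognormal(rng, p.noise_cv_vtco2 if noise else 0.0, n)
        for r, t, ffa, fvt in zip(records, truth, f_fa, f_vt):
            all_rows.append({
                "subject_id": subject_id, "step_id": step_id,
                "breath_index": r.index, "dt_min": r.dt_min,
                "insp_s": r.insp_s, "exp_s": r.exp_s,
                "vtco2_l": r.vtco2_l * fvt, "faco2": r.faco2 * ffa,
                "phase": r.phase,
            })
            t = dict(t)
            t["subject_id"] = subject_id
            t["step_id"] = step_id
            truth_rows.append(t)
        idx += n

    records, truth, state = run_stream(
        p, pattern, burn_in_breaths, state, start_index=idx, cycle_phase=0)
    emit(records, truth, 0)

    for step in protocol:
        pao2, pvr, epbf = hpv_response(step.fio2, step.ino_ppm, p)
        n = step.n_breaths
        ramp = min(step.ramp_breaths, n)
        w = np.minimum(np.arange(1, n + 1) / max(ramp, 1), 1.0)
        epbf_path = (1.0 - w) * state.epbf + w * epbf
        if step.flow_instability_cv > 0:
            # stationary AR(1) vasomotor fluctuation, mean-one in level
            cv_f = step.flow_instability_cv
            rho = 0.8
            var = np.log1p(cv_f * cv_f)
            g = np.empty(n)
            g[0] = rng.normal(0.0, np.sqrt(var))
            eps = rng.normal(0.0, np.sqrt(var * (1 - rho * rho)), n)
            for k in range(1, n):
                g[k] = rho * g[k - 1] + eps[k]
            epbf_path = epbf_path * np.exp(g - 0.5 * var)
        state = replace(state, pvr=pvr, pao2=pao2,
                        fio2=step.fio2, ino_ppm=step.ino_ppm)
        records, truth, state = run_stream(
            p, pattern, n, state, start_index=idx, cycle_phase=idx,
            epbf_path=epbf_path)
        state = replace(state, epbf=epbf)
        emit(records, truth, step.step_id)
        last_cycle = truth[-pattern.cycle_length:]
        vco2 = sum(t["vtco2_l"] for t in last_cycle) / sum(
            t["dt_min"] for t in last_cycle)
        step_rows.append({
            "subject_id": subject_id, "step_id": step.step_id,
            "fio2": step.fio2, "ino_ppm": step.ino_ppm,
            "pao2_kpa": pao2, "pvr_woods": pvr, "epbf_lmin": epbf,
            "cvco2": state.cvco2, "eelv_true_l": p.eelv_true,
            "eelv_anatomic_l": p.eelv_anatomic,
            "vco2_mlmin": vco2 * 1000.0,
        })

    return SimulationResult(
        breaths=pd.DataFrame(all_rows),
        breath_truth=pd.DataFrame(truth_rows),
        step_truth=pd.DataFrame(step_rows),
    )


def molar_balance_residuals(breaths: pd.DataFrame, breath_truth: pd.DataFrame,
                            p: SubjectParameters) -> np.ndarray:
    """Per-breath residual of the CO2 molar balance evaluated with the truth.

    Zero (to machine precision) on noiseless simulator output; the
    independent consistency oracle for the forward model.
    """
    b = breaths.sort_values("breath_index").reset_index(drop=True)
    t = breath_truth.sort_values("breath_index").reset_index(drop=True)
    fa = b["faco2"].to_numpy()
    fa_prev = np.concatenate([[np.nan], fa[:-1]])
    cc = t["ccco2"].to_numpy()
    res = (
        p.eelv_true * (fa - fa_prev)
        - t["epbf_lmin"].to_numpy() * b["dt_min"].to_numpy()
        * (t["cvco2"].to_numpy() - cc)
        + b["vtco2_l"].to_numpy()
    )
    return res[1:]
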