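"""SF6 wash-in/washout reference measurement of anatomical EELV.

Sulfur hexafluoride is inert and insoluble, so its wash-in/washout sees
only the anatomical gas volume (``eelv_anatomic``), not the dissolved-CO2
and airway volume the capnodynamic method includes — this is what makes
the reference systematically smaller than EELV-CO2.

Single-compartment tidal mixing: with dilution factor
a = EELV/(EELV + VT_alv), the end-tidal fraction obeys
F_k = a·F_{k−1} + (1 − a)·F_insp during wash-in (geometric approach to
the inspired fraction) and F_k = a^k·F_end during washout.  The volume
of tracer recovered over a complete washout is Σ VT_alv·a^k·F_end =
EELV·F_end, so EELV = washed-out volume / F_end exactly in the
noiseless, tail-corrected limit — the idealized model is unbiased by
construction, as a reference method must be.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class NonEquilibrationError(RuntimeError):
    """Wash-in failed to reach tolerance within the breath cap."""


@dataclass
class SF6Config:
    f_insp: float = 0.005            # inspired SF6 fraction during wash-in
    equilibration_tol: float = 0.01  # relative end-tidal/inspired gap ending wash-in
    max_breaths: int = 500
    washout_cutoff: float = 40.0     # stop when end-tidal falls below f_end/cutoff
    tail_correction: bool = True
    #: lumped measurement noise CV; 0.08/1.96 so six-repeat precision ~ +/-8 %
    noise_cv: float = 0.0408

    def __post_init__(self) -> None:
        if not 0 < self.f_insp < 0.01:
            raise ValueError("f_insp must be in (0, 0.01)")
        if not 0 < self.equilibration_tol <= 0.05:
            raise ValueError("equilibration_tol must be in (0, 0.05]")
        if self.max_breaths < 1 or self.washout_cutoff <= 1:
            raise ValueError("invalid breath cap or washout cutoff")


@dataclass(frozen=True)
class SF6Result:
    f_end: float              # end-tidal SF6 fraction at end of wash-in
    washed_out_volume: float  # L of SF6 recovered during washout (incl. tail)
    eelv_sf6: float           # L
    n_washin: int
    n_washout: int


def simulate_washin(eelv_anatomic: float, vt_alv: float,
                    cfg: SF6Config | None = None, f0: float = 0.0) -> np.ndarray:
    """End-tidal SF6 fraction after each wash-in breath.

    Terminates when |F_k − F_insp|/F_insp <= tol; raises
    :class:`NonEquilibrationError` if the cap is reached first.
    """
    cfg = cfg or SF6Config()
    if eelv_anatomic <= 0 or vt_alv <= 0:
        raise ValueError("eelv_anatomic and vt_alv must be positive")
    a = eelv_anatomic / (eelv_anatomic + vt_alv)
    f = f0
    series = []
    for _ in range(cfg.max_breaths):
        f = a * f + (1.0 - a) * cfg.f_insp
        series.append(f)
        if abs(f - cfg.f_insp) / cfg.f_insp <= cfg.equilibration_tol:
            return np.asarray(series)
    raise NonEquilibrationError(
        f"end-tidal fraction {f:.3g} vs inspired {cfg.f_insp:.3g} after "
        f"{cfg.max_breaths} breaths"
    )


def simulate_washout_and_compute(eelv_anatomic: float, vt_alv: float,
                                 f_end: float,
                                 cfg: SF6Config | None = None) -> SF6Result:
    """Washout bookkeeping and the EELV-SF6 estimate.

    Expired tracer is summed breath by breath until the end-tidal
    fraction falls below ``f_end/washout_cutoff``; the geometric tail
    beyond the cutoff is added analytically from the observed decay
    ratio (so truncation does not bias the volume).
    """
    cfg = cfg or SF6Config()
    if f_end <= 0:
        raise ValueError("f_end must be positive")
    if eelv_anatomic <= 0 or vt_alv <= 0:
        raise ValueError("eelv_anatomic and vt_alv must be positive")
    a = eelv_anatomic / (eelv_anatomic + vt_alv)
    f = f_end
    series = []
    washed = 0.0
    for _ in range(cfg.max_breaths):
        f = a * f
        series.append(f)
        washed += vt_alv * f
        if f < f_end / cfg.washout_cutoff:
            break
    else:
        raise NonEquilibrationError("washout did not reach cutoff")
    if cfg.tail_correction:
        # decay ratio estimated from the recorded end-tidal series
        a_hat = series[-1] / series[-2] if len(series) >= 2 else series[-1] / f_end
        washed += vt_alv * series[-1] * a_hat / (1.0 - a_hat)
    return SF6Result(
        f_end=f_end, washed_out_volume=washed,
        eelv_sf6=washed / f_end, n_washin=0, n_washout=len(series),
    )


def measure_eelv_sf6(eelv_anatomic: float, weight_kg: float, vt_alv: float,
                     cfg: SF6Config | None = None,
                     rng: np.random.Generator | None = None
                     ) -> tuple[float, SF6Result]:
    """One complete wash-in + washout measurement, in ml·kg⁻¹.

    Optional multiplicative lognormal noise (``cfg.noise_cv``, applied
    when an ``rng`` is supplied) lumps the device's measurement error on
    the final volume; noiseless calls return
    ``eelv_anatomic/weight·1000`` exactly.
    """
    cfg = cfg or SF6Config()
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    washin = simulate_washin(eelv_anatomic, vt_alv, cfg)
    res = simulate_washout_and_compute(eelv_anatomic, vt_alv, float(washin[-1]), cfg)
    res = SF6Result(
        f_end=res.f_end, washed_out_volume=res.washed_out_volume,
        eelv_sf6=res.eelv_sf6, n_washin=len(washin), n_washout=res.n_washout,
    )
    value = res.eelv_sf6
    if rng is not None and cfg.noise_cv > 0:
        sigma = np.sqrt(np.log1p(cfg.noise_cv ** 2))
        value *= rng.lognormal(-0.5 * sigma * sigma, sigma)
    return value / weight_kg * 1000.0, res
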