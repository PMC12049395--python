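"""Breath-level signals: synthesis and volumetric-capnography analysis.

The study pipeline runs on per-breath aggregates (``BreathRecord``); this
module is the optional signal-fidelity layer.  It can synthesize airway
flow / CO2-fraction waveforms for a breath, segment a continuous stream
into breaths at flow zero-crossings, and recover the volumetric
capnography quantities (VTCO2, end-tidal alveolar CO2 fraction) that the
capnodynamic estimator consumes.

Conventions
-----------
* flow is in L·min⁻¹, positive during inspiration;
* CO2 fraction is dimensionless in [0, 0.15];
* VTCO2 is the expired CO2 volume of one breath in liters;
* FACO2 is the volume-weighted mean CO2 fraction over the last 15 % of
  expired volume (an end-tidal plateau proxy — the plateau estimator is a
  module convention, not a measured-device fact).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: default waveform sampling step, seconds
DEFAULT_STEP_S = 0.010

#: hysteresis band for flow zero-crossing detection, L·min⁻¹
FLOW_HYSTERESIS_LPM = 1.0

#: fraction of expired volume used for the end-tidal plateau estimate
PLATEAU_VOLUME_FRACTION = 0.15

FACO2_MAX = 0.15


class WaveformError(ValueError):
    """Invalid waveform specification or unanalyzable breath."""


@dataclass(frozen=True)
class BreathWaveform:
    """Uniformly sampled flow / CO2 signals of a single breath.

    Attributes
    ----------
    time : ndarray
        Seconds since breath start, strictly increasing, uniform step.
    flow : ndarray
        Airway flow, L·min⁻¹, positive = inspiration.
    co2_frac : ndarray
        CO2 fraction at the sensor, dimensionless.
    """

    time: np.ndarray
    flow: np.ndarray
    co2_frac: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.flow, dtype=float)
        c = np.asarray(self.co2_frac, dtype=float)
        if not (t.shape == f.shape == c.shape) or t.ndim != 1 or t.size < 2:
            raise WaveformError("time/flow/co2_frac must be equal-length 1-d arrays")
        dt = np.diff(t)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise WaveformError("time must be strictly increasing with uniform step")
        if np.any(c < -1e-12) or np.any(c > FACO2_MAX):
            raise WaveformError("co2_frac outside [0, 0.15]")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "flow", f)
        object.__setattr__(self, "co2_frac", c)

    @property
    def step_s(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def duration_s(self) -> float:
        return float(self.time.size * self.step_s)


@dataclass(frozen=True)
class BreathRecord:
    """Per-breath aggregate: the capnodynamic estimator's sole input.

    ``dt_min`` is the full breath cycle time in minutes; ``faco2`` is the
    end-expiratory alveolar CO2 fraction at the *end* of this breath.
    """

    index: int
    dt_min: float
    insp_s: float
    exp_s: float
    vtco2_l: float
    faco2: float
    phase: str = "normal"
    valid: bool = True
    reason: str = ""

    def validate(self, step_s: float = DEFAULT_STEP_S) -> None:
        if self.dt_min <= 0:
            raise ValueError("dt_min must be positive")
        if abs(self.dt_min * 60.0 - (self.insp_s + self.exp_s)) > step_s + 1e-9:
            raise ValueError("dt_min inconsistent with insp_s + exp_s")
        if self.vtco2_l < 0:
            raise ValueError("vtco2_l must be non-negative")
        if not (0.0 < self.faco2 < FACO2_MAX):
            raise ValueError("faco2 outside (0, 0.15)")


def waveform_to_csv(w: BreathWaveform, path) -> None:
    """Write a waveform stream as CSV with columns time_s, flow_lpm, co2_frac."""
    import pandas as pd

    pd.DataFrame(
        {"time_s": w.time, "flow_lpm": w.flow, "co2_frac": w.co2_frac}
    ).to_csv(path, index=False)


def waveform_from_csv(path) -> BreathWaveform:
    import pandas as pd

    df = pd.read_csv(path)
    return BreathWaveform(
        time=df["time_s"].to_numpy(),
        flow=df["flow_lpm"].to_numpy(),
        co2_frac=df["co2_frac"].to_numpy(),
    )


def synthesize_breath(
    faco2_target: float,
    *,
    tidal_volume: float,
    insp_s: float,
    exp_s: float,
    dead_space: float = 0.0,
    pause_s: float = 0.0,
    step_s: float = DEFAULT_STEP_S,
) -> BreathWaveform:
    """Build an idealized single-breath waveform.

    Square-wave flow (constant inspiratory / expiratory flow, optional
    zero-flow end-expiratory pause).  Expired CO2 rises from zero through
    a linear dead-space transition (centered on ``dead_space`` expired
    volume, width 0.6·dead_space) to a flat alveolar plateau at
    ``faco2_target``.  Discrete flow integrals are exact by construction:
    inspired volume equals expired volume equals ``tidal_volume``.
    """
    if tidal_volume <= 0 or step_s <= 0:
        raise WaveformError("tidal_volume and step_s must be positive")
    if insp_s <= 0 or exp_s <= 0 or pause_s < 0:
        raise WaveformError("breath timings must be positive")
    if not 0 <= dead_space < tidal_volume:
        raise WaveformError("need tidal_volume > dead_space >= 0")
    if not 0 <= faco2_target < FACO2_MAX:
        raise WaveformError("faco2_target outside [0, 0.15)")

    n_insp = max(int(round(insp_s / step_s)), 2)
    n_exp = max(int(round(exp_s / step_s)), 2)
    n_pause = int(round(pause_s / step_s))
    n = n_insp + n_exp + n_pause

    time = np.arange(n) * step_s
    flow = np.zeros(n)
    co2 = np.zeros(n)

    # constant flows chosen so the rectangle-rule integral is exactly VT
    flow[:n_insp] = tidal_volume / (n_insp * step_s) * 60.0
    flow[n_insp : n_insp + n_exp] = -tidal_volume / (n_exp * step_s) * 60.0

    # expired volume at each expiratory sample midpoint
    v_exp = tidal_volume * (np.arange(n_exp) + 0.5) / n_exp
    if dead_space == 0.0:
        co2_exp = np.full(n_exp, faco2_target)
    else:
        co2_exp = np.interp(
            v_exp, [0.7 * dead_space, 1.3 * dead_space], [0.0, faco2_target]
        )
    co2[n_insp : n_insp + n_exp] = co2_exp
    co2[n_insp + n_exp :] = faco2_target  # sensor dwells on alveolar gas in pause

    return BreathWaveform(time=time, flow=flow, co2_frac=co2)


def concatenate(waveforms: list[BreathWaveform]) -> BreathWaveform:
    """Join breath waveforms into one continuous stream (time restarted at 0)."""
    if not waveforms:
        raise WaveformError("nothing to concatenate")
    step = waveforms[0].step_s
    flow = np.concatenate([w.flow for w in waveforms])
    co2 = np.concatenate([w.co2_frac for w in waveforms])
    time = np.arange(flow.size) * step
    return BreathWaveform(time=time, flow=flow, co2_frac=co2)


def segment_breaths(
    stream: BreathWaveform, hysteresis_lpm: float = FLOW_HYSTERESIS_LPM
) -> list[BreathWaveform]:
    """Split a continuous stream into one waveform per breath.

    Boundaries sit at expiration→inspiration transitions of the flow
    signal, detected with a ±``hysteresis_lpm`` band to suppress chatter
    around zero flow.  The segments partition the stream: no samples are
    dropped or duplicated.  A stream with no qualifying transition (e.g.
    all-zero flow) yields an empty list and a warning.
    """
    flow = stream.flow
    state = None
    boundaries: list[int] = []
    for i, f in enumerate(flow):
        if f > hysteresis_lpm:
            if state == "exp":
                boundaries.append(i)
            state = "insp"
        elif f < -hysteresis_lpm:
            state = "exp"
    if state is None:
        warnings.warn("no flow activity above hysteresis band; no breaths found")
        logger.warning("segment_breaths: no zero crossings detected")
        return []

    edges = [0, *boundaries, flow.size]
    out = []
    for a, b in zip(edges[:-1], edges[1:]):
        if b > a:
            out.append(
                BreathWaveform(
                    time=np.arange(b - a) * stream.step_s,
                    flow=flow[a:b],
                    co2_frac=stream.co2_frac[a:b],
                )
            )
    return out


def analyze_breath(w: BreathWaveform, index: int = 0, phase: str = "normal") -> BreathRecord:
    """Volumetric capnography of one breath waveform.

    VTCO2 is the rectangle-rule integral of CO2 fraction times expired
    flow; FACO2 is the volume-weighted mean CO2 fraction over the last
    15 % of expired volume.  Breaths whose expiration is shorter than two
    samples, or whose recovered quantities violate the BreathRecord
    ranges, are returned flagged invalid rather than raising.
    """
    step = w.step_s
    exp_mask = w.flow < 0
    insp_s = float(np.count_nonzero(w.flow > 0) * step)
    exp_s = float(w.duration_s - insp_s)
    dt_min = w.duration_s / 60.0

    if np.count_nonzero(exp_mask) < 2:
        return BreathRecord(
            index=index, dt_min=dt_min, insp_s=insp_s, exp_s=exp_s,
            vtco2_l=0.0, faco2=0.0, phase=phase, valid=False,
            reason="expiration shorter than 2 samples",
        )

    dvol = np.abs(w.flow[exp_mask]) / 60.0 * step  # liters per sample
    co2 = w.co2_frac[exp_mask]
    vtco2 = float(np.sum(co2 * dvol))
    v_total = float(np.sum(dvol))

    # tail samples covering the last 15 % of expired volume
    rev_cum = np.cumsum(dvol[::-1])
    k = int(np.searchsorted(rev_cum, PLATEAU_VOLUME_FRACTION * v_total) + 1)
    k = min(k, dvol.size)
    faco2 = float(np.sum((co2 * dvol)[-k:]) / np.sum(dvol[-k:]))

    rec = BreathRecord(
        index=index, dt_min=dt_min, insp_s=insp_s, exp_s=exp_s,
        vtco2_l=vtco2, faco2=faco2, phase=phase,
    )
    try:
        rec.validate(step_s=step)
    except ValueError as exc:
        return BreathRecord(
            index=index, dt_min=dt_min, insp_s=insp_s, exp_s=exp_s,
            vtco2_l=vtco2, faco2=faco2, phase=phase, valid=False, reason=str(exc),
        )
    return rec
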