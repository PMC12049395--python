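# Methods

## The capnodynamic method

During mechanical ventilation, the CO₂ stored in the lung at end
expiration obeys a per-breath molar balance over the pulmonary
circulation:

```
EELV · (FACO₂ⁿ − FACO₂ⁿ⁻¹) = EPBF · Δtⁿ · (CvCO₂ − CcCO₂ⁿ) − VTCO₂ⁿ
```

where EELV (L) is the CO₂-containing end-expiratory lung volume, FACO₂ⁿ
the end-expiratory alveolar CO₂ fraction of breath *n*, EPBF (L·min⁻¹)
the effective (non-shunted) pulmonary blood flow, Δtⁿ (min) the breath
cycle time, CvCO₂ and CcCO₂ⁿ the mixed-venous and lung-capillary CO₂
contents (L gas per L blood), and VTCO₂ⁿ (L) the CO₂ volume eliminated
by the breath.  FACO₂, VTCO₂ and Δt are measured by volumetric
capnography; CcCO₂ is computed from FACO₂ and hemoglobin through a CO₂
dissociation model.

With the substitution x₃ = EPBF·CvCO₂ the balance is linear in
(EELV, EPBF, x₃).  Each breath n ≥ 2 of a window contributes one row

```
[FACO₂ⁿ − FACO₂ⁿ⁻¹,   Δtⁿ·CcCO₂ⁿ,   −Δtⁿ] · (EELV, EPBF, x₃)ᵀ = −VTCO₂ⁿ
```

and ordinary least squares over a sliding window solves for the triple;
this is the standard linearization — the clinical implementation's
solver is proprietary and undisclosed.  Under steady ventilation the
system is rank-deficient (all rows proportional), so the ventilation
pattern forces identifiability: six breaths at I:E 1:2 are followed by
three breaths with a 2.5 s end-expiratory pause, cyclically.  The pause
breaths lengthen Δt, raising FACO₂ a few breaths per cycle, and the
induced excursion separates the three columns (window condition number
≈ 10²).  The default window is one full 9-breath cycle, advanced one
breath at a time.

Window quality flags: alveolar-fraction excursion below `1e-4`
("unidentifiable"), condition number above `1e8`, relative residual
above 0.25 (about 30× the measurement-noise floor; gross model
violation), or non-positive volume/flow.  Flagged windows are never
discarded silently — they carry the last valid values forward and stay
marked, which mirrors a monitor that keeps displaying its last reliable
reading.  A step's reported value is the mean of valid estimates over
the step's final pattern cycle; one "recording" elsewhere (e.g. the
precision repeats) uses the same convention.

### Numerical conventions

The balance needs a convention for which breath's FACO₂ defines CcCO₂ⁿ.
This package evaluates CcCO₂ⁿ at the **current** end-expiratory fraction
FACO₂ⁿ, in both the simulator and the estimator.  Because the
dissociation model is linear in PCO₂, the per-breath update then has an
exact closed form

```
FACO₂ⁿ = (EELV·FACO₂ⁿ⁻¹ + EPBF·Δtⁿ·CvCO₂ − VTCO₂ⁿ) / (EELV + EPBF·Δtⁿ·κ)
```

(κ = dCcCO₂/dFACO₂) which is unconditionally stable.  The alternative —
evaluating CcCO₂ⁿ at the previous fraction — makes the forward map
explicit with per-breath amplification (EPBF·Δt·κ + VT_alv)/EELV ≈ 2.6
at physiologic porcine values, i.e. divergent; it is not usable as a
ground-truth generator.  VTCO₂ⁿ = (VT − VD)·FACO₂ⁿ⁻¹: the expired gas
left the alveoli before the breath's new equilibrium.  Either way the
emitted (Δt, VTCO₂, FACO₂) triples satisfy the balance *exactly* with
the true parameters, so noiseless streams are identifiable to machine
precision (measured ≈ 4·10⁻¹⁴ relative) rather than up to a
discretization error.

The simulator and the estimator deliberately share one dissociation
function (an "inverse crime"): the validation isolates the inversion,
noise propagation and protocol dynamics, not dissociation-model error.
The estimator's `cc_scale` parameter can break the match on purpose to
study sensitivity to a mis-specified dissociation slope.

## Blood CO₂ content

`co2_content` implements the Douglas–Jones–Reed (1988) whole-blood CO₂
model: plasma content S·PCO₂·(1 + 10^(pH−pK′)) with solubility S and
apparent pK′ polynomial in temperature and pH, corrected to whole blood
by 1 − 0.0289·Hb / ((3.352 − 0.456·SO₂)(8.142 − pH)) (Hb in g·dL⁻¹),
converted to L gas·L blood⁻¹ with the CO₂ molar volume 22.263 L·mol⁻¹.
Capillary SO₂ is fixed at 1.0 and pH at 7.40 unless configured — the
blood-gas inputs actually used by the clinical device are not public.
Inputs outside PCO₂ ∈ (0, 30] kPa or pH ∈ [6.8, 7.8] raise.

## The virtual subject

A single well-mixed alveolar compartment (volume `eelv_true`) plus a
one-compartment venous CO₂ store:

```
dCvCO₂/dt = [VCO₂_met − EPBF·(CvCO₂ − CcCO₂)] / V_store
```

integrated explicitly per breath; the fixed point CvCO₂ = CcCO₂ +
VCO₂_met/EPBF is the Fick relation.  Defaults (a 24 kg piglet):

| parameter | default | rationale |
|---|---|---|
| weight | 24 kg | study group mean |
| tidal volume | 10 ml·kg⁻¹ | ventilator setting of the study |
| airway dead space | 2.1 ml·kg⁻¹ | porcine anatomical value |
| respiratory rate (normal breaths) | 20 min⁻¹ | gives FACO₂ ≈ 0.06 at the metabolic rate below |
| expiratory pause (extended breaths) | 2.5 s | middle of the stated 2–3 s range |
| eelv_true | 24 ml·kg⁻¹ | CO₂-containing volume; matches the tested method's reported absolute values |
| eelv_anatomic | eelv_true − 5.5 ml·kg⁻¹ | airway volume up to the sensor plus dissolved CO₂ are *inside* eelv_true; the SF₆-visible volume excludes them, reproducing the systematic positive bias by construction |
| EPBF (baseline) | 3.0 L·min⁻¹ | non-shunted flow of a 24 kg piglet |
| VCO₂ (metabolic) | 7.5 ml·kg⁻¹·min⁻¹ | reproduces the measured ≈ 180 ml·min⁻¹ |
| Hb | 100 g·L⁻¹ | porcine normal |
| V_store | 20 L | effective venous/tissue CO₂ capacitance; body CO₂ stores are large, giving multi-minute equilibration time constants (V_store/EPBF ≈ 7–19 min across protocol steps) |
| shunt | 0.10 | baseline porcine shunt |
| noise CVs (FACO₂, VTCO₂) | 0.0016 | calibrated so six-repeat EELV-CO₂ precision ≈ ±8 % (see below) |

### Hypoxic pulmonary vasoconstriction and iNO

PaO₂ is piecewise-linear in FiO₂ through the measured group-mean
anchors (FiO₂ 1.0 → 63.2 kPa, 0.5 → 29.8, 0.21 → 10.9, 0.16 → 6.5).
PVR = PVR₀·(1 + k·g·s(PaO₂)) with a piecewise-linear saturating hypoxic
stimulus s anchored to the measured PVR ratios (zero above 45 kPa,
saturating below 6.5 kPa), per-subject gain g, and iNO factor
k = 1 − η·min(iNO/20 ppm, 1).  η ≈ 0.614 is calibrated so 20 ppm iNO at
FiO₂ 0.16 returns PVR from 6.8 to the measured 4.1 Woods units.  EPBF =
ΔP₀/PVR·(1 − shunt): flow falls as PVR rises under a constant driving
pressure.  Between-anchor behavior is an interpolation choice; only
step means were measured.

### Protocol dynamics

The 7 steps (FiO₂ 1.0 / 0.5 / 0.21 / 0.16 / 0.16+iNO / 0.21+iNO /
1.0+iNO) run 11 pattern cycles each, except: step 4 runs 18 cycles (in
vivo, PVR doubling was approached by successive FiO₂ reductions roughly
every 10 minutes) and step 5 runs 2 cycles (iNO acts within seconds and
its paired recording followed directly).  Each transition ramps
PaO₂/PVR/EPBF linearly over 9 breaths (gas mixing and drug wash-in are
fast but not instantaneous; the first baseline step starts at its
steady state).

Two stochastic physiologic elements produce the transient disagreement
seen in vivo after iNO:

* **Vasomotor flow instability** — breath-to-breath fluctuation of true
  EPBF, a stationary mean-one lognormal AR(1) (ρ = 0.8) whose CV is
  step-dependent: 0.01 at baseline, rising through hypoxia (0.035–0.05)
  to 0.12 immediately after iNO abruptly releases active
  vasoconstriction, then subsiding (0.035, 0.02).  Fluctuating flow
  violates the estimator's constant-parameter window assumption and is
  exactly the mechanism the in-vivo study invokes (sudden changes in
  pulmonary blood flow and CO₂ washout, a VCO₂ spike after iNO).
* **Per-subject heterogeneity** — each subject draws a vasomotor
  "lability" factor (1.0 ± 0.25), an iNO response ramp of 3–12 breaths,
  and all physiologic parameters from truncated normal distributions
  whose means are the study's group means.

With these conditions the synthetic study lands where the in-vivo study
did: pooled bias ≈ +5 to +6 ml·kg⁻¹, pooled limits ≈ −2…+13 ml·kg⁻¹,
pooled MPE ≈ 32–41 %, per-step MPE maximal at the iNO step (≈ 50–75 %)
and returning toward baseline afterwards.  These figures are emergent —
none of them is assigned anywhere.

Measurement noise is multiplicative mean-one lognormal on the emitted
FACO₂ and VTCO₂ only (it never feeds back into the hidden state),
independent across breaths.  The breath-level CV of 0.0016 looks small,
but the window inversion amplifies it ≈ 50-fold; it was calibrated once
so that the six-repeat precision of the EELV-CO₂ recording is ≈ ±8 %
(Monte-Carlo mean 8.4 %), the precision the in-vivo study reports for
both methods.  A single six-repeat CV estimate has χ²₅ sampling spread
(SD ≈ 3.5 points), so precision checks average replicate sessions.

## SF₆ wash-in/washout reference

Single-compartment tidal mixing with dilution factor
a = EELV/(EELV + VT_alv): wash-in F_k = a·F_{k−1} + (1−a)·F_insp
(terminating within 1 % of the inspired fraction, default 0.005);
washout F_k = aᵏ·F_end, truncated when the end-tidal fraction falls
below F_end/40 with the geometric tail added analytically from the
observed decay ratio.  The recovered tracer volume is EELV·F_end
exactly, so EELV-SF₆ = washed-out volume / F_end is unbiased and
independent of tidal volume — the idealized reference the design needs
(in vivo, EELV-SF₆ stayed essentially constant throughout the
protocol).  SF₆ is inert and insoluble, so it sees only the anatomical
gas volume; measurement error is lumped as one multiplicative lognormal
on the final volume (CV 0.08/1.96 ≈ 4.08 %, i.e. six-repeat precision
≈ ±8 %).  Ventilation inhomogeneity and the dispensing hardware are not
modelled.

## Agreement statistics

* **Precision** = 1.96 × CV of ≥ 2 (study: six) repeated measurements;
  sample SD with n−1.
* **Repeated-measures Bland-Altman** ("multiple observations per
  individual, true value varies"): one-way ANOVA of the inter-method
  differences by subject; SD²_diff = max(0, (MSB − MSW)/m₀) + MSW with
  the standard averaged group size m₀; limits = bias ± 1.96·SD_diff.
  SE(bias) uses the between-subject mean square (differences within a
  subject are correlated); SE(limit) = √3·SE(bias); CIs are normal
  (±1.96·SE).  With one pair per subject everything reduces exactly to
  the classic analysis.  The cited statistical references do not name
  the exact variant used in vivo; this decomposition is the standard
  one for a 7-condition × 10-subject design.
* **Mean percentage error** (Critchley) = 1.96·SD_diff / mean of the
  reference method, computed as half the limit range over the reference
  mean; < 30 % is the conventional interchangeability bound.  Limits
  are treated as an unordered pair (published tables occasionally swap
  the labels).  For the pooled table the reference mean is ambiguous
  (grand mean over 70 points vs mean of step means); both are reported.

## What the synthetic data do and do not show

The generator emulates breath tables whose noiseless core is *exactly*
the model the estimator inverts, plus calibrated measurement noise and
physiologic instability.  Passing tests therefore demonstrate the
correctness of the inversion, the statistics, and the qualitative
protocol phenomenology — not robustness to real-world deviations:
dissociation-model error (available via `cc_scale`, off by default),
ventilation inhomogeneity, capnogram phase-III slope, sensor drift,
atelectasis-driven EELV loss, and anaerobic metabolism are all outside
the simulator.  The in-vivo headline numbers (bias +5, limits −1…+11,
MPE 34 %) depend on real animals and are reproduced here only in the
sense that the calibrated synthetic study lands in the same range.

## Problem sizes

The default study (10 subjects × 7 steps, ≈ 80 pattern cycles per
subject, ≈ 8 000 breaths and ≈ 7 600 sliding windows in total) runs in
about two seconds on one CPU; the statistics recovery check uses 500
replications of the 10 × 7 design; precision checks average 30
six-repeat sessions.
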