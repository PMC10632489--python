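# Methods

## Pipeline

`petdose` computes internal radiation dose from organ time–activity
curves (TACs) in four stages.

**1. TAC representation and decay handling.** A whole-body dynamic PET
protocol acquires a handful of multi-minute passes separated by rest
gaps; two clinical schedules are built in (seven passes 0–120 min and
five passes 0–114 min). Each frame is reduced to a single sample at its
temporal midpoint and the TAC is treated as a point series — frame
durations enter only through the midpoint, not as weights, because the
sparse pass structure gives no information about intra-frame shape.
Dosimetry integrates the *decay-uncorrected* TAC (the activity
physically present); curves stored decay-corrected are converted by
multiplying each sample at midpoint *t* by exp(−λt), with the reference
time at injection. The conversion refuses already-uncorrected input: a
silent second application would bias every downstream dose low.

**2. Cumulated activity and residence times.** The cumulated activity is
a trapezoidal integral over the observed window plus an analytic tail:

- *Leading segment* (injection to first midpoint t₁): three conventions
  are supported because published pipelines do not state theirs.
  `ramp` (default) integrates a linear rise from zero activity at
  injection — exact to O(t₁³) for any kinetics with A(0)=0, which is
  physically the case for an organ that starts empty. `flat`
  back-extrapolates the first sample as a constant — the consistent
  choice when activity at injection is *not* zero (e.g. a
  mono-exponential test curve), where the ramp would introduce a
  first-order error of ½·A(0)·t₁. `none` starts the integral at t₁.
- *Tail* (last midpoint to infinity): `physical_decay` (default)
  assumes the last observed activity decays at the isotope's physical
  rate, giving A_last/λ. For any organ whose biological clearance is
  non-negative this is an upper bound on the true remaining integral
  once uptake is complete, so residence times err conservative.
  `exponential_fit(k)` instead fits log-linear least squares through
  the last k samples (default 3) and uses A_last/λ_fit; λ_fit is
  floored at the physical λ (an organ cannot clear slower than physical
  decay) and a non-positive fitted rate falls back to physical decay
  with a warning.

Residence times are τ = Ã/ID. The remainder of body is assigned by
closure, τ_rem = T½/ln2 − Στ, with T½(F-18) = 109.77 min so that
T½/ln2 = 2.6394 h (printed as 2.64 at two decimals). A summed source τ
exceeding the budget raises rather than clamping: it signals
overlapping VOIs or a broken tail, not a rounding issue. Closure is
applied per subject; tables of *averaged* rounded residence times need
not close, which is why published cohort-mean tables can appear
inconsistent with the 2.64 constant.

Negative activities are rejected at parse time rather than clamped —
silent clamping hides VOI delineation errors.

**3. MIRD doses and ICRP weighting.** D_k = Σ_h τ_h·S(k←h) with
S-values in mGy/(MBq·h); doses are reported ×1000 as μGy/MBq, which at
w_R = 1 (photons/positrons) is numerically μSv/MBq. The remainder term
is an ordinary source named `remainder` that must have its own column
in the S-table, mirroring how phantom dose software folds it in.
S-tables may carry per-entry provenance (absorbed fractions φᵢ,
equilibrium dose constants Δᵢ, target mass); when present the stored S
is validated against Σφᵢ·Δᵢ/m to 1e-9 relative. Real phantom S-values
are not bundled (they are proprietary-format phantom data); the
schema accepts user-supplied CSV tables, and tests use seeded synthetic
matrices with self-dose dominance S(k←k) ≥ 10·max cross term, labelled
synthetic.

Two weighting schemes are built in with their published values:
ICRP 103 (bladder 0.04, brain 0.01, gonads 0.08, …) and ICRP 60
(bladder 0.05, gonads 0.20, …), each summing to 1 to 1e-6. Some
clinical reports quote looser lists (e.g. brain or kidney at 0.12)
that matches neither publication; the package encodes only the
published ICRP values. Weighted tissues with no matching dose entry
contribute zero with a warning — unavoidable when the S-table is
restricted to the delineated source organs — so effective doses
computed from a source-organ-only table are lower bounds with respect
to tissue coverage.

**4. Compliance and method comparison.** The administered effective
dose E·ID/1000 mSv is checked against 30 mSv/administration and
50 mSv/year with a strict-exceed rule (exactly at the limit passes).
Two pipeline presets are defined — `conventional` (ramp leading
segment, physical tail) and `pmod` (no leading segment, physical tail) —
and the comparison module computes per-organ percent differences
*per subject first*, then averages within sex strata; computing
differences on averaged tables conflates between-subject variance with
method disagreement. Conventions: `rel_first` = (a−b)/a·100 (signed,
relative to the reference method, default) and `rel_mean` =
|a−b|/((a+b)/2)·100 (symmetric). A zero denominator yields NaN, not an
exception, and NaNs are excluded from stratum means so an organ with
zero uptake does not poison the report. Descriptive statistics only
(mean ± sample SD, n per stratum); no inferential tests.

## Synthetic subjects

The generator emulates the two excretion phenotypes visible in
whole-body ¹⁸F images — hepatobiliary retention and renal accumulation —
with per-organ kinetics whose decay-uncorrected activity is

- washout: `ID·f·k_u/(k_u−k_c)·(e^(−k_c t) − e^(−k_u t))·e^(−λt)`
- accumulation: `ID·f·(1 − e^(−k_u t))·e^(−λt)`

(f = fraction of injected activity routed through the organ, k_u uptake
and k_c clearance rates in h⁻¹). Both integrate in closed form, so every
simulated organ carries an exact residence time and the remainder truth
T½/ln2 − Στ_true is well defined (Σf ≤ 1 in both presets).

Preset constants are fixed, documented values chosen under two
constraints: (i) the τ rank ordering follows the clinical pattern
(liver ≫ lungs > brain for hepatobiliary; bladder ≫ liver for renal),
with no claim of quantitative match to any cohort; (ii) every organ is
either a pure retention compartment (k_c = 0, k_u ≥ 3 h⁻¹ — trapped,
cleared by physical decay only) or a fast-washout compartment
(k_c ≥ 4 h⁻¹, essentially cleared within the 2 h window). Constraint
(ii) is what makes the physical-decay tail accurate for every organ: an
intermediate biological clearance (say k_c ≈ 0.2 h⁻¹) leaves a large
remaining integral at 2 h that the physical tail overestimates by
~λ/(k_c+λ) regardless of how densely the window is sampled, so no
schedule refinement could bring those organs near the analytic truth.
With the presets as shipped, the worst per-organ recovery error is
≈4.2 % on the sparse five-pass clinical schedule and ≈0.5 % on a dense
50-frame schedule (both recomputed by `scripts/acceptance.py`).

Noise is multiplicative lognormal per frame with a user-set CV
(default studies here use CV = 0.1, a realistic organ-VOI level for
whole-body PET), using the *mean-preserving* parameterisation
exp(σZ − σ²/2), σ² = ln(1+CV²). Residence-time estimates are linear in
the sampled activities, so a mean-one multiplier keeps them unbiased;
the median-preserving alternative would inflate every τ by
exp(σ²/2) ≈ 1 + CV²/2 — a systematic ~0.5 % bias at CV = 0.1 that is
detectable across 100 seeds and would masquerade as a pipeline defect.
Identical seeds reproduce subjects bit for bit.

What the generator does *not* emulate: plasma input functions and
compartmental exchange, bladder voiding (bladder content is assumed
retained, matching the constant-volume assumption of the clinical
protocols), partial-volume and motion effects, count-rate–dependent
noise, and inter-subject biological variability beyond the noise seed.
Passing tests therefore demonstrate the *integration and bookkeeping*
machinery — AUC, tails, closure, dose algebra — not the fidelity of any
kinetic model to real tracers, and absolute dose values from the
synthetic S-tables have no clinical meaning.

## Numerical choices and degenerate inputs

- Canonical units: minutes for schedules, hours for residence times,
  MBq for activity, mGy/(MBq·h) for S-values; conversions are
  centralized in the containers.
- λ is always derived from the stored half-life (never stored
  separately), so λ·T½ = ln2 holds to machine precision.
- A single-sample TAC is integrable: the window reduces to the leading
  segment and the tail starts at that sample. An all-zero TAC gives
  τ = 0 exactly (zero tail, no fit attempted).
- The trapezoid requires strictly increasing times and ≥ 2 samples; the
  exponential tail fit requires ≥ 2 strictly positive recent samples
  and otherwise falls back to physical decay with a warning.
- Remainder closure tolerates −1e-9·budget of floating-point slack and
  clamps to zero; anything beyond raises.
- The closure invariant Στ + τ_rem = T½/ln2 holds by construction and
  is asserted to 1e-9 h in tests and in the pipeline run log.
- Organ/tissue name matching is case- and punctuation-insensitive with
  a small alias table (lungs↔lung, urinary bladder wall↔urinary
  bladder, heart wall↔heart, …).

## Problem sizes

Validation studies run at the scale the science needs and no larger:
conservation is checked over 100 noisy subjects per phenotype,
convergence on 25/50/100-frame schedules, unbiasedness over 100 seeds,
cohorts of 6 subjects (3 per sex) for the method comparison — mirroring
the size of a typical first-in-human dosimetry cohort.

## Known limitations

- The effective dose from a source-organ-only S-table omits tissues
  that a full phantom would dose (warned at run time); supply a full
  phantom S-table for regulatory-grade numbers.
- The exponential tail fit uses the last k samples unweighted on the
  log scale; with k = 3 and noisy data the fitted rate is volatile, and
  the physical-λ floor is what keeps the tail bounded.
- Closure assigns *all* unaccounted decays to the remainder; organs
  outside the imaging field of view are indistinguishable from
  remainder tissue.
- No bladder-voiding model: residence times for renal tracers are
  conservative (upper bounds) with respect to voiding.
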