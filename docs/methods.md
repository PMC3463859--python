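# Methods

## Model

Aβ level in a compartment (brain interstitium or CSF; analytes Aβ40/Aβ42)
is modeled as an indirect-response turnover system on the
percent-of-vehicle scale:

    dA/dt = Kin · (1 − Imax · C(t)^γ / (IC50^γ + C(t)^γ)) − kout · A,  A(0) = 100

Assumptions: Aβ generation is zero-order and is the only process the drug
touches (BACE and γ-secretase act on production, not clearance); clearance
is first-order; the compartments are homeostatically independent (no
brain→CSF transit is modeled — each compartment is fit on its own, so
cross-compartment transport is absorbed into each compartment's apparent
kout); baseline is stationary (no circadian or tolerance dynamics). The
drive C(t) is whatever concentration was measured or assumed — plasma,
brain, or CSF — and is supplied by the caller; IC50 inherits its units.

Working on the normalized scale makes `Kin = 100·kout` an identity rather
than a parameter, which is why the model never simulates absolute Aβ:
absolute baselines cancel in the percent-of-concurrent-vehicle transform.

Derived quantities: `Rgen(C) = 1 − Imax·C^γ/(IC50^γ+C^γ)` (the intrinsic
exposure–response curve, independent of PK and of kout), the washout
offset half-time `ln 2 / kout`, and the periodic steady-state identity
⟨A⟩ = 100·⟨Rgen⟩ over one dosing interval (integrate the ODE over a
period at steady state; the net change is zero).

## Parameters

| parameter | units | meaning | default handling |
|---|---|---|---|
| kout | 1/h | fractional turnover (clearance) rate | estimated; log-transformed |
| Imax | – | maximal fractional inhibition of generation, ∈ (0, 1] | estimated (logit) or fixed at 1 for full inhibitors |
| IC50 | drive units | concentration at half-maximal inhibition | estimated; log-transformed |
| γ | – | Hill steepness | free by default, commonly fixed at 1 |

Reference values used throughout the test bed: mouse CSF Aβ40
kout = 1.42/h, mouse brain Aβ42 kout = 0.49/h (≈ threefold slower), and
the cross-species CSF Aβ40 law kout = 0.415 · BW^−0.36 (BW in kg).
Extrapolating the law to a 25 g mouse gives 1.57/h, close to but not equal
to the directly estimated 1.42/h; the package reports both and does not
force agreement.

## Numerics

Two integration paths solve the same ODE:

* **lsoda** (default): `scipy.integrate.solve_ivp` with LSODA,
  rtol 1e−8 / atol 1e−10, drive evaluated continuously, and a maximum step
  of span/200 (capped at 1 h floor of 1e−3 h) so short drive transients
  are not stepped over. Verified against the constant-drive closed form
  `A(t) = 100(1−I) + 100·I·e^(−kout·t)` to ≤1e−6 relative error across a
  100-case random parameter grid.
* **expstep**: the ODE is linear in A given the drive, so an exact
  per-step propagator with trapezoidal treatment of the forcing
  (exponential time differencing, order 2 in the forcing quadrature) runs
  on a uniform grid (default dt = 0.02 h; the recurrence is a first-order
  IIR filter evaluated in C via `scipy.signal.lfilter`). Output times off
  the grid get one exact partial step, not linear interpolation. This path
  is ~100× faster than LSODA and is the default inside estimation and
  bootstrap loops; it agrees with the closed form to ~1e−9 at dt = 0.02.

Periodic steady state is declared when the trajectory over successive
periods changes by < 0.01 percentage points everywhere (cap 200 periods);
the period average uses the trapezoid rule on a 4001-point grid.

The Hill term is computed as `Imax · (x/(1+x))` with `x = (C/IC50)^γ` so
overflow at extreme concentrations saturates cleanly at Imax and roundoff
cannot push the inhibition above Imax.

## Estimation

Naive pooled nonlinear least squares: every normalized observation
(vehicle records included — they carry residual-variance information and
predict exactly 100) is treated as independent, and all dose groups are
fit simultaneously. Destructive sampling yields one observation per
animal, so there is no within-animal structure for a mixed model to use.
Residuals are on the percent scale by default; a log-percent option exists
for data whose noise is clearly multiplicative.

Free parameters are transformed — log(kout), log(IC50), log(γ),
logit(Imax) — so box bounds are respected smoothly; `lmfit` with the
trust-region-reflective `least_squares` backend minimizes the residual.
Five jittered restarts (N(0, 0.3²) on the transformed scale, deterministic
sub-seeds) guard against local minima; near-tied optima (< 1% in SSR) with
parameter disagreement > 10% raise a multimodality flag. Standard errors
come from the Jacobian at the optimum and are mapped back to the natural
scale by the delta method; 95% CIs are transformed from the internal
scale, so they respect positivity and the Imax ≤ 1 cap. Estimates pinned
at bounds and optimizer non-convergence are flagged in the result status,
and predictions from non-converged fits are refused unless forced.

Identifiability guards: a dataset with no treated records, or a single
treated sampling time while kout is free, raises an error rather than
returning a flat-likelihood answer. Single-time-point dose–response
designs are thereby surfaced as degenerate instead of silently producing
arbitrary kinetic parameters.

### Bootstrap

Case-resampling over animals within (dose, compartment, analyte) groups,
re-normalizing each resample so vehicle variability propagates, refitting
from the point estimate (single start), and taking percentile intervals.
The stratum is the dose group rather than the dose × time cell: animals in
a dose group are exchangeable before their terminal-time assignment, and
resampling within cells of ~4 animals makes the bootstrap distribution
systematically too narrow (measured bootstrap SD ≈ 0.74× the true sampling
SD on synthetic replicates, 90% intervals covering ≈ 78%); dose-level
resampling restores coverage to ≈ 89–91% in the operating-characteristics
study. Resamples that lose all treated records or a concurrent vehicle
stratum are redrawn.

## Synthetic studies

The generator emulates destructive-sampling rodent studies: per-time-point
concurrent vehicle groups, a dose ladder, one terminal observation per
animal per measured (compartment, analyte) stratum. Each animal draws a
mean-preserving lognormal baseline (default between-animal CV 20% — a
placeholder for unpublished study magnitudes), the model supplies its
percent-of-control at its sampling time, multiplicative lognormal assay
noise (and an optional additive floor) is applied, and the emitted value
is absolute (baseline × pct/100). A repeated-sampling mode reuses animals
across times with a shared baseline to emulate serial CSF sampling in
large species. A master seed spawns per-animal sub-streams keyed by
(dose, time index, animal index), so extending a design with a new dose
group leaves existing animals' draws untouched.

What the generator does *not* emulate: assay matrix effects, LLOQ
censoring beyond the additive floor, transgenic overexpression kinetics,
circadian baseline drift, and any brain↔CSF transport coupling. Passing
tests therefore demonstrate that the estimation machinery is correct and
well-calibrated *under the model's own assumptions*, not that the model is
adequate for any particular real dataset.

### Reference study conditions

The recovery and operating-characteristics studies
(`abeta_pkpd.studies`) use a washout-informative mouse time-course
design: subcutaneous-like one-compartment PK with ka = 3/h, ke = 1/h
(drug gone within ~5 h so the offset phase reveals turnover), sampling at
0.5, 1, 2, 3, 5, 8, 12 h, doses 1/3/10 units spanning ~0.5–10× the
IC50 of 0.5, 4 animals per dose × time cell, full inhibition
(Imax = 1, γ = 1). Noise in the stochastic study is a single 10%
multiplicative lognormal error per observation: under destructive
sampling, between-animal baseline spread and assay error are
indistinguishable and compound into one per-record factor, so the stated
10% is the total. The noiseless recovery studies free all four
parameters; the stochastic study fixes Imax and γ at the full-inhibitor
configuration and estimates kout and IC50, with 100 replicates and 100
bootstrap resamples per replicate — sizes chosen to keep the whole
reference suite in the minutes range on one CPU.

## Workflow conventions

* Hysteresis loops are summarized on the (concentration, % lowering)
  plane: points ordered by time, polygon closed, shoelace signed area.
  The indirect-response delay traverses the loop counterclockwise
  (positive area); |area| below 1e−9 × (range product) reports "none".
  The lag is effect-nadir time minus drive-peak time.
* Intrinsic-curve comparison evaluates Rgen on a 200-point log-spaced
  grid from IC50/100 of the smallest-IC50 fit to 100× the largest, and
  restricts differences to grid points inside every curve's own 0–50%
  lowering band (Rgen ∈ [0.5, 1]), the region where preclinical data are
  informative; disjoint bands are flagged rather than silently compared.
* Prediction of a new regimen is simulation under the fitted parameters —
  no refitting — which is exactly the model's claim to extrapolation.

## Known limitations

* Pooled fitting understates uncertainty when animals contribute repeated
  measures (the non-destructive mode); a mixed-effects layer is out of
  scope.
* The bootstrap's dose-level exchangeability argument weakens for designs
  where treatment-time cells differ systematically in n.
* Percentile intervals remain slightly liberal (~89% observed for a
  nominal 90%) at n = 4 animals/cell; BCa or studentized intervals would
  cost a jackknife per replicate and are not implemented.
* Allometric scaling is implemented for the system parameter kout only;
  compound potency (IC50, Imax, γ) does not scale with body weight and
  must come from fits or in vitro data.
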