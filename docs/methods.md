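# Methods

This note documents the models behind `ampersense`, the choices made
where the underlying methods leave room, and what the synthetic-data
generators do and do not emulate.

## Units and conventions

Internally everything is in A, V, s, cm and mol/cm³ — the convention
under which the Randles–Sevcik prefactor takes its textbook value
2.69×10⁵ at 298.15 K.  User-facing I/O (µA, mV/s, mM, mL, µL) is
converted at the boundary (`ampersense.io`).  Anodic (oxidative) current
is positive.  Physical constants live in one place:
F = 96 485 C/mol, R = 8.314 J/(mol·K).

## Cyclic-voltammetry simulator

One-step, one-electron redox couple `R ⇌ O + e⁻` with semi-infinite
planar diffusion and a Butler–Volmer surface condition:

    J_red = k_red·C_O(0) − k_ox·C_R(0)
    k_red = k⁰ exp(−α f η),  k_ox = k⁰ exp((1−α) f η),  f = nF/RT, η = E − E⁰'

and faradaic current i = nFA·(k_ox C_R(0) − k_red C_O(0)).  The bulk
initially contains only the species consumed on the forward sweep.
Assumptions: no migration or convection, no double-layer charging, no
iR drop, single couple, planar 1-D geometry.

**Discretization.** Finite volumes on a geometrically expanding grid:
the first cell width resolves the sweep-scale diffusion layer
δ = √(D·RT/(nFv)) with ≈ n_space/7.5 cells (≈ δ/20 at the default
n_space = 150), and widths grow so that n_space cells span
6·√(D·t_total).  A uniform grid over the same domain would place only a
couple of nodes inside δ at 100 mV/s, which is why the expanding grid is
used.  Time stepping is Crank–Nicolson for diffusion; the surface
reaction is taken fully implicit at the mid-step potential because the
Butler–Volmer rates are stiff at large k⁰ and a trapezoidal reaction
term rings at ±1 amplification.  The Butler–Volmer condition is imposed
at the wall, half a cell from the first cell centre: eliminating the
wall concentrations through the quasi-steady flux balance rescales both
rate constants by 1/(1 + (w₀/2)(k_red/D_O + k_ox/D_R)), which restores
second-order surface accuracy and bounds the boundary stiffness.  An
explicit scheme is provided for cross-checks and refuses to run when
λ = D·Δt/Δx² > 0.5, naming the violated criterion.

**Verification.** At the defaults (n_space = 150, n_time = 2400 per
sweep) the reversible limit (k⁰ = 1 cm/s) reproduces the Randles–Sevcik
peak current to 0.1% and ΔEp = 60.2 mV (theory ≈ 57–59 mV for a far
switching potential); halving Δx and Δt moves the peak current by
< 0.1%.  Total dissolved material is conserved to machine precision by
construction (the finite-volume fluxes telescope and the surface
reaction converts O↔R 1:1); the realized drift is recorded in the trace
metadata.  Peak positions are refined below the potential step by a
local quadratic fit around the discrete extremum.

A note on the "fully blocked" limit: because the rates grow as
exp(α f η), a nominally tiny k⁰ still turns over at large overpotential
— at k⁰ = 10⁻⁹ cm/s the ±1 V program shows the shifted irreversible
peak at ≈ 79% of the reversible height (the theoretical
0.496·√α/0.4463 ratio).  Currents below 1% of the reversible peak
require k⁰ ≲ 10⁻¹⁵ cm/s over this window.

## Peak extraction and surface area

Each branch of the sweep gets a linear baseline fitted on its leading
20% (configurable); the peak is the interior extremum of the corrected
current and must exceed 3× the baseline residual SD, otherwise
`NoPeakFound` is raised (mirroring real traces where a peak is not
discernable).  Ties break to the earliest sample.  The ESA comes from
the least-squares line of |i_p| vs √v (≥ 3 rates), intercept retained to
absorb capacitive offsets, slope inverted through the Randles–Sevcik
coefficient evaluated at the cell temperature.  Following the field's
loose usage this i_p-vs-√v plot is called a "Cottrell plot" even though
the classical Cottrell plot is i vs t^(−1/2).  The anodic branch is the
default; the cathodic branch is supported (and recorded in the result)
for electrodes whose oxidation peaks vanish at high scan rates.

**Known bias.** The inversion assumes a reversible peak.  For
quasi-reversible kinetics the simulated peak currents are attenuated by
3–19% over k⁰ ∈ [10⁻³, 10⁻²] cm/s at 25–100 mV/s, and the recovered
area inherits that bias (8–22% low on the synthetic sets), while the
same pipeline on a reversible couple recovers the area to < 1%.  This
is a property of the method, not of the extraction.

## Electron-transfer kinetics

ψ follows the paper-standard form ψ = γ^α·k⁰·(π·a·D_O)^(−1/2) with
γ = D_O/D_R (γ = 1 by default; the value is configurable because the
diffusion asymmetry of a real couple is rarely known).  Two routes map
ΔEp → ψ:

* **Rational working-curve fit** for 59 mV < n·ΔEp ≤ 212 mV.  Below
  59 mV the couple is Nernstian and `NearReversible` is raised; above
  212 mV (the top of the tabulated working curve) the caller is directed
  to the extension.  Cross-validated against the simulator, the fit
  agrees within ~10% up to ≈ 150 mV but degrades toward the top of the
  window (−17% at 160 mV, −26% near 190 mV): the fit pins ψ = 0.1 at
  192 mV where the classical table puts it at 212 mV.  The
  simulator-based oracle (`psi_oracle`, bisection over k⁰ to match a
  target ΔEp within 1 mV) is the reference when the two disagree.
* **Irreversible-regime extension** for n·ΔEp > 212 mV:
  k⁰ = 2.18·√(D_O·α·n·F·v/(R·T))·exp(−(α²·n·F/(R·T))·ΔEp), mapped onto ψ
  through the same relation so one regression handles both regimes.

`het_fit` regresses ψ on (π·a·D_O)^(−1/2) **through the origin**: the
model is exactly proportional, an intercept has no physical source, and
with only a few scan rates an intercept doubles the recovery error at
the slow-kinetics end.  The quoted R² is therefore uncentered.  On
synthetic sets (k⁰ ∈ {1, 3, 10}×10⁻³ cm/s, v ∈ {25, 50, 100} mV/s) the
pipeline recovers k⁰ within 16%, 3% and 1% respectively.

## Amperometric biosensor model and calibration

The enzyme layer and electrode are lumped into a first-order transducer:
each injection raises the steady-state current by S·[f(C_after) −
f(C_before)], approached as 1 − exp(−Δt/τ), where f is identity below
c_sat and saturates Michaelis–Menten-like on the excess above it
(plateau at 2·c_sat).  Gaussian white noise and a linear drift are
added; every generator takes an explicit seed and is bit-reproducible.

Generator defaults are the conditions of a locally-sourced-enzyme
histamine biosensor: S = 23.3 µA/mM, τ = 2.44 s (t95 = τ·ln 20 = 7.3 s),
σ_blank = 0.0903 µA (3σ/S = 11.6 µM), c_sat = 1.6 mM.  The polarized
baseline (10 µA) and drift (0.1 nA/s) are not constrained by published
data and were fixed once at plausible magnitudes.

Calibration: steps are segmented at the scheduled injection times, each
fitted by least squares to i_pre + Δi·(1 − e^(−(t−t₀)/τ)); steady states
are taken from the fitted asymptote (robust to truncated steps);
non-convergent fits are excluded and logged, and a step with
|Δi| < 3× the residual SD is flagged null.  The blank statistics come
from the linearly detrended pre-injection window (≥ 30 s, default 60 s).
The linear range is the longest low-end contiguous run with R² ≥ 0.99
and every point within 5% of the fit — with a 3σ_blank absolute floor on
the deviation criterion so that low-concentration points inside the
noise band cannot disqualify an otherwise linear run.  Sensitivity is
the slope over that run; LOD = 3σ_blank/S; t95 is the mean ± SD of the
first three usable in-range steps.  Because the saturation model bends
gradually, the detected upper range can exceed the saturation onset by a
point or two (e.g. 1.8 mM for a 1.6 mM onset); the sensitivity bias this
introduces is ≈ 1–2%.  Dilution by the injected stock volume
(5 µL into 10 mL per step) is neglected.

## Sample runs and quantification

Supernatant injections produce transient pulses, not steps, because the
delivered substrate plume reaches the sensor before mixing into the
bulk and is then consumed/diluted.  The generator models each pulse as a
bi-exponential (rise τ, decay τ_d, default 60 s — a free parameter since
no depletion kinetics are published) with amplitude S·(injected
moles)/V_mix, where V_mix ≈ 0.22 µL is an effective near-electrode
mixing volume chosen so that the default fermented-fish conditions
(19.24 mg/kg) give ≈ 10 µA spikes.  V_mix cancels between standards and
samples in the area calibration, so quantification accuracy does not
depend on it.

Quantification integrates `∫(i − i₀)dt` per injection (trapezoid on the
native grid, negative sub-areas retained) after removing the linear
baseline drift estimated from the pre-injection anchor means — drift
otherwise contributes ~d·T²/2 per window (≈ 6% of a default pulse area).
i₀ is per-injection, matching the convention of normalizing each
injection to its own baseline.  Areas are converted to per-injection
cell concentrations through a histamine standard calibration (area vs
delivered cell concentration, OLS slope); the cumulative concentration
is back-calculated to the supernatant by tracer dilution
(c_sup = c_cell·V_cell/(n·V_inj)) and then to mg histamine-equivalents
per kg via the preparation arithmetic.  The cell volume (default 10 mL)
is an explicit assumption recorded in every report; the molar mass
defaults to histamine (111.15 g/mol).  By default the extract volume is
the diluent alone (9 mL per 1 g sample); counting the sample's own mass
as aqueous volume is an option.

A run is flagged below the detection limit when every injection's
drift-corrected, 5-s-smoothed excursion stays below
max(1% of baseline, 3σ_blank), or when the summed concentration falls
below an LOD-equivalent obtained by propagating the blank noise through
the area integral; below-LOD results are reported as "< bound" with the
machine-readable flag set.  On synthetic zero-content runs the measured
change stays below 0.7% of baseline across seeds; 19.24 mg/kg runs are
recovered within ~1% (mean) at the default noise.

## What the generators do and do not emulate

They reproduce the signal structure the analysis consumes: √v peak
scaling, quasi-reversible peak separation, first-order step responses,
saturation, white noise, slow linear drift, transient sample pulses.
They do not emulate capacitive/charging currents, iR drop, electrode
fouling, temperature excursions, correlated (1/f) noise, matrix
interferents, or enzyme-kinetic (K_M/V_max) behaviour — so green tests
demonstrate correctness of the computations under the stated model, not
robustness to every artifact of real traces.

## Problem sizes

Test and acceptance runs use scaled study sizes chosen for fast, stable
statistics: CVs at 150 spatial cells × 2400 steps/sweep; calibrations of
12–30 steps sampled at 10 Hz (the hardware's kHz sampling adds nothing
for τ ≈ 2.4 s responses); 10–100 seeds for the recovery studies; sample
runs of 3 injections at 600–960 s spacing.
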