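# ampersense

Electroanalytical computations for amperometric enzyme biosensors, built
around the workflow used to characterize diamine-oxidase (DAO) biosensors
for biogenic amines (histamine, putrescine, cadaverine, tyramine) in food
samples.

Biogenic amines accumulate in fermented and spoiled fish products, and
their total concentration is a standard food-safety index.  A DAO
electrode oxidizes the amine and the liberated H2O2 is re-oxidized at
+500 mV, so the steady-state current tracks the amine concentration in
the measurement cell.  Characterizing such a sensor takes four
computations, all implemented here as a tested, reusable pipeline:

1. **Electroactive surface area (ESA)** from cyclic voltammetry of a
   ferri/ferrocyanide probe via the Randles–Sevcik relation
   `i_p = 2.69e5 · n^1.5 · D^0.5 · C · A · v^0.5`
   (A in amperes with D in cm²/s, C in mol/cm³, A in cm², v in V/s): the
   slope of |i_p| vs √v inverts to A.
2. **Heterogeneous electron-transfer constant (k⁰)** from the
   anodic–cathodic peak separation ΔEp via Nicholson's dimensionless
   parameter `ψ = γ^α · k⁰ · (π·a·D_O)^(−1/2)`, `a = nFv/RT`, using
   Lavagnini's rational fit `ψ = (−0.6288 + 0.0021·X)/(1 − 0.017·X)`
   (X = n·ΔEp in mV) inside the tabulated window and the
   irreversible-regime relation beyond it.
3. **Amperometric calibration** from constant-potential staircase
   injections: exponential-rise fits per step (t95 = τ·ln 20), the
   linear-portion slope as sensitivity, and the 3σ limit of detection
   `LOD = 3σ_blank / sensitivity`.
4. **Biogenic-amine quantification** of food-sample supernatant
   injections via the normalized peak area `∫(i − i₀) dt`, converted to
   mg histamine-equivalents per kg sample through the preparation
   arithmetic (1 g sample / 9 mL diluent / 5 µL aliquots).

Because no public data sets exist for this workflow, the package ships a
physics-based synthetic-data module: a finite-volume Butler–Volmer
diffusion solver generates quasi-reversible cyclic voltammograms with
known kinetics, and a lumped first-order transducer model generates
calibration staircases and transient sample-injection runs with known
ground truth.  Every stage is therefore testable end to end, and the
simulator doubles as an independent oracle for the closed-form methods.

## Worked example

Generate the standard synthetic bundle and push it through the pipeline:

```bash
ampersense fixtures --out demo --seed 1
ampersense analyze-cv --manifest demo/cv_manifest.json --out demo
# ESA = 0.0992 cm^2 (R^2=0.9999); k0 = 2.91e-03 cm/s

ampersense calibrate --trace demo/calibration_histamine.csv \
    --schedule demo/calibration_schedule.csv --out demo
# sensitivity = 22.88 uA/mM, LOD = 12.3 uM, t95 = 7.2 s

ampersense quantify --trace demo/sample_fermented.csv \
    --schedule demo/sample_schedule.csv \
    --area-cal demo/area_calibration.json --out demo
# 19 mg/kg

ampersense quantify --trace demo/sample_fresh.csv \
    --schedule demo/sample_schedule.csv \
    --area-cal demo/area_calibration.json --out demo
# < 0.407 mg/kg
```

Reading the numbers: the CV set was simulated with k⁰ = 3.0×10⁻³ cm/s on
a 0.12 cm² electrode — the kinetic pipeline recovers 2.9×10⁻³ cm/s, while
the Randles–Sevcik area (0.099 cm²) sits ~17% below the true area because
the quasi-reversible peaks are attenuated relative to the reversible
peaks the relation assumes (see `docs/methods.md`).  The calibration run
was generated with 23.3 µA/mM sensitivity, 0.0903 µA blank noise
(3σ LOD = 11.6 µM) and τ = 2.44 s (t95 = 7.3 s); the fitted values agree
within the noise.  The fermented-fish run was generated at
19.24 mg histamine-equivalents/kg and is recovered as 19 mg/kg; the
fresh-fish run contains no amine, changes the current by less than 1%,
and is reported as below the detection limit with an upper bound.

Each command writes a JSON report carrying the config digest, seed and
package version needed to re-run it bit-identically.  The same
functionality is available as a library (`ampersense.simulate_cv`,
`extract_peaks`, `het_from_peaks`, `build_calibration`,
`quantify_sample_run`, ...).

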