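# Methods

## Stress–strain reconstruction

Raw recordings are triples (time, load, displacement) at machine cadence.
The analysis assumes:

* **Origin.** Contact is declared at the first sample whose preload exceeds
  0.02 N/mm² referred to the *initial* projected area A₀ — at contact no
  other area is measurable. Displacement is re-zeroed there. Recordings
  whose preload never crosses the threshold raise a "no contact" error
  rather than guessing.
* **Evolving area.** The nodule's volume V₀ = A₀·H₀ is treated as conserved,
  so the volume-consistent cross-section at height H = H₀(1 − ε) is V₀/H.
  Only a fraction R_c of it carries load: R_c = 0.5 at first contact,
  rising linearly to 1.0 at half height and clamped at 1.0 beyond (the
  continuous extension of the stated ramp). Hence
  A = R_c·A₀/(1 − ε) and σ = F/A.
* **Strain domain.** Samples at ε ≥ 0.95 are discarded — the area correction
  diverges and the specimen is fully densified. A displacement implying
  ε ≥ 1.0 means the platens would meet through the specimen; the measured
  height is then suspect and the curve is rejected (GeometryError), never
  silently truncated.
* **Monotone strain.** Displacement jitter at the stated ±0.01 mm accuracy
  can exceed the ~0.0007 mm per-sample advance. Since the crosshead cannot
  retract, strain is made non-decreasing by running maximum (reversals
  become flat segments). Negative loads are a read error; a stalled
  displacement is not.

CS(s) is the peak stress and CE(s) the trapezoidal integral of σ(ε) over
[0, s], both computed on the raw origin-corrected curve at full sampling
resolution; the 0.05-strain grid (linear interpolation, grid from 0 to the
largest multiple ≤ max strain) exists for cohort tables and classification
only. CE's trapezoid is exact for the piecewise-linear data model; the
integral at s closes with the interpolated σ(s). Levels beyond the achieved
strain are reported missing (NaN), never extrapolated. MPa × strain =
MJ/m³ = J/cm³, so CE needs no unit factor; `mpa_to_gf_mm2` converts
stresses to gram-force/mm² via standard gravity (0.378 MPa = 38.5 gf/mm²).

## Crush-pattern classification

Two tentative criteria, evaluated on the 0.05 grid (raw serration at ±0.1 N
accuracy would trigger on noise):

* **Area ratio** = ∫₀^0.5 max(σ − 0.02, 0) dε / [(σ(0.5) − 0.02)·0.5] ≥ 0.7.
  The baseline is subtracted in the numerator and clipped at zero; the
  rectangle's base sits at the preload threshold. For σ = 4ε² the clipped
  closed form gives 0.3217 (unclipped: 0.3197) — both well below 0.7. If
  σ(0.5) ≤ 0.02 the ratio is undefined (NaN) and only the slope criterion
  can label the curve three-phase.
* **Negative slope**: any decrease between consecutive grid points whose
  strains lie in [0.05, 0.5].

A curve reaching less than 0.5 strain is unclassifiable and carries a
missing label. On noise-free synthetic cohorts the labels agree with the
generating pattern in ≥ 95 % of curves; disagreement concentrates in
gradual curves with power just above 1 (their fill factor approaches 0.5
from below, still short of 0.7, but steep-scale cases can graze the
threshold).

## Synthetic data

The generator defines a true stress curve σ*(ε) and inverts the analysis
transform, F(ε) = σ*(ε)·R_c(ε)·A₀/(1 − ε), sampled at machine cadence and
truncated at the 2000 N limit or ε = 0.95.

* **Three-phase**: Stage I linear (slope = elastic modulus, default 10 MPa)
  to the yield strain; Stage II constant plateau (default 1 MPa in the
  single-curve API; lognormal with median 0.42 MPa, log-sd 0.95 in cohorts,
  calibrated so the analyzed cohort's CS10 median lands near 0.38 MPa and
  CE10 near 0.020 J/cm³); Stage III adds
  plateau·((ε − onset)/(0.95 − ε))^m, a two-parameter law (onset, m) that
  diverges toward full densification as in foam models, with the scale tied
  to the plateau. Serration is a Poisson process (default 12 events per
  unit strain) of multiplicative stress drops (default depth 12 %) with
  exponential recovery over 0.02 strain — a phenomenological stand-in for
  microfracture-and-relief, not a fracture-physics model. A consequence of
  the flat plateau with a plateau-tied densification scale is that
  simulated mid/high-strain stress medians sit below the reference cohort's
  (e.g. CS50 median ≈ 0.45 vs 1.73 MPa) even though the low-strain
  calibration targets are met; cohort-level checks therefore pin low-strain
  quantities only.
* **Gradual** (soft, convex): σ = scale·ε^power, power in (1, 2.5].
* **Preload and contact.** Pre-contact samples ramp linearly to half the
  origin threshold; the contact sample itself records twice the threshold
  (a platen "seating snap"). This keeps every pre-contact sample below the
  detection threshold and puts the detected origin exactly on the true
  contact sample, so the noise-free round trip (analyze ∘ simulate) is
  exact to float precision at every post-contact sample. The seating-snap
  sample itself is a synthetic artifact and is excluded from round-trip
  comparisons. Origin detection under noise is exact to ±1 sample for
  typical nodules (A₀ ≈ 24 mm²); for small nodules the threshold force
  approaches the noise floor and detection can wander several samples, as
  it would on a real machine.
* **Noise.** Load: white Gaussian at the stated accuracy (sd 0.1 N),
  clipped to [0, load limit]. Displacement: stationary AR(1) with marginal
  sd 0.01 mm and autocorrelation 0.995 — encoder error drifts slowly; white
  noise at that scale would imply impossible sample-to-sample crosshead
  reversals and would violate the reader's own monotonicity tolerance.
* **Cohorts.** Pattern counts and per-pattern dialysis counts are exact at
  the assignment level (defaults 118/129 three-phase; dialysis 20/118 vs
  7/11). CT density is mean 937 HU, sd from the IQR [842, 1018]
  (sd = width/1.349), drawn as
  HU = mean + sd·(ρ·z + √(1−ρ²)·noise) where z is the standardized latent
  log-stiffness (log of the noise-free stress at 10 % strain). This
  linear-plus-noise coupling achieves the target Pearson ρ (default 0.45)
  in expectation regardless of the stiffness mixture's shape, where a plain
  Gaussian copula drifts low under the three-phase/gradual mixture; at
  n = 2000 the sample r is within ±0.05 of the target, at n = 129 the
  sampling sd of r is ≈ 0.07, so single-cohort correlations scatter
  accordingly. Geometry: projected area lognormal, median 23.67 mm² with
  quartiles [15.9, 35.22] (log-sd 0.589); height lognormal, median 3.0 mm,
  log-sd 0.25 — the height distribution is an assumption, no reference
  distribution being available.
* **CT phantoms** are additive uniform ellipsoids on a constant background
  with optional Gaussian noise; the ROI is a rectangle around the designated
  blob's projection. They exercise the MIP/ROI code, not anatomy.

What the generator does **not** emulate: within-patient clustering of
nodule properties (patient ids are assigned round-robin), viscoelasticity
or rate dependence, unloading, formalin-fixation effects, rising plateaus,
anatomical CT context (valve, annulus, neighbouring calcium). Passing tests
therefore demonstrate correctness of the computational pipeline under the
stated data model — not that the model captures every feature of real
resected-nodule recordings.

## Cohort statistics

Quantiles use linear interpolation of order statistics (R type 7 / numpy
default), pinned because published quartile tables from this field are
typically produced in R. Ratio rows (p75/p25, max/min) are quotients of the
unrounded statistics; rounding is display-only (rounded-cell quotients can
disagree with printed ratios). A zero minimum yields an infinite ratio, not
an error. Curves contribute to a strain column only if they reach it;
empty columns are omitted. Fisher's exact test is two-sided (tested against
full hypergeometric enumeration); the Mann–Whitney U uses the normal
approximation with tie correction. CT pairs are deleted listwise per
parameter. No multiple-testing correction is applied — p values are
reported raw, as is conventional for descriptive reference datasets; treat
the per-parameter correlations as a family when interpreting.

## Numerical conventions

* Grid landmarks use absolute tolerances of 1e-9 on strain comparisons to
  absorb float error at exact multiples of the increment.
* Pixel-in-polygon: pixel centers at integer (x = column, y = row)
  coordinates, even-odd ray-casting rule, so vertex order is irrelevant;
  the ≥ 600 HU threshold is inclusive. MIP slabs select voxels by center
  coordinate; thickness outside 15–20 mm warns but proceeds.
* Problem sizes in the test-suite and acceptance script (cohorts of
  40–129 recordings at default cadence, 1000 curves at 10× coarser cadence
  for invariant sweeps, one 2000-nodule cohort for correlation recovery)
  were chosen to estimate each quantity comfortably within its tolerance.

## Known limitations

* Young's modulus is deliberately absent: at very small strains the origin
  region is noise-dominated and fixed tissue is unrepresentative.
* Nodules are treated as independent observations; patient-level random
  effects are out of scope.
* Whether reference analyses computed CS/CE on raw or gridded curves is
  unknowable from the outside; this package uses raw curves (the peak-stress
  definition implies full resolution) and documents the grid as a
  table-building device.
* The three-phase criteria are tentative by construction; both thresholds
  (0.7 fill, 0.05-grid slope window) are configurable in `RunConfig`.
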