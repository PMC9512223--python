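# Methods

## The static-equilibrium model

The package models the hip during single-limb support — the least stable
sub-phase of gait, taken as 30–60 % of the gait cycle and attached as
metadata to every result record — as a quasi-static frontal-plane force
balance. Assumptions:

* the trunk and pelvis stay aligned with the earth's vertical on every
  inclination, so body weight *W* acts vertically through a fixed centre
  of gravity;
* the ground reaction force (GRF) is perpendicular to the walking
  surface with magnitude *W*. The source material states the orientation
  but not the transmitted magnitude; |GRF| = *W* is the only choice
  consistent with its own component family (Wx = W·cosΘ, Wy = W·sinΘ
  with Θ = 90° + θ, resultant W) and its level-ground value;
* the hip abductors act as one equivalent force of magnitude 2 *W*
  inclined 30° from vertical (horizontal component exactly *W*, vertical
  √3 *W*) — the classical one-legged-stance free-body construction;
* no dynamic (acceleration-dependent) terms, no muscle redundancy.

The joint reaction on the femoral head is the negative of the abductor
pull plus the transmitted load. In the 2-D (frontal-plane) composition
both horizontal terms act in the same half-plane — the orientation of the
transmitted term is under-determined by the verbal source description,
and this is the unique choice that reproduces the documented monotone
increase of the JRF with ramp angle over the tested 0–15° range — giving

J(θ) = W·√(5 + 2·sin θ + 2√3·cos θ),

which increases strictly up to θ = 30°. In the 3-D composition the
abductor horizontal component stays mediolateral and the ramp-tilt term
W·sin θ is carried anteroposteriorly; the 3-D resultant
W·√(5 + 2√3·cos θ) is then *not* monotone in θ, which is why the monotone
trend is claimed (and tested) for the 2-D magnitude only.

### Axis conventions and signs

All computation happens in one internal frame — anteroposterior (positive
with progression), mediolateral (positive toward the stance-side
midline), vertical (positive up) — and is only relabelled at output:
GRF reports use Y-up labels (X, Z, Y), JRF reports Z-up labels
(Fy, Fx, Fz). Relabelling is an isometry; values never change.

The GRF direction angle α is the principal arctangent of
vertical/horizontal, in (−90°, 90°), with the exact-zero horizontal case
pinned to +90° (level ground). Writing Wx = −W·sin θ resolves an internal
sign ambiguity in the source component formula (a second-quadrant cosine
is already negative): this form is negative on every incline and zero on
level ground, matching every qualitative statement made about it.

Degrees are used at every interface, radians internally; text reports
round to two decimals, machine formats (TSV/JSON) keep full precision
(floats serialised with `repr`, parsed with round-trip precision).

## Empirical calibration engine

The published per-ramp cohort means are calibration anchors, shipped in a
versioned plain-text file (`src/hipforce/data/calibration.txt`):

* JRF (printed unit "BW"): 119.4, 129.5, 138.6, 149 at 0/5/10/15°,
  SDs 16.1/17.4/18.2/19.6;
* GRF (N), per gender: 509.49/499.87/527.7/549.58 (male) and
  518.64/504.25/517.57/552.24 (female).

Policy: exact stored constants at anchors; piecewise-linear interpolation
between 0° and 15°; above 15°, a least-squares straight line through all
four anchors (slope 1.958, intercept 119.44 for JRF), evaluated up to the
70° gate. The policy is a field of `CalibrationTable` so an alternative
rule can be swapped in. Two caveats are deliberate:

* the printed JRF unit "BW" with values 119.4–149 is implausible as true
  body-weight multiples (the mechanistic engine gives ~2.9–3.0, and peak
  in-vivo values cited in the literature are ~7); the values are stored
  and reported verbatim, never reinterpreted;
* the least-squares line sits 0.19 units below the 15° anchor, so the
  estimator has a small downward step immediately above 15°; it is
  strictly increasing on any grid of ≥ 0.1° spacing (tests use the
  integer-degree grid).

## Synthetic cohort simulator

`cohort` replaces the original study's data acquisition (40 university
students, 20 per gender, walking four ramps) with a generator:

* body masses from gender-specific normals truncated at ±3 SD and floored
  at 30 kg — male 70 ± 8 kg, female 58 ± 7 kg. These anthropometrics are
  declared plumbing constants for a young-adult student population (none
  were published) and are fully exposed in `CohortConfig`;
* each engine value (per subject × ramp) is multiplied by an independent
  lognormal noise factor with **unit mean** and coefficient of variation
  `noise_cv` (default 0.135 = 16.1/119.4, the level-ground dispersion of
  the published JRF table). Multiplicative noise is used because the
  published per-ramp SDs scale with the cell means; the unit-mean
  parameterisation (μ = −σ²/2, σ² = ln(1 + cv²)) makes cell means
  converge to the engine value, so the simulator reproduces the published
  mean ± SD cells rather than overshooting the mean by the ~0.9 % a
  unit-median factor would introduce;
* summaries report the sample mean, sample SD (n−1 denominator; the
  published ± values are assumed to be sample SDs) and n per
  (gender × ramp × quantity) cell, plus a pooled "all" stratum, rendered
  as an aligned text grid mirroring the published table layout or as CSV.

What the simulator does **not** emulate: within-subject gait variability,
gender differences in the force means (the mechanistic engine is
gender-blind; the empirical GRF engine carries the published gender
anchors), correlations between ramps for the same subject (noise is
independent per observation), and any kinematic quantity. Passing tests
therefore validate parameter recovery of the declared generative model,
not fidelity to real gait data.

Problem sizes used by the statistical tests: mean-convergence uses 500
replicate cohorts (Monte-Carlo SE ≈ 0.1 % against a ±0.5 % band);
CV-recovery uses 220 replicate cohorts of 20 subjects per gender against
a ±10 % band. All randomness flows through `numpy.random.default_rng`
seeded from `CohortConfig.random_seed`; identical configurations give
bit-identical observation tables and summaries.

## Numerical and degenerate-input choices

* Ramp gate: θ must be finite and in [0, 70]; 70° exactly is accepted.
* Zero force vector: direction is undefined and raises; a zero-weight
  GRF result reports the level-ground +90° convention for its angle.
* Anchor lookup is a dict hit before interpolation, so anchor queries are
  bit-exact, not merely within interpolation error.
* Percent change requires a strictly positive reference; the reference is
  always the first element of the swept list.
* Result files are written via temp-file + atomic rename; a failing run
  never leaves a partial file.
* Body weight from mass uses standard gravity 9.80665 m/s², recorded in
  result-file comments.

## Known limitations

* The mechanistic engine reconstructs the printed equations only; the
  regression the original authors used to produce their cohort tables was
  never disclosed, so mechanistic and empirical outputs are on different
  scales (true BW multiples vs the printed "BW" unit) by design.
* Gender-specific JRF cell values were illegible in the source table and
  are not shipped.
* No inferential statistics (MANOVA/post-hoc) — only mean ± SD summaries.
* Extrapolation beyond 15° is a modelling convention (least-squares line),
  not a measurement.
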