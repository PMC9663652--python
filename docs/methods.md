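# Methods

## Model overview

`dbsuggest` predicts, for each selectable stimulation site of a directional
DBS lead, the current amplitude ("effect threshold") at which the volume of
tissue activated (VTA) overlaps a target sweet spot by a desired amount
V_d, and ranks sites by that threshold. The chain is:

1. geometry — contact positions p_e (surface center) and level centers p_c
   in world millimetres, from a reconstruction record or a parameterized
   trajectory;
2. VTA model — a sphere whose radius follows the zero-intercept quadratic
   current↔radius transform I = a1 r + a2 r² (defaults a1 = 0.43 mA/mm,
   a2 = 0.36 mA/mm²; exact inverse
   r = (−a1 + √(a1² + 4 a2 I)) / 2a2), centered at p_c for
   omnidirectional/ring-mode sites and at p_e + γ·û·r for directional
   segments, û = (p_e − p_c)/|p_e − p_c|, γ = 0.1;
3. overlap — the closed-form sphere-sphere lens volume, completed with the
   disjoint (0) and containment (full inner-sphere volume) branches so the
   overlap is defined and continuous for every configuration;
4. target V_d — constant (33% of sweet-spot volume) or distance-dependent
   (fixed effects of a linear mixed model predicting percent coverage from
   contact-to-sweet-spot-center distance), clamped to [1, 100] mm³;
5. search — smallest I with overlap ≥ V_d.

### Assumptions

* Spherical VTAs in a homogeneous medium; no pulse-width/frequency
  dependence, no tissue anisotropy, no encapsulation effects.
* The sweet spot is approximated by the *equal-volume* sphere about its
  (binary) center of mass. Equal volume is chosen so the "fraction of the
  sweet spot" semantics of V_d is preserved exactly; a weighted centroid is
  available as an option.
* γ < 1 guarantees the overlap is non-decreasing in current (the radius
  grows by dr while the center moves at most γ·dr), which the bisection
  search exploits; the package enforces γ ∈ [0, 1).

## Threshold searches

* Continuous (default with the analytic engine): bisection on [0, I_max]
  (I_max default 8 mA) for the smallest current whose overlap reaches V_d,
  tolerance 0.01 mA. The returned value is the upper bracket end, i.e. it
  always reaches the target.
* Grid mode (only option for voxel engines): overlaps on a 1..8 mA grid,
  initial index = argmin |V(i) − V_d| with ties resolved toward the lower
  current (clinically conservative), refined by linear interpolation toward
  the neighbor on the deficit side. An overestimate at the first node
  interpolates from (0 mA, 0 mm³); an underestimate at the last node is
  not refined. A flat bracketing segment degenerates to the node current
  (logged).
* Unreachable targets produce an explicit "not reached" instead of
  clamping to I_max — silently suggesting the ceiling amplitude would be
  unsafe; callers can still clamp downstream if they want.
* Best level uses the four ring-mode sites (the two outer omnidirectional
  contacts plus one virtual ring contact per segmented level); best
  contact uses the eight physical contacts. Exact threshold ties (≤ 1 nA)
  are kept as sets and scored as "partially correct" downstream.

## Desired-overlap model fitting

Percent coverage at the clinical effect threshold is regressed on distance
with `statsmodels` MixedLM (REML), random intercept and slope grouped by
lead. If that fit fails or is singular, the model downgrades to a random
intercept, and — when even that has no estimable variance components, e.g.
exactly collinear noiseless data — to OLS; each downgrade is logged and
recorded in `fit_info`. Predictions for new leads use fixed effects only
(random effects are unobservable for an unseen lead). The percentage is
converted to mm³ via the sweet-spot volume and then clamped in mm³ to
[1, 100]; negative predicted percentages are absorbed by the lower bound.
Ring-mode records are included in the fit by default (`include_ring=False`
to drop them).

## Field-model stand-in

The voxel engine treats a contact as a point current source in an infinite
homogeneous gray-matter medium (σ = 0.33 S/m), binarized at |E| ≥ 0.2 V/mm,
giving a ball of radius √(I / 4πσE_thr); directional contacts are
restricted to a 60° half-angle cone about the segment direction (solid
angle fraction 25%). This is deliberately simple — it exists to exercise
the grid-search path, transform refitting (the sweep is 0.6–10 mA in
0.1 mA steps), and voxel-based validation, and produces a nearly pure
quadratic current-radius relationship (fitted a1 ≈ 0, R² > 0.999). σ for
white matter is kept in the config so a two-compartment variant is a
drop-in.

## Synthetic cohort generator

Defaults emulate a 24-patient bilateral cohort:

* sweet spot: sphere of radius 2.5 mm (≈65 mm³, on the scale of the motor
  STN) at MNI (12, −13, −6); left hemisphere is the mirror image. STN:
  ellipsoid of ≈160 mm³ nearby.
* leads: ideal 1-3-3-1 geometry (1.5 mm contacts, 0.5 mm spacers, 0.65 mm
  body radius), aimed so the segmented levels straddle the target, then
  perturbed by a random roll (uniform), translation jitter (SD 1 mm) and a
  small rigid rotation (SD 5°). Left leads are mirrored right-hemisphere
  scenes.
* thresholds: for each site, the true threshold solves overlap(I) = V_d(d)
  under the analytic engine, where V_d carries per-lead random effects
  (intercept SD 10%, slope SD 1 %/mm around the true line 70 − 8d %),
  clamped to [1, 100] mm³; the observed value multiplies lognormal noise
  (CV 0.1), rounds to the 0.1 mA titration step and clips to [0.5, 10] mA.
  Sites unreachable at the solve ceiling produce no review row; a lead
  with no site reachable at 8 mA is re-placed (bounded retries).

Reusing the analytic engine as the forward model is circular *by design*:
recovery experiments then isolate the statistical machinery from VTA-model
error. `engine="field"` generates thresholds from the voxel stand-in
instead, giving a model-mismatch stress test. What passing recovery tests
therefore show is internal consistency of the pipeline — not that the
spherical model matches finite-element VTAs or clinical behaviour; real
monopolar reviews carry anatomy, side-effect limits and rater variability
that the generator does not emulate.

## Numerical choices

* All geometry in double precision; no snapping. Lens-formula continuity
  at the case boundaries is verified to 1e-9 in tests.
* Sphere/ellipsoid rasterization is by voxel-center membership, making
  every voxel count (and hence Dice and voxel overlaps) bit-reproducible;
  a sphere smaller than roughly half a voxel may rasterize empty.
* The transform refit is a non-negative least-squares fit of I on (r, r²)
  (the transform's parameter space requires a1 ≥ 0, a2 > 0); data
  satisfying the constraints are recovered exactly.
* Cohort ground-truth thresholds are solved to 1e-3 mA, an order below the
  0.01 mA suggestion tolerance, so end-to-end error is dominated by the
  0.1 mA clinical rounding.
* Experiment sizes: the Monte-Carlo overlap oracle uses 1,000 random
  configurations × 4·10⁵ samples (sampling error ≈0.2 mm³, well under the
  0.5 mm³ agreement band); mixed-model recovery uses 100 cohorts of
  24 leads × 8 contacts.

## Design decisions that were genuinely open

* Tie-breaking of the grid-search argmin toward the lower current:
  conservative for the patient.
* Partial-credit weight for tied best-site suggestions: 0.5 by default,
  with the strict (0) and lenient (1) extremes always reported, since any
  single choice is a convention.
* Unreached thresholds are excluded from MAE pairing and reported as a
  count rather than imputed.
* For best-contact scoring, ring-mode review rows are excluded from the
  clinical ground truth (they are level-scale observations, not candidate
  contacts); for best-level scoring every row of a level competes,
  ring-mode included.
* Left/right sweet-spot transfer is a mid-sagittal mirror flip, not a
  nonlinear warp; flagged in logs.
* p_e is taken as the geometric center of the contact surface.

## Known limitations

* The spherical VTA and the point-source stand-in ignore tissue
  heterogeneity and electrode geometry; cross-model agreement numbers on
  clinical FEM pipelines cannot be reproduced here.
* Side effects ("sour spots"), multipolar steering, and symptom-specific
  targets are out of scope.
* Mixed-model CIs are Wald-type; with 24 groups their joint coverage of
  both fixed effects is a few points below nominal.
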