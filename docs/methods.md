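# Methods

`gaitgen` implements a parametric generator of three-dimensional ankle gait
references for robot-assisted rehabilitation: given one motion parameter (MP,
walking speed `v` in km/h) and four structure parameters (SP: body height `h`
in cm, foot progression angle `fpa` in deg, foot length and foot width in cm),
it produces a full-cycle trajectory of the ankle center position (ACP, the
ankle joint center expressed in the hip frame, cm) and of the three ankle
joint angles (AJA: dorsiflexion/plantarflexion A1, inversion/eversion A2,
internal/external rotation A3, deg).

## Coordinate frames

The pelvis frame {P} is built per sample from the Helen Hayes pelvis markers:
origin at the midpoint of R.Asis and L.Asis; y axis from R.Asis toward
L.Asis; z axis normal to the marker plane with its sign chosen inferior
(negative projection on the laboratory up axis); x = y × z, after which
y := z × x restores exact orthonormality. The axis triple
(anterior, left, inferior) quoted in gait descriptions is left-handed; we
keep y and z as described and accept that the right-handed completion points
x *posteriorly* (det R = +1 is asserted). Only the sign convention of the
ACP X channel depends on this choice, and the package uses it consistently.

The hip frame {H} shares the pelvis axes with its origin at the hip joint
center (accepted as an input series, as exported by mocap software; no
regression-based estimation). The ACP is `R_WH^T (p_AJC − p_HJC)` per
sample — the inverse of the homogeneous transform whose rotation columns are
the frame axes. An alternative pelvis-origin ACP is available via
`acp_in_hip(..., origin="pelvis")`; the hip origin is the default because the
generated trajectory is meant as an end-effector reference for a leg
manipulator rooted at the hip.

All positions are cm internally; the TRC reader converts from the file's
Units field (mm common).

## Gait events and normalization

Initial contact (IC) and toe-off (TO) are detected kinematically: a foot
marker is "in contact" while its vertical position sits below a threshold
placed `threshold_frac` (default 0.08) of the marker's vertical excursion
above its stance level (10th percentile). The signal is first low-passed
(zero-phase Butterworth, default 12 Hz cutoff) and contact/flight runs
shorter than 0.15 s are removed. Entry/exit crossing times are refined by
extrapolating the one-sided vertical slope on the airborne side of the
crossing down to stance level, which locates touchdown/lift-off to a few
milliseconds when the height change is near-linear at impact. IC comes from
the heel marker, TO from the toe marker; contralateral markers provide the
opposite-leg events (OTO, OIC). Each stride yields the event set
IC < OTO < OIC < TO < next IC, from which the phase durations DSP1/SSP1/DSP2
(stance sub-phases) and swing follow as percentages that sum to 100 exactly.

Channels are resampled by linear interpolation onto a uniform percent grid,
101 points by default (0–100% inclusive, IC at 0%), the convention in gait
analysis; integer percents are then exact grid nodes.

The foot progression angle is the signed transverse-plane angle between the
heel→toe vector and the forward laboratory axis (toe-out positive, sign
resolved by the stance side), averaged over the foot-flat window. The exact
foot-flat definition varies between labs; we use [OTO, OIC] by default (end
of loading response to contralateral contact), configurable.

## Gait features

Per channel: values at the four events (`e1..e4`), global extremes (`f1`
minimum, `f2` maximum, earliest occurrence on ties) with relative timings
(`t<ch>f1/2`, % of cycle), and derivatives with respect to percent (central
differences) at events and extremes (`d`-prefixed). Phase features: cycle
duration (s) and DSP1/SSP1/DSP2 (%). Velocities are per-percent so they are
comparable across speeds; multiply by 100/cycle for per-second units. The
default enumeration is 14 features per channel + 4 phase features (88 total
over six channels); the set is config-driven rather than fixed, since which
velocity features a lab models varies. Features are averaged across strides
within a subject × speed cell, giving one tidy row per cell.

## Regression and model selection

Each feature Y is fitted as `Y = b0 + Σ B_i R_i` with `R_i` coded powers of
the predictors, order ≤ 3 per variable. Coding is centered-and-scaled,
`R = ((x − mean)/sd)^k`, which keeps order-3 design matrices conditioned;
raw powers are available (`coding="raw"`). Scaling constants come from the
full cohort table (a fixed affine rescaling, so cross-validation is
unaffected and fold refits are exactly reproducible).

Selection proceeds in three stages:

1. **Screening** (family-wise α = 0.05, Bonferroni over the five
   candidates). Speed is a within-subject factor: one-way ANOVA of
   subject-mean-centered values across speed levels, replaced by a Friedman
   test when Shapiro-Wilk rejects residual normality. Structure parameters
   are screened on subject-level means by a forward residual correlation
   test (Pearson, Spearman fallback): after a predictor is admitted it is
   regressed out, so a strong SP cannot mask a weaker one. The family-wise
   control makes a pure-noise feature screen empty with probability ≈ 0.95.
2. **Enumeration**: all order combinations 0..3 over the screened predictors
   (4^k candidates, no stepwise heuristics). Polynomials are hierarchical —
   order k includes powers 1..k — and a candidate is admitted only if each
   variable's highest-order coefficient is significant at P = 0.05 in the
   full-data fit. Testing every power instead would reject a pure odd cubic
   (null quadratic coefficient) almost surely.
3. **Selection**: least leave-one-*subject*-out cross-validated MSE among
   admitted candidates, with the intercept-only (cohort mean) model always
   in the pool. All rows of a held-out subject leave together because rows
   within a subject share SPs and are not exchangeable; the score therefore
   measures generalization to a new person, the method's use case.
   Trial-wise hold-out is available (`unit="trial"`).

A feature with no admitted predictor keeps the cohort mean exactly.
Interactions are excluded (the model is additive in coded terms).
Rank-deficient folds are skipped with a warning; an all-folds-skipped spec
raises. Prediction outside the training range (± 10% of the range by
default) emits a non-fatal extrapolation warning.

FPA-vs-speed independence is checked by paired Wilcoxon signed-rank tests on
each adjacent speed pair with a Bonferroni-corrected threshold (default
family = the adjacent pairs; a larger family size can be passed when the
correction should span a whole feature battery).

## Trajectory generation

Predicted features become knots `(t %, value, velocity per %)`: events at 0,
DSP1, DSP1+SSP1, DSP1+SSP1+DSP2; extremes at their predicted timings. Knots
closer than 0.5% of the cycle merge by value averaging (regression noise can
produce near-coincident predictions); event ordering violations beyond
repair raise a diagnostic error. Velocities come from the modelled
`d`-features at event knots; extreme knots are stationary points, so their
tangents are pinned to zero (the `d<ch>f*` features remain available and can
be used instead via `zero_extreme_velocity=False`); any remaining knot gets
a periodic three-point finite-difference tangent.

Between consecutive knots the unique cubic with prescribed end positions and
velocities is found by solving the 4×4 linear system in local normalized
time τ = (t−t0)/(t1−t0) (coefficients are reported in that basis with the
segment bounds, for conditioning). One extra segment from the last knot to
the first knot shifted by +100% closes the cycle, making the reference
periodic and C1 across the initial-contact wrap — a cyclic robot reference
cannot tolerate a discontinuity at IC. Cycle duration attaches from the
predicted `cycle` feature.

The comparison baseline (`average_baseline`) is the traditional pointwise
mean trajectory across participants; averaging smears inter-subject timing
differences, so its peaks are systematically flatter than individual peaks.

## Synthetic data

No public dataset accompanies the method, so `gaitgen.synthetic` emulates
treadmill cohorts with full ground truth:

* **Subjects**: height ~ N(168.8, 5.64) cm, foot length ~ N(25, 1.5) cm,
  foot width ~ N(9.5, 0.8) cm, FPA ~ N(7, 4)°, clipped to physiological
  ranges (the height distribution matches a young healthy cohort). Each
  subject also carries a small template deviation (phase 0.003 cycles,
  amplitude 1.5% SD per channel).
* **Channels**: two phase-locked harmonics per channel with programmed
  dependencies — X amplitude ∝ stride length (speed × cycle duration),
  Z amplitude grows with speed and height, Y and A2/A3 with FPA, A1 with
  speed and foot length; cycle duration `1.06 (h/168.8)^0.45 (4/v)^0.42` s;
  stance fraction 0.60 at 4 km/h, −0.012 per km/h. Harmonic peak phases are
  placed so each channel's extremes fall mid-gap between event knots
  (~25–35% and ~75–85% of the cycle), keeping the largest knot gap ≤ ~25% of
  the cycle; with extremes sitting on events the spline benchmark would
  degenerate to four effective knots and its error would be dominated by an
  amplitude-proportional interpolation artifact rather than by the method
  under study.
* **Trials**: markers synthesized from a moving, gently yawing pelvis
  (pelvis triad placed exactly in the frame plane so frame recovery is
  exact), the programmed hip-relative ACP, and heel/toe tracks consistent
  with the programmed events (linear belt travel during stance, smooth
  cosine return with half-sine lift during swing — linear near touchdown so
  threshold detection can extrapolate to the exact instant) and with the
  programmed FPA. Marker noise is iid Gaussian, default SD 0.2 cm (100 Hz
  capture jitter); angle series are taken as inputs and carry no added
  noise.
* **Cycle-level fast path**: `simulate_cycles` skips the marker stage,
  adding stride-to-stride variability (phase SD 0.006 cycles, amplitude SD
  3% — a stride CV of ~3% is physiological for treadmill walking) plus grid
  noise (0.3 cm / 0.5°). The variance partition puts more weight on
  stride-level than on subject-template deviation, as treadmill studies
  report; a generator with predominantly subject-level multiplicative
  deviation would make held-out error deterministically amplitude-
  proportional and hence monotone in speed by construction.
* **Feature-table path**: `simulate_feature_table` programs feature values
  directly (linear SP effects, cubic speed effects) with noise scaled to
  10% of each feature's systematic range, for regression studies.

What the generator does *not* emulate: soft-tissue artifact and marker
occlusion, asymmetric or pathological gait, turning, double-peaked channels
(only two extremes per channel), and kinematic consistency between foot
markers and the ankle center. Passing tests therefore demonstrate internal
correctness and statistical behavior under controlled, favorable conditions,
not clinical validity on real motion-capture data.

## Study sizes and numerical choices

The bundled studies (`gaitgen.studies`) use a training cohort of 25 subjects
× 5 speeds (3–5 km/h) × 3 strides — the cohort scale of a typical treadmill
study — with one held-out subject per replicate; the validation target is
the held-out subject's mean measured (noisy) cycle per speed, and RMSE /
Pearson correlation are computed on the 101-point grid per channel.
Tolerances: frames and splines are exact to 1e-9; event detection is judged
at ±0.02 s; FPA at ±0.1° noise-free; feature closure at 1% of channel range.
Ties in extremes resolve to the earliest grid point; `argmin`/`argmax`
provide this deterministically. Degenerate inputs (collinear pelvis markers,
zero-length segments, constant series for correlation) raise typed errors
rather than propagating NaNs.

## Known limitations

* The regression form is additive in coded powers; interaction effects
  (e.g. speed × height) are not representable.
* Only two extremes per channel are parameterized; trajectories with more
  structure between events are under-knotted.
* Event detection assumes treadmill-like vertical marker excursions and
  fails gracefully (insufficient-data error) on non-gait input, but is not
  validated for pathological gait.
* The generated cycle duration comes from one scalar feature; intra-cycle
  time warping between subjects is not modelled.
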