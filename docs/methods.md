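# Methods

## The kinematic chain

The package models the upper limb as a proximal-to-distal chain with seven
degrees of freedom. Joint coordinates act as rotations about model-defined
axes that are in general *not* orthogonal and are distributed over several
bodies:

* **Shoulder** — four consecutive rotations: elevation plane (θ_elv),
  elevation (θ_sh_elv), elevation plane back (−θ_elv), axial rotation
  (θ_sh_rot). The elevation-plane and axial rotations share one axis; the
  elevation axis is (nearly) perpendicular to it. In the orthonormal
  shoulder basis B_sh_orth the compound rotation is
  A(θ_elv)·E(θ_sh_elv)·A(−θ_elv)·A(θ_sh_rot), where A is the elemental
  rotation about basis column 2 and E about column 3. Column 3 as the
  elevation axis is forced by the inversion formulas: any other choice
  breaks the exact FK→IK round trip, which the tests verify.
* **Elbow** — flexion (θ_el_flex) as an axis-angle rotation about a unit
  axis r_el_flex = [x y z] expressed in the elbow basis B_pro_sup (whose
  column 1 is the forearm-rotation axis), followed by the elemental forearm
  rotation (θ_pro_sup) about column 1.
* **Wrist** — deviation (θ_dev_c) and flexion (θ_flex_c) are *compound*
  coordinates distributed over the proximal (lunate) and distal (capitate)
  carpal rows: exp(s_d·θ_dev_c·r̂_dev) · exp((θ_flex_c/2)·r̂_flex) ·
  exp((1−s_d)·θ_dev_c·r̂_pdr1) · exp((θ_flex_c/2)·ê₁), all axes in the wrist
  basis B_pdr3 (column 1 = distal-row flexion axis). The flexion split is
  exactly one half per row, which is what makes θ_flex_c = 2μ with μ the
  per-row flexion; the deviation split s_d (`wrist_split`) defaults to 0.5
  and is configurable, since published implementations encode this coupling
  in the model file rather than in print.

Joint limits (degrees): θ_sh_elv ∈ [0, 180], θ_sh_rot ∈ [−90, 20],
θ_el_flex ∈ [0, 130], θ_pro_sup ∈ [−90, 90], per-row wrist flexion ∈
[−35, 35] (hence θ_flex_c ∈ [−70, 70]) are fixed properties of the chain.
θ_elv ∈ [−90, 130] and θ_dev_c ∈ [−10, 25] are surrogate defaults
(configurable) because the chain itself does not pin them down.

## Orthonormal bases and obliquity

Real model files specify shoulder axes that are only *nearly* orthogonal
(pairwise deviations from 90° of order 0.003°). The solver requires an
orthonormal basis, obtained by QR decomposition with the sign convention of
a positive diagonal in the triangular factor, so every orthogonalized column
keeps a positive dot product with — and stays within ~the obliquity of —
its input column. QR orthogonalization is sequential, so the per-column
deviations grow from essentially zero (first column) to roughly the pairwise
obliquity (last column), matching the published behaviour.

The synthetic reference model (`build_reference_model`) emulates this
structure deterministically from a seed: the raw shoulder triad has *all*
pairwise deviations from 90° equal to the requested obliquity (symmetric
Gram construction, default 0.0029°); the elbow flexion axis is tilted 5–15°
out of the plane perpendicular to the forearm axis so the general axis-angle
formulas are exercised away from the trivial orthogonal case; the wrist axes
are distinct non-orthogonal unit vectors within 30° of their nominal basis
columns. Segment origins are fixed world offsets — translations cancel in
the marker difference vectors, which the tests check explicitly.

Forward kinematics supports two shoulder modes. The default composes the
elemental rotations in B_sh_orth (the algorithm's own idealization — exactly
invertible). `shoulder_axes="raw"` composes the rotations about the raw
oblique axes instead, while the solver still assumes B_sh_orth: this
reproduces the model/algorithm mismatch a real model file induces and yields
shoulder reconstruction errors of the obliquity's order (~0.003° RMS). The
validation experiment uses raw mode by default. Note that in raw mode the
elevation-plane/axial error is amplified like obliquity/sin(θ_sh_elv) near
the gimbal orientations — a conditioning property of the chain itself, not
of the solver.

## The wrist root problem

Eliminating both deviation rotations from the wrist compound rotation R̃
uses the invariant (d = r_dev, f = r_flex, p = r_pdr1, all in B_pdr3):

    dᵀ·exp(μ·f̂)·p = dᵀ·R̃·exp(−μ·ê₁)·p

— the left side kills the distal deviation (it fixes p), the right side the
proximal one (it fixes d). Both sides are sinusoids in μ, giving
a·cosμ + b·sinμ = c(μ) with

    a = d·p − (d·f)(f·p)        b = d·(f×p)          q = R̃ᵀd
    x = q·p − (q·ê₁)(p·ê₁)      y = −q·(ê₁×p)        z = (q·ê₁)(p·ê₁) − (d·f)(f·p)

and c(θ) = x·cosθ + y·sinθ + z. Writing the left side as
√ξ·cos(μ−η) (η = atan2(b,a), ξ = a²+b²) produces the root function
F(θ,σ) = −θ + η + σ·atan2(Re√(ξ−c²), c), whose valid root satisfies
σ = sign(μ−η). The constants are verified in the tests against a direct
matrix-form evaluation on a dense grid and by the exact round trip.

**Singularity borders.** c²(ϑ) = ξ is solved in closed form through the
exponential substitution w = e^{iϑ}, giving two complex values per sign of
c (four in total). A real pair bounds a region where the discriminant is
negative; there F sticks to its baseline −θ+η (for c > +√ξ) or to the
baseline shifted by σπ (for c < −√ξ). Roots cannot lie strictly inside
either region — in the first, F equals the baseline which vanishes only at
η; in the second, the generating equation has no solution — so the scan
masks points with ξ − c² < 0 (with a small negative tolerance so that knots
*on* a border, where the discriminant rounds to ±1e−16, are kept). Testing
the discriminant sign rather than interval membership also handles regions
that wrap around ±180°, where the two real borders bound the complement of
the naive sorted interval.

**Root finding.** Branch σ=+1 is scanned on [η, 35°], σ=−1 on [−35°, η], at
0.1° resolution with η, the domain limits and any real borders inserted as
exact knots; sign changes are refined by Brent's method (xtol 1e−12 rad in
double, 1e−6 rad in single precision). Two safeguards cover cases the plain
scan misses: (i) a root sitting exactly on a domain endpoint or border knot
(|F| < 1e−9 with no sign change available) is accepted directly; (ii) if no
candidate is found at 0.1°, the scan is refined to 0.01° and 0.001° — near a
*developing* singularity (borders almost real) two roots can lie a few
hundredths of a degree apart and cancel within one coarse cell.

**Candidate selection.** Near a developing singularity several exact roots
can coexist on the valid branch, and |F| cannot rank them (all are zeros).
In streaming use the candidate nearest the previous frame's flexion is
taken. Without history, each candidate's full wrist rotation is rebuilt
from (μ, θ_dev(μ)) and compared to R̃; the smallest reconstruction residual
identifies the physical root. This residual check is the package's
disambiguation rule; selection rules based on root order or |F| mis-pick in
exactly the near-singular cases where the ambiguity arises.

**Deviation.** For a root μ, v₁ = exp(μ·r̂_flex)·r_pdr1 and
w₁ = R̃·exp(−μ·ê₁)·r_pdr1 differ by the proximal-row deviation rotation
about r_dev; the standard two-vector/axis atan2 expression yields
s_d·θ_dev_c, divided by the split to give the compound angle. Building both
vectors from r_pdr1 is what makes the relation exact for the row-split
structure above (verified by round trip); variants applying the rotation to
r_flex do not invert the chain.

## Gimbal handling and degenerate inputs

At θ_sh_elv = 0° or 180° the elevation-plane and axial angles are not
individually identifiable (only a combination is observable). Within 1e−6
rad of these orientations the solver returns the previous frame's θ_elv (0
at the first frame), solves the axial angle from the residual rotation about
the shared axis, and flags the frame (`IKResult.gimbal`). The returned
angles are kinematically equivalent to the input — they reproduce the
marker frame — which is the strongest statement possible there. Similarly,
at zero elbow flexion the forearm angle is read off the residual elemental
rotation. arccos/arcsin arguments are clamped to [−1, 1] against
floating-point overshoot. Out-of-limit outputs are flagged, not clamped, by
default (`saturate=True` clamps); out-of-range inputs should be prevented
upstream rather than repaired.

## Precision modes and the continuity filter

`double` runs in float64; `single` casts the markers, bases and all solver
arithmetic — including the root-function evaluations driving the bracketed
iteration — to float32 (xtol 1e−6 rad). `single_mod` adds the wrist output
continuity check: when successive θ_flex_c values differ by more than 5°,
the output is the previous value **plus 0.5°** — applied literally as an
unsigned step, which is the published rule; a signed variant (±0.5° toward
the raw value) is available behind a flag. With the reconstruction-residual
candidate selection, single precision rarely mis-picks roots, so the filter
mostly acts as a guard; its worked example (previous 10°, raw 30° → 10.5°)
is part of the test surface.

## Validation experiment and what it shows

`run_validation` draws pseudo-random trials (default 100), each a 5th-order
Bézier curve per coordinate with six control points uniform within the
joint limits, sampled for 5 s at 100 Hz (500 samples; the Bézier parameter
spans [0, 1] inclusive). By the convex-hull property trajectories stay
within limits. Forward kinematics (raw shoulder axes) produces the marker
trajectories; the solver reconstructs the coordinates in each requested
mode; per-trial per-coordinate RMS errors are aggregated as mean ± SD
across trials (sample SD, n−1). An optional exclusion rule drops trials
whose worst coordinate RMS exceeds a threshold (5° in the published use,
where it affected only the optimization-based reference method, not this
solver). Mean per-frame wall-clock time is reported informationally;
timing is hardware-dependent and not part of any assertion.

The generator emulates the published study conditions, not real recordings:
there is no sensor noise, no orientation-estimate drift, no soft-tissue
artifact, and sensor-to-segment alignment is identity. Passing tests
therefore demonstrate the *algorithmic* properties — exact invertibility of
the chain, correct root selection, obliquity-limited accuracy — and say
nothing about robustness to real IMU error sources, which the package does
not model.

## Problem sizes used by the test suite

The automated checks run the experiment at the study's own scale: 10,000
random configurations for the round-trip identity, 100 trials × 500 frames
for the accuracy and precision studies, and a 181×141 grid of wrist
configurations for the root-finder-versus-bisection comparison. A full run
of the suite takes a few minutes on one CPU core.

## Known limitations

* The deviation split s_d is a single fraction; real model files may encode
  a more general per-row coupling.
* The surrogate θ_elv and θ_dev_c limits are plausible defaults, not
  model-derived values.
* Exact published accuracy-table values depend on the published model
  file's axes; with the synthetic reference model only the error *scale*
  (sub-0.01° shoulder RMS from ~0.003° obliquity) is comparable.
* The shoulder gimbal convention keeps outputs continuous but cannot
  recover unidentifiable angles; applications commanding sustained motion
  at 0°/180° elevation should treat θ_elv/θ_sh_rot jointly.
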