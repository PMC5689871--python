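# Methods

This note documents the model behind `fluqa`, the numerical and design
choices made where the method left room, what the synthetic fixtures do and
do not emulate, and the package's known limitations.  It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The fluence model and its assumptions

The quantity reconstructed is the **primary fluence in air**: the MU
delivered to each point of an isocenter-centered volume by the cumulative
beam aperture over the whole delivery,

    I(r) = sum over segments of  F(r') * M(r') * dMU * SAD^2 / |r - s|^2 .

Assumptions, in decreasing order of importance:

* **Single point source** on the SAD sphere (SAD = 100 cm).  The finite
  focal spot and the secondary (flattening-filter) source are ignored.
* **Binary aperture mask** `M` sampled at voxel-center projections.  In
  reality the penumbra makes the mask a smooth function of aperture size;
  small apertures therefore accumulate slightly less fluence than this
  model predicts.  The binary approximation keeps the engine trivially
  verifiable against a brute-force reference and is sufficient for
  detecting machine-parameter errors, which act through `M` geometrically.
* **No attenuation, no scatter, no MLC transmission** — the volume is MU in
  air, not dose.  Tongue-and-groove, rounded leaf ends, and interleaf
  leakage are likewise out of scope.
* **Inverse-square scaling** `SAD^2/|r-s|^2` is the only depth dependence.
* The in-air profile `F` defaults to a flat unit profile; any callable
  `(u, w) -> intensity` can be plugged in for a measured radial profile.

### Coordinate conventions

Room frame: origin at the isocenter; `+y` is the beam direction at gantry
0, so the source sits at `(0, -SAD, 0)`; `+x` is the X-jaw/MLC travel
direction at all-zero angles; `+z` the Y-jaw direction (couch long axis).
The gantry rotates about `z`, the couch about `y`, and the collimator acts
as a 2D rotation on the projected portal coordinates `(u, w)` — applied
after the divergent projection, so the projection formula holds exactly as
written.  These conventions are self-consistent (verified by the
geometry property tests) but not uniquely determined by the physics; a
different handedness would produce mirrored volumes.

Angles are stored in the signed range (-180, 180] and interpolated along
shortest arcs, since VMAT arcs routinely cross the 0/360 seam.

## Discretization

* **Plan path**: control-point intervals are split so consecutive segment
  centers differ by at most 1 degree of gantry (default).  Within an
  interval all axes — angles, jaws, leaves, meterset — interpolate
  linearly, which is exactly the delivery machine's published behaviour
  between control points.  Each segment carries the arithmetic mean of its
  endpoint states, a proportional share of the interval's MU, and the mean
  of the endpoint source positions (the chord midpoint, which lies inside
  the SAD sphere).  Static-gantry (IMRT) intervals pass through unsplit;
  the interpolation parameter is then the control-point index.
* **Log path**: 20 ms records are merged in groups of 16 (default):
  circular-mean angles, arithmetic-mean jaws and leaves, and an MU
  increment equal to the cumulative-MU step across the group.  Cumulative
  MU is treated as absolute from beam-on, so the increments telescope to
  the delivered meterset exactly.  A trailing partial group is merged the
  same way, conserving MU at any factor.
* **Grid**: cubic, isocenter-centered, 3 mm isotropic voxels, half-extent
  equal to the largest jaw edge plus a 1 cm margin, snapped up to whole
  voxels.

At these defaults the two paths agree to well under the 3% QA criterion:
the dominant residual is the binary mask interacting with the different
bin widths (1 degree vs ~0.77 degrees), which produces isolated
aperture-edge deviations of order one segment's MU (~1/360 of the arc
meterset per 1-degree segment, i.e. a few tenths of a percent of the
maximum, stacking at worst to ~1%).  This is why a noise-free delivery
yields exactly 0% failing rates at the 3% criterion, and why tightening
the criterion much below 1% would start flagging pure discretization.

## The comparison tests

Both tests use **global normalization** to the reference (plan) maximum,
and both evaluate only voxels at or above 10% of that maximum.  The
failing-rate denominator is the number of evaluated voxels — excluded
voxels are excluded from both numerator and denominator.

* Difference test: fail when `|eval - ref| >= 3%` of the reference max.
* Gamma (3%, 3 mm): fail when the minimum of
  `sqrt(dose^2/tol^2 + dist^2/DTA^2)` over the search neighborhood exceeds
  1; a gamma of exactly 1 passes (ties resolved with a 1e-9 relative
  guard).  The search covers a radius of 3 x DTA on a 1/3-voxel offset
  lattice with trilinear interpolation of the evaluated volume; offsets
  are visited in increasing distance with early exit once a voxel's
  current gamma cannot be improved.  Candidates outside the volume are
  excluded rather than extrapolated.

Because the zero-offset gamma candidate *is* the difference-test ratio,
every voxel passing the difference test passes gamma: `F_gamma <= F_I`
structurally at matched criteria.

Verdict: "investigate" when the gamma failing rate exceeds the 5% action
level, else "pass".

The 2D composite baseline (gantry and couch forced to 0, map on the
isocenter portal plane) accumulates control-point-interval segments
without angular up-sampling — with the gantry pinned, the up-sampling
parameter is vacuous — and applies no off-plane divergence scaling.  Both
choices make the map exactly invariant under gantry perturbations, which
is the structural blindness the 3D method is designed to remove.

## Error simulation

Tolerances and distributions follow linac QA practice: gantry 1 deg, MU
1 MU, jaw 1 mm, collimator 1 deg (all uniform), MLC 2 mm (Gaussian).
Within-tolerance draws are signed magnitudes in [0, tolerance]; the MLC
Gaussian uses sigma = tolerance/2 truncated at the tolerance (the sigma is
a package choice; only the family was prescribed).  Out-of-tolerance
draws are signed uniforms on the published ranges (gantry/collimator
1-2 deg, MU 1-2 MU, jaw 1-2 mm, MLC 2-3 mm).  Errors are injected into
plans per control point; MLC shifts touch only open leaf pairs inside the
Y-jaw window (leaves that actually shape fluence), and bank crossings
caused by a shift are clamped closed.  MU errors perturb the per-interval
meterset increments (clamped at zero) with the cumulative weights rebuilt,
keeping the plan's monotonicity invariant.

`sensitivity_sweep` normalizes error magnitudes to percent-of-tolerance
and reuses one unit-scale draw per replicate across all levels (common
random numbers).  Draws scale exactly linearly with the level — including
the truncated Gaussian, whose rejection pattern is scale-invariant — so
the mean failing-rate curves are monotone up to the physics rather than
the sampling, and far fewer replicates are needed for a stable shape.

## The synthetic fixtures

The generator emulates the delivery regime the method targets: 360-degree
arcs with 91 control points (4 degrees per control point), ~600 MU per
arc, 10 cm jaw fields, delivered in 2 minutes (6000 records at 20 ms);
multi-arc plans alternate rotation direction and split the meterset
evenly.  Four leaf patterns are provided: `open`, a seeded
`sliding-window` sweep (~2.5 cm window, leaf speeds ~0.2 cm/s, well within
machine limits), a smoothed `random-leaf` walk, and `closed-junction`
(closed pairs parked inside the open field — the classic planning defect
this QA class catches).  Matched logs trace the plan's linear
inter-control-point trajectories at constant dose rate, with optional
zero-mean Gaussian tracking noise per axis.

What the fixtures do **not** emulate: optimizer-derived modulation,
variable dose rate and gantry speed, beam holds/gating, couch translation,
and any dosimetric realism.  Passing tests therefore demonstrate the
geometry, bookkeeping, and statistics of the QA pipeline — not agreement
with measured dose.  The log format is fluqa's own documented binary
layout mirroring trajectory-log content; vendor binary formats are read
only through the adapter hook.

## Numerical choices and degenerate inputs

* Accumulation in float64, deterministic segment order (time/control-point
  order); results are bit-reproducible.
* Half-open interval convention `[lower, upper)` at every jaw, leaf, and
  leaf-boundary edge: points exactly on an edge resolve deterministically,
  and a closed leaf pair (zero gap) admits nothing.
* "Behind source" guard at `y <= -SAD + 1e-6 cm`; such points are outside
  every aperture in practice and are masked out of the vectorized path.
* A voxel within 1e-3 cm of the source is a hard error (degenerate
  geometry) rather than a silent infinity.
* All-zero jaws degenerate to a minimal 3-voxel grid; an all-zero
  reference volume is a comparison error, not a 0% pass.
* Leaf-bank crossings within 1e-4 cm are snapped closed; larger crossings
  are rejected.

## Known limitations

* No penumbra/aperture-size correction: fluence near small apertures is
  overestimated relative to reality (by design; see assumptions).
* The 2D composite is a pure portal-plane map without off-plane
  inverse-square scaling; it exists as the comparison baseline, not as a
  standalone QA method.
* Gamma cost grows with the failing fraction (early exit helps only
  passing voxels); grossly mismatched volumes are slower to score.
* Couch translations, jaw tracking during arcs, and pre-trajectory-log
  (50 ms dynalog) formats are out of scope.
* The QA compares machine-reported positions with planned ones: a log that
  misreports the machine state (a known failure mode of log-based QA) is
  invisible to it, which is why this method complements rather than
  replaces measurement-based QA.
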