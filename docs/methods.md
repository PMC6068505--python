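# Methods

This note documents the models, numerical choices and limitations of
`gaze3d`. Units are mm and pixels throughout; the rig frame is the leftmost
virtual camera's frame, right-handed, +Z from the cameras toward the face.

## Geometry model

**Sightlines and the point of regard.** A sightline is the infinite line
through an eye's 3D pupil center and its line-of-sight convergence point
(the modelled intra-ocular point where rays entering the pupil converge).
Because two measured lines in space generically do not intersect, the PoR
is the midpoint of the feet of their common perpendicular; the residual gap
between the feet is carried as a per-estimate quality metric. The feet are
computed in closed form: with line directions a⃗, b⃗ and common normal
n⃗ = a⃗ × b⃗, each foot is the intersection of one line with the plane
spanned by the other line and n⃗ (plane normals n⃗ × a⃗ and n⃗ × b⃗). The
denominators equal ∓‖n⃗‖², so the form is defined exactly when the lines
are not parallel; parallelism is declared at the dimensionless threshold
‖n⃗‖/(‖a⃗‖‖b⃗‖) < 1e−12. Lines are infinite — no clamping to rays. The
closed form is verified against the textbook two-unknown least-squares
solve to < 1e−9 relative over 10⁴ random pairs.

**Stereo reconstruction.** Cameras are pinhole models with rig-frame pose;
images are assumed rectified (corresponding points share rows; distortion
coefficients are carried but must be zero). The pupil boundary is
textureless, so correspondences are resolved by row order: the fitted
image ellipses are intersected with the integer rows both views share and
the left/right chord endpoints paired in x-order. Triangulation is the
midpoint of the two back-projected rays. The spatial pupil circle comes
from a total-least-squares plane (SVD), an in-plane Kåsa algebraic circle
fit, and lifting the center back to 3D; the returned plane normal has
non-negative Z. **Pupil size S is the diameter (2r, mm) of that circle** —
a metric quantity invariant to eye–camera distance, unlike any image-plane
measure. The plane+Kåsa route agrees with a generic 6-parameter nonlinear
circle fit to < 1e−6 mm noiseless and < 2% relative under noise.

## Image feature extraction

Pixel conventions: 0-based, x = column, y = row, width m, height n.

**Eye localisation.** Smoothed row/column intensity projections
(gaussian σ = 2% of the dimension); the dark pupil is the joint projection
minimum; a flat profile (peak-to-peak < 5 gray levels) means no eye.

**Adaptive gradient edge map.** Central-difference gradient magnitude
G = √(Gx² + Gy²); amplitudes zeroed in a center margin and four corner
margins (default 5% of each dimension — the sizes are not fixed by the
procedure's description, so they are configurable); within each block of a
3×3 partition only values above the block mean *of the surviving non-zero
values* are kept; amplitudes zeroed inside the specular-spot mask
(components ≥ gray level 250, dilated by a Euclidean disk of radius 3 px);
finally a pixel is retained iff its 3×3 neighborhood sum exceeds 0.6 × the
global mean neighborhood sum. The printed form of that threshold is
typographically ambiguous (a stray ×6 in the denominator); the global-mean
reading is implemented, and a literal per-pixel re-implementation in the
test suite must agree bit for bit — the production code therefore uses the
same fixed shift-add summation order as the literal loop.

**Two-step ellipse fit.** Step 1: RANSAC with 5-point minimal conic
samples, metric (orthogonal) point-to-ellipse inlier distance at 1.5 px,
at most 500 iterations with the standard adaptive trial bound (99.99%
confidence), MSAC consensus scoring (truncated squared distance — it
separates occluder/arc mixtures that tie on raw counts), rejection of
candidates whose center falls outside the edge-cloud bounding box (+25%),
and two local refinement passes of the consensus fit. Step 2: points
farther than A/8 (one eighth of the consensus major axis) from the
consensus ellipse are discarded and a final least-squares conic fit is run
on the survivors. Ellipses are canonicalised to A ≥ B, α ∈ (−π/2, π/2].
The metric point-to-ellipse distance is solved by safeguarded bisection on
the first-quadrant foot angle (60 iterations, ~1e−12·A accuracy) — the A/8
rule is a metric rule, not an algebraic-residual rule. The RANSAC seed is
an explicit argument; the underlying conic solver is
`skimage.measure.EllipseModel` with a direct SVD conic fallback for
exactly-circular data.

**Inner corner.** Harris responses at scales σ ∈ {1, 2, 4} px,
scale-normalised by σ² and combined with weights {0.5, 0.3, 0.2}; the
arg-max (restricted away from crop and frame borders by 16 px = 4·σ_max,
where gaussian edge artefacts live) is refined to sub-pixel by a 2D
quadratic fit on its 3×3 neighborhood. A peak below 1e−6 (images scaled to
[0, 1]) means no corner. The corner search region is found by threshold
segmentation of the eye box (largest dark component outside the pupil
crop).

## Convergence-point calibration

Per board placement the four fixations share one distance, hence one pupil
size and one convergence pair. The initial guess per eye is the mean of
the four pupil centers plus 10 mm on +Z (into the eyeball — the anatomical
prior for the convergence depth). The search region is a 4 mm cube around
each initial point, the lattice step starts at 0.2 mm, and each round
keeps the best candidate and halves both the cube and the step,
terminating when the step drops below 0.0005 mm — nine rounds. A 4 mm cube
at 1 mm step enumerates (4+1)³ = 125 candidates; the default schedule has
21³ per cube per round.

Candidates are scored by `exp(−TotalGap/Dispersion − ShapeError/ε)` with
ε = 10: TotalGap is the sum of the four sightline gaps, ShapeError the
summed absolute deviations of the four *consecutive* cross-to-cross PoR
distances from L = 150 mm (the diagonal is never used), and Dispersion the
RMS (uncentered second moment, n−1 divisor) of the shape errors of all
candidates in the current evaluation pass. The square root makes the first
exponent dimensionless. A zero dispersion with a positive gap scores 0 by
convention. Ties resolve to the lowest lattice index; the search contains
no randomness, so identical inputs give identical outputs.

**Coupling of the two cubes.** The objective is joint in (P_L, P_R). The
exact Cartesian product of the two default lattices is ~8.6×10⁷ pairs per
round, so the default is block alternation: optimise the left point over
its lattice with the right point held, then the converse, iterated to a
fixed point (cap 8) within each round. `search_mode="product"` evaluates
the exact product and is intended for coarse lattices (guarded by
`max_product_pairs`).

**Intrinsic recovery floor (important).** The objective's global optimum
is the true pair and is isolated, but its basin is a narrow curved valley:
residual slopes are ~300–900 mm/mm across the valley versus ~0.1–0.3 along
it (the across/along ratio is set by the target-distance to
convergence-offset leverage, d/10 ≈ 40–120, squared through the vergence
triangulation). Near-optimal "compensation" pairs with sub-millimetre
residuals surround the optimum, and at any lattice step st the nearest
on-lattice point to the truth scores far worse than such compensation
points. Consequently *any* shrinking-lattice argmax with the prescribed
cutoff stalls at roughly (slope ratio)·st_min ≈ 0.3–3 mm from the planted
pair — confirmed empirically for alternation, shared-displacement,
symmetric/antisymmetric and beam variants. The package keeps the plain
alternation default (empirically the best and the simplest). Downstream,
the pupil-size polynomial amplifies this floor: depth errors of the final
PoR reach centimetres at metre range, which is exactly the error regime
such devices exhibit in practice. Tests and the acceptance script report
these figures honestly rather than asserting unreachable precision.

## Corner-vector alignment

The eye coordinate system has its origin at the right inner corner and rig
axes (pure translation); the corner vector is v = left − right (the sign
is a convention fixed package-wide). A calibrated convergence point is
stored as the minimal (geodesic) rotation carrying v₀'s direction onto the
origin→point direction plus the vector norm. The rotation between two
vectors is 1-DOF underdetermined; the minimal rotation (about u⃗ × w⃗, by
the enclosed angle; for anti-parallel inputs π about a deterministic
orthogonal axis) is the only canonical continuous choice. Transfer to a
new frame applies R′ = minimal_rotation(v₀, vᵢ) to the stored vector and
rescales to the stored norm: P = O_E′ + R′(R_e v₀)·‖v_e‖/‖R′R_e v₀‖. Note
the operator order — the corner rotation acts on the *calibrated
convergence vector*; this is the unique order that is exact under rigid
motions composed of translations and minimal corner-vector rotations
(verified to < 1e−9 mm over 10³ random frames) and preserves the stored
norms identically. Head roll about the corner vector leaves vᵢ unchanged
and is therefore unobservable — a model property asserted by the suite,
mitigated in hardware by restricting head pitch/roll.

## Pupil-size model

Per eye, ordinary least squares: Z on (1, S, S²) first (depth is the
coordinate sensitive to pupil size), then X on (1, Z) and Y on (1, Z) —
the calibrated points lie essentially along a spatial line parametrised by
depth, and a 3D line (X₀,Y₀,Z₀,m,n,p) reduces to exactly these two scalar
line equations. Each eye uses its own pupil size. Calibration samples are
one (S, point) pair per placement per eye, with S the mean of the four
fixations' sizes. Fewer than 3 placements or all-equal S is an error;
constant depth degenerates the lines to intercepts. Prediction outside the
calibrated S range (±10% of the range, configurable) logs a warning but
proceeds. Both per-frame estimates and window averaging
(`average_por`) are exposed, since pupil size fluctuates frame to frame.

## Synthetic rig

The generator's defaults are the study conditions: inner corners 28 mm
apart ~74 mm in front of the cameras (the folded mirror path), targets at
negative Z (in front of the face, beyond the device), five board
placements at {400, 600, 800, 1000, 1200} mm with 150 mm cross spacing,
pupil diameter rising linearly from 2.2 mm at 400 mm to 4.6 mm at 1200 mm
(near-triad miosis: the pupil constricts for near targets under fixed
illumination), planted per-eye convergence laws with dZ/dS < 0 over that
range, a fixed 10 mm convergence→pupil offset matching the search prior,
and Gaussian feature noise (σ in mm, also applied to S) drawn from one
seeded generator per session. Exact sightlines contain their targets by
construction to 1e−12.

The renderer projects the 3D pupil and iris circles through the pinhole
cameras (the projected boundary is fitted with an exact ellipse as ground
truth), fills them with soft 1-px edges over a flat sclera, adds an
eyelid-corner wedge whose only sharp junction is the apex (radial fade),
an optional occluding eyelid wedge over the pupil top, optional saturated
specular spots, and Gaussian pixel noise. It does **not** model corneal
refraction (the gaze model has no cornea), eyelashes, iris texture,
illumination gradients or motion blur — so passing image-level tests shows
the pipeline's correctness on clean dark-pupil geometry, not robustness to
every real-world artefact. Reference camera constants: 22 mm baseline,
640×580 px, 600 px focal length (3.6 mm lens at 6 µm pitch).

## Problem sizes and determinism

Default test and acceptance runs use: 10⁴ random line pairs for the
closed-form oracle, 20 single-placement sessions for recovery, one
five-placement session (12 held-out fixations) for the noiseless
end-to-end run, three distances × 20 fixations for the noise-anisotropy
run, four 64×64 images for edge-map bit-equivalence, and a handful of
full-resolution renders for detection accuracy. All randomness flows
through explicit seeds; the detector's RANSAC stream is treated as a fixed
algorithm parameter while data seeds vary.

## Known limitations

* Convergence-point recovery is floor-limited (see above); absolute PoR
  depth at metre range is centimetre-grade. The depth/lateral error
  anisotropy (Z ≫ X, Y) is robust and reproduced under noise.
* The winning score is renormalised per round (Dispersion is a
  region statistic), so scores are comparable within a round but not
  monotone across rounds.
* Pupil-size → depth requires strictly fixed illumination; luminous
  targets (screens) break the accommodation law by construction.
* The alignment transfer is exact only for the motions the corner vector
  can observe; roll about it is invisible.
* Rectification is assumed given; lens distortion is not undone here.
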