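# Methods

## The measurement problem

Two volumetric scans of the same bone, taken weeks apart, are to be
overlaid so that remodelling — apposition and resorption at the surface —
can be read off as a signed distance between the two bone surfaces.  The
overlay must be anchored to structures growth does not move; here those
anchors are small (1 mm) spherical metallic implants seated in a stable
region of the bone.  The package implements two superimposition routes
and the measurement apparatus around them.

## Fiducial detection

Markers are far brighter than bone.  Detection thresholds the volume at a
metal level, takes 26-connected components, and filters by

* volume: within `(1 ± tol)³` of the analytic sphere volume `(π/6)d³`
  (default `d = 1 mm`, `tol = 0.6`), with single-voxel components always
  rejected (noise speckle passes the lower volume edge once voxels exceed
  ~0.38 mm);
* sphericity: `π^{1/3}(6V)^{2/3}/A ≥ 0.6`, computed from the voxelised
  volume and exposed-face area — cheap, rotation-invariant, and excludes
  wire-like metal fragments.

The default metal level sits midway between the bone level and the
lattice maximum.  The bone level is the *median* of the bone class: at
coarse voxel sizes the partial-volume shell drags the mean ~20 % low,
which collapses the threshold into bone noise.  Each retained component
is localised by a centroid weighted with the *squared* intensity excess
over the threshold: weighting reads the partial-volume shell
(sub-voxel accuracy), and squaring emphasises the blob's peak over its
rim, whose voxel-in/voxel-out truncation is the main residual bias.
Measured accuracy at the nominal conditions (0.3 mm voxels, blur σ
0.3 mm): ≤ 0.2 voxel worst-case without noise, ~0.1–0.25 voxel at noise
σ = 5 % of bone–background contrast.  Detection is physically marginal
once blur σ and voxel size both reach ~0.45 mm — the blurred sphere peak
then sits only ~50 % above bone — so studies at that scale need a sharper
reconstruction kernel or larger markers.

Markers are labelled `m1..mN` by sorted world coordinates; since
labelling is position-based, correspondence across time points goes
through the exhaustive matcher (all permutations scored by the rigid-fit
residual; exact for the ≤ 8 markers supported).

## Implant-based superimposition and stability

The rigid fit is the closed-form least-squares solution (centroid
subtraction, SVD of the cross-covariance, smallest singular direction
negated if a reflection would otherwise result).  Its fiducial
registration error (FRE, RMS residual) is ~0.05 mm at nominal conditions.

A displaced implant (the classic failure: tooth eruption carries a marker
with it) is detected by a leave-one-out diagnostic.  Plain leave-one-out
— fit on the others, report the prediction error — is not enough: the
displaced marker contaminates every fit that includes it, smearing
~0.3–0.6 mm of apparent displacement onto good markers.  The diagnostic
therefore greedily removes the worst marker above the flag threshold
(default 1.0 mm — the marker diameter; genuine implant failures of
~1.6 mm clear it, observation noise of < 0.2 mm does not) and refits
until the remaining set is self-consistent; final per-marker estimates
are computed against that consistent subset.  Markers flagged this way
are excluded from the final rigid fit.

## Intensity-based route

The affine stage minimises the mean-squared intensity difference over a
three-level pyramid (exact strided subsampling after Gaussian smoothing,
so coarse lattices keep exact geometry).  The coarsest level optimises
translation only — a full 12-parameter affine on a coarse, nearly
symmetric object can over-fit shear — and finer levels run L-BFGS on the
analytic metric gradient with matrix parameters preconditioned by the
content radius, step control by line search.  A known limitation: on
noise-free, mirror-symmetric synthetic images the affine MSE landscape
has near-degenerate shear directions and the fit can settle 0.1–0.3 mm
off; under realistic imaging noise (σ = 5 % contrast) recovery is
0.05 mm / 0.5 % scale.  Intensity-route tests therefore run at the
nominal noise level.

The nonrigid stage is additive demons: per-voxel force
`−diff·∇M / (|∇M|² + diff²)`, Gaussian smoothing of the update (σ 1.0
voxel) and of the accumulated field (σ 1.5 voxels), two pyramid levels.
An iteration is accepted only if the metric strictly decreases, so the
metric is monotone over accepted iterations; a sustained rise raises a
divergence error carrying the iteration trace.  The returned field lives
on the follow-up (fixed) grid and maps follow-up points into baseline
space, composed with the affine; warping the baseline *mesh* into the
follow-up frame therefore uses the fixed-point inverse (10 iterations,
0.01 voxel tolerance).  Recovery at nominal conditions: ≤ 0.1 voxel mean
endpoint error for a 1.5-voxel translation, ≤ 0.15 voxel inside the bone
for a smooth 2-voxel bump.

Warped baseline meshes are aligned to their pre-warp configuration by
ordinary Procrustes (correspondence is free — warping preserves vertex
identity).  Scaling is enabled by default and the scale factor is
reported prominently: scaling absorbs true size growth, which is exactly
why this route shows less remodelling than the implant route and why its
biological reading is limited.

## Surface measurement

Surfaces come from marching cubes; binary masks are Gaussian-smoothed
(σ 0.5 voxel) first to remove the voxel staircase, and the lattice is
padded with one background voxel so objects clipped by the field of view
still yield closed meshes.  Meshes are oriented outward (positive signed
volume); volume uses the divergence theorem (sum of signed tetrahedra),
invariant under rigid motion.

Per-vertex distances are exact vertex-to-*triangle* minima (unbiased when
mesh resolutions differ): a k-d tree over target vertices gives an upper
bound per query, a second tree over triangle centroids plus the largest
centroid-to-corner radius prunes the candidate set, and the exact
point-triangle kernel runs on the candidates — provably equal to the
brute-force all-triangles scan, which the tests also run.  The Hausdorff
distance and the directional mean minimum distances are vertex-sampled at
mesh resolution; the directional mean is the unweighted vertex mean
(an area-weighted variant is available by flag).

The remodelling sign convention is anchored to the baseline outward
normal: positive (red) where the follow-up surface lies outside the
baseline surface.  Where remodelling is large relative to the local
feature size (the condyle growing by about its own radius), the nearest
point can land on the far side of the structure and flip the sign; for
such cases the sign can instead be taken from volumetric containment in
the follow-up bone mask (`signed_distances(..., containment=mask)`),
which stays well-posed.  The colour export renders |value| ≤ 0.2 mm
green — below the registration noise observed in simulation, so
registration error is not displayed as growth.

## The phantom

The synthetic subject is a mandible-like solid — an elongated
superellipsoid body, a boxier vertical ramus slab, a spherical condylar
knob — at bone intensity 1000 on background 0, with metal spheres at
3000 (arbitrary units; only the rank order matters).  Defaults: 96³
voxels at 0.3 mm (a ~29 mm scene), blur σ 0.3 mm, additive Gaussian
noise σ 50, five markers placed where real implants go (symphysis,
lateral/posterior molar region, upper body) — all in the growth-stable
zone, spread in all three axes so the rigid fit is well-conditioned.

Growth is an analytic, closed-form map: a vertical smoothstep stretch
ramping from z = 12 mm to full amplitude at z = 20 mm (condylar growth,
default 2 mm) plus a posterior smoothstep stretch from y = 14 mm to 19 mm
(ramus apposition, default 1.5 mm).  Each ramp depends only on its own
coordinate, so the Jacobian is diagonal, the divergence is non-negative
everywhere (pure expansion), the molar region displacement is *exactly*
zero, and the inverse map (needed to render the follow-up volume) is a
convergent fixed-point iteration.  The follow-up adds a rigid pose change
(sampled about the volume centre with rejection of poses that push bone
out of view) and a fresh noise realisation; optionally one marker is
displaced by a configured offset to emulate implant failure.  All
randomness flows from one seed; identical seeds give bit-identical
volumes.

What the phantom does not emulate: beam hardening and metal artefacts,
anatomically accurate geometry, spatially correlated CT noise, and
non-affine motion between acquisition and reconstruction.  Passing tests
therefore demonstrate the correctness and noise behaviour of the
measurement chain, not robustness to scanner physics.

## Simulation studies and problem sizes

`bonemorph.studies` packages three seeded end-to-end studies, which the
acceptance script and test suite share:

* **Registration-error bound** — 20 pairs at nominal conditions differing
  only by rigid pose + noise; the maximum over pairs of the mean minimum
  surface distance after implant superimposition is ~0.08–0.1 mm, an
  order of magnitude inside the 1 mm acceptance bound.
* **Displaced implant** — one marker offset 1.6 mm: it is the only flag
  at the 1 mm threshold and its displacement is estimated within 0.1 mm.
* **Growth recovery** — estimated signed surface displacement vs the
  analytic truth (the same signed-distance measure taken against the
  noise-free grown surface, both with containment signs): correlation
  ≈ 0.97–0.99.

Pose recovery itself is accurate to < 1° rotation and < 0.03 mm
translation at the fiducial centroid; the rotation figure is limited by
the deterministic sub-voxel centroid bias of 3–5-voxel marker blobs
amplified over a ~4 mm lever arm, not by image noise (it is unchanged
between σ = 2 % and 5 % contrast).

Smaller lattices (64³ at 0.45 mm, or 48³ at 0.6 mm for the registration
unit tests) are used where full resolution adds nothing; these sizes keep
the whole suite at about 1–2 minutes on one CPU.

## Degenerate inputs and numerical choices

Fewer than 3 markers: no rigid fit (error); 3 markers: stability falls
back to full-fit residuals with a warning.  Collinear marker
configurations are rejected (rank < 2).  Empty masks from an
over-threshold are a warning, not an error.  Open meshes refuse volume
computation and report their boundary-edge count.  All registrations are
deterministic given inputs and configuration — no random initialisation
anywhere; ties in marker matching break lexicographically.
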