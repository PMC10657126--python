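# Methods

This note records the models, algorithms and numerical choices behind
`fdpfit`, and what the synthetic validation does and does not demonstrate.

## Geometry, units, conventions

All meshes are interpreted in millimetres (STL itself is unitless);
marginal discrepancies are reported in micrometres. Coordinates are
right-handed with no imposed axis convention — every operation is rigid
and convention-free. Meshes are welded on load (exact-duplicate merge at
1e-6 mm, four orders of magnitude below scanner accuracy) because
edge-adjacency analysis requires shared vertex indices; representatives
keep their original order so that an already-welded mesh round-trips with
identical indices, which keeps vertex-index region masks valid across
save/load.

## Phantom model

The phantom replaces the physical model/prosthesis pairs of a bench study.
Each preparation is a surface of revolution: cervical skirt, flat annular
90° shoulder (outer radius *r* = 4 mm, width *w* = 1 mm), axial wall
tapering at 6°, occlusal table at height 4 mm; both preparations stand on
a plate that provides the unchanged scan context. The crown is a closed
shell whose intaglio offsets the preparation by the cement gap
(*g* = 0.05 mm, the usual CAD design value) and whose margin edge sits at
radius `r + Δ(θ)` and height `v(θ)` above the shoulder plane; a bar pontic
joins the two crowns. The ground-truth AMD at azimuth θ is therefore
`√(Δ(θ)² + v(θ)²)` — defined on the analytic margin curves before meshing,
hence exactly invariant to pose, resolution and noise settings.

Defaults: 192 angular samples (margin chord sagitta ≈ 0.5 µm, far below
the discrepancies of interest), three subdivisions per profile segment.
Scanner error is modelled as i.i.d. Gaussian displacement along vertex
normals, independently per dataset, with sd 0 by default and 0.02 mm when
emulating a 20 µm-accurate scanner. This is deliberately the simplest
model: real scanner error is spatially correlated and partly systematic
(patch stitching, reflectance), and real margins carry fabrication
roughness; passing the phantom suite therefore demonstrates the
*measurement chain* is unbiased and well-calibrated, not that any
particular scanner achieves these numbers. One integer seed drives all
stochastic elements through named substreams, so every dataset is
reproducible byte-for-byte.

## Registration

Coarse alignment solves the orthogonal Procrustes problem (SVD with the
determinant correction, so a reflection-optimal configuration still
returns a proper rotation) on ordered landmark correspondences — the
reproducible stand-in for interactive point picking. Refinement is
point-to-point ICP: nearest neighbours in the target vertex set via a k-d
tree, optional trimming of the worst fraction, optional absolute distance
gate, convergence when the RMS residual improves by less than 1e-6 mm
(well below scanner accuracy) or after 100 iterations. The residual
history is non-increasing by construction: an iteration whose
correspondence switch would raise the trimmed objective terminates the run
at the previous best. Point-to-point is the canonical reading of a
"best-fit" module; point-to-plane converges faster on smooth surfaces but
needs reliable normals, which noisy margins don't offer.

Seating is reconstructed by two pairwise alignments — seated → abutment on
the unchanged-context region, prosthesis → seated on the external
prosthesis surface — composed into one transform that carries the
prosthesis scan (with its hidden margin and intaglio) into the abutment
frame. Which regions anchor each alignment is supplied as vertex-index
masks (emitted by the phantom generator, or user files for real scans)
because the choice is inherently scan-specific.

## Margin extraction

"Edge sharpening" is realized as the dihedral-angle operator: an interior
edge is a feature edge when its adjacent face normals differ by more than
30° (a 90° shoulder crease clears this comfortably; axial-wall curvature
at the default resolution stays far below it); boundary edges always
count. Feature edges are chained into polylines and closed chains become
candidate loops; the margin is selected among closed loops whose mean
height along the retainer axis falls within ±0.75 mm of the expected
margin level, as the one with the greatest mean radius — the *outer*
shoulder edge, which is the AMD landmark, as opposed to the inner shoulder
edge or wall creases. Two candidates within 1 µm of mean radius raise an
ambiguity error rather than guessing.

Two choices depart from a textbook crease chaining and exist for noise
robustness:

- **Straightest continuation.** At a vertex where more than two feature
  edges meet, the walk continues along the straightest unused edge if the
  turn is below 60°, else the chain ends. On clean meshes this reduces to
  splitting at branches (perpendicular creases never continue into each
  other), while on noisy scans it traces the margin straight through the
  short spurious stubs that noise hangs onto it. Open chains whose
  endpoints fall within a configurable gap (default 0.2 mm) are stitched
  greedily by increasing endpoint distance, each endpoint joining at most
  once.
- **Detection on a denoised copy, coordinates from the raw mesh.** Surface
  noise of 20 µm at ~0.13 mm edge length tips dihedral angles past any
  usable threshold, so edge *topology* is detected after a few Taubin
  smoothing passes (default 3; shrink-compensated). Measuring on the
  smoothed mesh would be wrong — smoothing rounds the crease and pulls the
  margin ring inward by ~0.15 mm, an order of magnitude above the effects
  being measured — so loop coordinates are always taken from the raw
  vertices via the shared indexing.

Selected loops are arc-length resampled to 720 points and lightly smoothed
with a circular moving average (window 5; the induced radial flattening of
a 4 mm circle is ~0.1 µm and cancels between the two loops).

## AMD sampling and summary

The central axis of a retainer/abutment pair is the normal of the margin
loop's best-fit plane through its centroid, oriented toward the
preparation's far centroid (its bulk lies occlusal to the margin); θ = 0
is the projection of the global +x axis, tie-broken to +y, which makes
runs deterministic. 25 axial sections give 50 half-planes at exactly 7.2°;
both margin loops are intersected with the *same* fan built on the
abutment's axis, so the 50 point pairs correspond by shared radial
half-plane — the only pairing consistent with the sectioning construction.
Each crossing segment is interpolated linearly; multiple crossings on one
half-plane keep the outermost point (the landmark is the outer edge) and
are counted; azimuths without a crossing are marked missing and excluded
from summaries rather than imputed, with the count always reported.

The AMD per azimuth is the straight-line 3D distance of the pair × 1000.
A retainer is clinically acceptable when its mean AMD is strictly below
120 µm; the fraction of azimuths individually exceeding the threshold is
reported alongside. A prosthesis is summarized by default as the
unweighted mean of its retainer means (each retainer's seat matters
equally for a multi-unit prosthesis); a pooled-distances rule is provided
as the alternative when retainers have unequal valid counts.

## Statistics

Descriptives use the sample sd (n−1) and exact Student-t 95% CIs — these,
not z-based bounds, reproduce printed small-sample tables. One-way ANOVA
is available from raw values and from `(n, mean, sd)` summaries; the two
paths are algebraically identical when the summaries come from the raw
data (property-tested to 1e-9), and reproducing a printed table from its
rounded summary inputs carries last-digit discrepancies of a few tenths of
a percent. Levene's test centers on the mean by default (classic Levene),
with the median (Brown–Forsythe) available. A vectorized Monte-Carlo
driver verifies the type-I error of the ANOVA path under equal-mean
normal groups.

The study layer analyzes one AMD value per prosthesis (retainer means are
not independent replicates), and its phantom group generator draws each
prosthesis's true misfit from a normal distribution with the group's mean
and sd, realized as a uniform horizontal extension with independent random
poses per dataset — fabrication variation between prostheses dominating
measurement error, which is the regime such studies assume.

## Numerical and degenerate-input policy

Malformed binary STL (declared facet count vs file length) fails with the
byte offset; empty meshes, collinear landmark sets, sub-minimum group
sizes, fans below 8 sections and fully-missing profiles raise typed errors
rather than propagating NaNs. Vertices exactly on a section half-plane are
nudged by 1e-300 so crossings are well-defined. Rigid-motion invariance of
the full pipeline holds to ~1e-4 µm (limited by ICP stopping, not by the
geometry), orders of magnitude below any quantity of interest.

## Problem sizes used in validation

The shipped tests and the acceptance script run phantoms at the default
192-angle resolution for single-prosthesis checks, 20 noise seeds for the
noisy-recovery bias, 96-angle phantoms for multi-pipeline study tests, and
10 000 replicates for the ANOVA calibration — sizes chosen so the entire
validation completes in minutes on one core while keeping every Monte-
Carlo interval decisively narrower than the property being asserted.

## Known limitations

- Margin detection targets shoulder-type finish lines; chamfer and
  knife-edge margins lack a sharp crease and would need curvature-based
  salient-line detection.
- Correspondence by shared azimuth assumes margins star-shaped about the
  axis; strongly scalloped anatomical margins can produce multiple
  crossings, which are resolved outermost but counted, not modelled.
- The noise model is uncorrelated and Gaussian; scanner-specific artefacts
  (stitching drift, edge rounding of the optics) are out of scope.
- Non-rigid deformation (e.g. prosthesis flexure during seating) is not
  modelled; all alignments are rigid with no scale estimation.
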