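# Methods

## The phantom

Each vertebra is a stylized watertight solid: a sagittal profile — a
vertebral-body block (14 × 44 mm, 1 mm top bevel) carrying a 120 mm dorsal
blade that stands in for the dorsal spinous process — extruded 40 mm
mediolaterally, then tapered so the blade narrows to a 10 mm-wide tip and
sheared 2.5 mm at the tip so the most craniodorsal vertex is unique in all
three coordinates. The blade leans cranially (taper 0.08 per mm of height),
making the tip the cranial extreme of the dorsal region. No anatomical
realism is attempted: every downstream computation (thresholding, marching
cubes, ICP, landmarks, Hausdorff) is geometry-generic, so a stylized shape
validates the pipeline as well as an anatomical one — that is precisely
what passing tests do and do not show about real data (see Limitations).

The resting chain must satisfy two observed facts simultaneously: adjacent
craniodorsal landmarks 39.9 mm apart (eight spaces) and a straight-line
T11→L1 landmark distance of 310 mm, which is *less* than 8 × 39.9 =
319.2 mm. The template therefore lays the landmarks on a circular,
dorsally convex arc whose per-joint bend angle is solved (Brent) so the
chord equals the target length; gaps are exact chords, so both defaults
hold to machine precision. The consequence is a real arc (~6.6° per joint,
end vertebrae tilted ~26°) whose geometry constrains the body block: at
142 mm below the landmarks the arc radius shrinks so bodies sit only
~24 mm apart, bounding the body length.

A fixed cranial→caudal gradient of per-space gap offsets (+1.5 … −1.5 mm,
summing to zero) reproduces the observed non-homogeneity of inter-DSP
spacing along the segment; it is what the repeated-measures space factor
detects.

## Articulation and ground truth

Joints rotate about the mediolateral (y) axis at a pivot on the
vertebral-body centre line (ventral offset from the DSP tips =
blade height + half body height; the centre of rotation is not otherwise
determinable and is configurable). Vertebra *i* carries the composed
product of joints 1…i−1, cranial-most outermost; T11 is the fixed root.
Flexion *decreases* inter-DSP distance and extension increases it — the
loading-rig reading of the phases; a `swap_phase_labels` switch reproduces
the opposite labelling, which some summary tables suggest. Desmotomy
multiplies only the flexion amplitude: transecting the ligament releases
tension (flexion separates the ligament's attachment points here) but
cannot add motion when the processes are pressed together.

Default amplitudes are calibrated once by bisection on the template
(`scripts/calibrate_defaults.py`): flexion 3.604° and extension 3.620° per
joint split the 17.9 mm pre-desmotomy mean per-space ROM evenly, and the
desmotomy flexion multiplier 1.624 raises it to 23.5 mm. With a ~143 mm
lever arm these are millimetre-scale tip motions per joint.

Each articulation also returns exact ground truth — per-vertebra rigid
transforms, landmark positions, inter-DSP distances, total length — which
is self-consistent to 1e-9 mm and serves as the oracle for the whole
measurement pipeline.

A note on global motion: because eight joints each rotate several degrees,
L1 rotates ~55° between flexion and extension and its centroid travels
>100 mm. In cadavers the same per-space ROM coexists with far smaller
global rotations (~12°), because real inter-DSP change is not purely joint
rotation about a ventral pivot (ligament stretch, translation and facet
kinematics all contribute). A rigid kinematic chain cannot reproduce both
scales at once; this package calibrates to the per-space ROM and reports
the global metrics as computed.

## Specimen sampling

Seven specimens per study (the study design), drawn deterministically from
one seed: specimen-level resting-gap shift (SD 2.84 mm, the observed
between-section spread), per-space jitter (SD 0.5 mm), overall size scale
(SD 3%), and a common flexion/extension amplitude scale (SD 17%, chosen so
the between-specimen ROM SD is ≈3 mm pre / 4 mm post as observed). Draws
whose articulation would bring bones into contact in any phase are
rejected and redrawn — a cadaver cannot occupy such a configuration. The
curvature target scales with the summed gaps so all specimens share the
template's chord-to-length ratio.

## CT emulation

Voxelization uses an even-odd column rasterizer: each triangle's
z-crossing toggles the fill state of its (x, y) sample column, exact for
watertight meshes; occupancy fractions come from 3× supersampling per axis
(partial volume). A voxel's HU is the occupancy-weighted mix of bone
(1500 HU) and context — soft tissue (40 HU) within a 30 mm dilation of
bone (the musculature stand-in, computed by Euclidean distance transform),
air (−1000 HU) beyond. All stochastic texture (bone SD 150, soft SD 30,
scanner noise SD 20) is one zero-mean Gaussian whose SD is the same
occupancy-weighted mix plus the noise term; with all SDs zero the
rendering is bit-deterministic, which the oracle tests use. Slice-overlap
reconstruction schemes are scanner-internal and not modelled; spacing is a
free parameter, default 0.5 mm isotropic for single volumes and 2 mm for
full studies (42 volumes per study; at 2 mm one study runs in ~2 minutes,
and all tolerance checks scale with the voxel diagonal). Volumes are
NIfTI/MetaImage; DICOM dialects are out of scope.

## Segmentation

Bone mask: +700 ≤ HU ≤ +3000, both ends inclusive. Connected components
(26-connectivity) above a voxel floor are relabelled cranial→caudal by
centroid. When the component count misses the expected vertebra count, one
binary opening (3³) is tried first; if vertebrae remain bridged (partial
volume at coarse spacing — the situation resolved manually in commercial
suites) they are split by progressive erosion until the expected cores
appear, each mask voxel then joining its nearest core. Surfaces are
marching cubes at iso 0.5 of the binary label after a 2-voxel morphological
closing (the "wrap" stand-in), vertices in physical mm (voxel centres at
0-based index × spacing + origin), followed by Taubin λ/μ smoothing
(volume-preserving within 1%). Ribs are simply not modelled.

## Registration

Kabsch (weighted SVD with determinant correction) is the least-squares
core. ICP samples the moving surface (seeded, deterministic) and matches
nearest neighbours on a dense sampling of the fixed surface by default;
an exact point-to-triangle mode exists where sub-0.01 mm recovery is
asserted. Initialization is centroid + principal axes with the four proper
sign combinations disambiguated by probe RMS. The RMS residual is asserted
non-increasing each iteration; convergence is a residual decrease below
tol (1e-6 mm standalone; the study pipeline uses 1e-4 mm and 200
iterations — differences are ~0.1 mm, far below the voxel). Anchor
superimposition applies each phase's T11 transform to all nine vertebrae,
preserving within-phase relationships exactly (to 1e-9 mm). L1 motion
between flexion and extension is composed through resting, matching how
the phases are superimposed.

## Landmarks

The craniodorsal landmark is the vertex maximizing the cranial coordinate
among vertices in the top `dorsal_fraction` (default 0.4) of the dorsal
extent; ties break by larger dorsal coordinate, then lowest index. Taken
literally in the anatomical frame (`frame="global"`) this is stable only
while a vertebra tilts less than the blade's own cranial lean; the resting
arc exceeds that for the end vertebrae, so the pipeline uses
`frame="pca"`: the vertebra's dorsal axis is its dominant principal
direction (signed toward the thin, tapering end), cranial is global +x
re-orthogonalized, and ranking uses the 45° craniodorsal direction, which
keeps the process tip a strict maximum at any articulation tilt. Both the
generator's ground truth and the measurement path use the same rule, so
the comparison is like-for-like. Only cranial landmarks are used — caudal
prominences are not repeatable measurement points.

Translation components of a rigid motion are reported for the bone's
centroid ((R − I)c + t), since the raw matrix translation depends on the
arbitrary coordinate origin.

## Statistics

Paired pre/post comparisons are gated by Shapiro–Wilk on the differences
(p > 0.05 → paired t, mean ± sd; otherwise Wilcoxon signed-rank, median
and range; exact Wilcoxon distribution for n ≤ 25, normal approximation
with continuity correction above, zero differences dropped). Identical
pre/post vectors short-circuit to statistic 0, p 1 with a warning. Effect
size is the standardized mean paired difference d_z. The two-way
repeated-measures ANOVA (space × condition, subjects = specimens) requires
a complete balanced table and reports Greenhouse–Geisser-corrected
p-values alongside uncorrected ones (sphericity of an 8-level factor is
doubtful); Tukey HSD runs on each factor's levels pooling over the other.
Power is computed from the noncentral-t distribution of the paired test;
sample-size solving returns the smallest integer n reaching the target.
Percent changes are computed per specimen and averaged (primary), with the
group-mean-ratio convention emitted alongside; per-site effects divide the
percent by the eight desmotomy sites. Rounding (1 decimal) happens only at
presentation.

In mesh-direct mode (no CT emulation) a small landmark jitter
(SD 0.1 mm) emulates digitization repeatability; without it, resting
pre/post measurements would be bit-identical and paired error terms
degenerate. The CT path needs no such term — voxelization and
segmentation supply realistic measurement error.

## Problem sizes

Default study: 7 specimens × 2 conditions × 3 phases; CT at 2 mm
isotropic (~2 million voxels per volume, 42 volumes, ~2 minutes); ICP with
3000 surface samples; Hausdorff with 3000 samples plus all vertices.
Statistical calibrations: 2000 null replicates for the paired-test type-I
rate, 500 for RM-ANOVA p-value uniformity, 20 studies for effect-recovery
coverage. These sizes are the package's defaults; single-volume work uses
0.5 mm spacing.

## Limitations

* The phantom is stylized: no anatomical vertebral shape, ribs,
  musculature (beyond a uniform soft-tissue envelope), facet joints, or
  load/stiffness modelling — phase amplitudes are kinematic inputs, not
  responses to the 2000 N load. Passing tests demonstrate that the
  *measurement chain* is correct, not that the phantom predicts equine
  tissue behaviour.
* Global L1 excursion and rotation magnitudes are properties of the rigid
  chain and intentionally not matched to cadaver values (see above).
* The CT model has no beam hardening, scatter or reconstruction kernel;
  HU values are Gaussian mixtures only.
* Between-specimen variability is parametric and modest in dimension;
  real anatomical covariance is far richer.
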