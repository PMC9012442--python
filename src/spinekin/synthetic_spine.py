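"""Parametric articulated spine phantoms with known kinematics.

Generates stylized nine-vertebra thoracolumbar segments (T11..T18, L1 —
eight interspinous spaces) as watertight surface meshes, articulates them
through resting / flexion / extension phases before and after interspinous
ligament desmotomy (ISLD), and records the exact ground truth (per-vertebra
rigid transforms, landmarks, inter-DSP distances) that the measurement
pipeline is validated against.

Each vertebra is a stylized extruded sagittal profile: a vertebral-body
block plus a tall tapering dorsal blade standing in for the dorsal spinous
process (DSP).  The blade leans slightly cranially and narrows to a thin
tip, so the most craniodorsal vertex — the landmark every distance is
measured from — is unique and stable under re-voxelization and surface
extraction.  All downstream mathematics is geometry-generic; anatomical
realism of the vertebral shape is a non-goal.

Default dimensions follow the study conditions: resting inter-DSP spacing
39.9 mm, straight-line T11->L1 length 310 mm (the chain is laid on a gentle
dorsally-convex arc so both hold simultaneously), and joint amplitudes
calibrated so the mean per-space dorsoventral ROM is 17.9 mm before and
23.5 mm after desmotomy.  Flexion *decreases* inter-DSP distance (the
loading-rig reading of the phases); ``swap_phase_labels`` reproduces the
opposite labelling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh
from scipy.optimize import brentq

from . import kinematics, meshdist
from .transforms import RigidTransform, rotation_about_axis, rotation_about_point

__all__ = [
    "SpineTemplate",
    "JointConfig",
    "SpecimenSampler",
    "GroundTruth",
    "SpinePose",
    "build_vertebra_mesh",
    "build_template",
    "articulate",
    "sample_specimens",
    "write_pose",
    "DEFAULT_LABELS",
]

DEFAULT_LABELS = ("T11", "T12", "T13", "T14", "T15", "T16", "T17", "T18", "L1")

# Joint amplitudes calibrated once (scripts/calibrate_defaults.py) so the
# default template's mean per-space ROM is 17.9 mm pre- and 23.5 mm
# post-desmotomy, split evenly between the flexion and extension phases.
DEFAULT_FLEXION_AMPLITUDE_DEG = 3.603881
DEFAULT_EXTENSION_AMPLITUDE_DEG = 3.619882
DEFAULT_ISLD_FLEXION_MULTIPLIER = 1.623903


@dataclass(frozen=True)
class SpineTemplate:
    """Geometry of one spine segment in its canonical resting frame."""

    n_vertebrae: int = 9
    labels: tuple = DEFAULT_LABELS
    # The chain must close a 310 mm chord over 8 x 39.9 mm landmark gaps, so
    # the resting pose is a fairly tight dorsal arc; at DSP-tip depth the
    # vertebral bodies sit on a much smaller-radius circle (~24 mm apart),
    # which bounds how long the stylized body block may be.
    body_size: tuple = (14.0, 40.0, 44.0)  # mm, (craniocaudal, mediolateral, dorsoventral)
    dsp_height: float = 120.0  # mm, dorsal spinous process above the body
    dsp_cranial_taper: float = 0.08  # cranial lean of the blade per mm of height
    blade_base_length: float = 12.0  # mm, blade extent along x at its base
    blade_tip_length: float = 7.0  # mm, blade extent along x at the tip
    blade_tip_halfwidth: float = 5.0  # mm, mediolateral half-width at the tip
    landmark_shear: float = 2.5  # mm, tip shear making the landmark vertex unique
    resting_gap: float = 39.9  # mm, inter-DSP cranial-point spacing
    space_gap_offsets: tuple | None = None  # per-space deviations from resting_gap
    target_total_length: float | None = 310.0  # mm, straight-line T11->L1 distance

    def __post_init__(self):
        if self.n_vertebrae < 2:
            raise ValueError("need at least 2 vertebrae")
        labels = tuple(self.labels)[: self.n_vertebrae]
        if len(labels) < self.n_vertebrae:
            labels = labels + tuple(
                f"V{i}" for i in range(len(labels), self.n_vertebrae)
            )
        if len(set(labels)) != len(labels):
            raise ValueError("vertebra labels must be unique")
        object.__setattr__(self, "labels", labels)
        if min(self.body_size) <= 0 or self.dsp_height <= 0 or self.resting_gap <= 0:
            raise ValueError("all dimensions must be positive")

    @property
    def n_spaces(self) -> int:
        return self.n_vertebrae - 1

    def gaps(self) -> np.ndarray:
        g = np.full(self.n_spaces, self.resting_gap, dtype=float)
        if self.space_gap_offsets is not None:
            off = np.asarray(self.space_gap_offsets, dtype=float)
            if off.shape != (self.n_spaces,):
                raise ValueError("space_gap_offsets must have one entry per space")
            g = g + off
        if np.any(g <= 0):
            raise ValueError("inter-DSP gaps must remain positive")
        return g


@dataclass(frozen=True)
class JointConfig:
    """Kinematic amplitudes of the interspinous joints.

    Flexion and extension rotate each space about its mediolateral pivot
    (placed ``pivot_offset`` mm ventral of the DSP tips, on the
    vertebral-body centre line by default).  After desmotomy only the
    flexion amplitude changes, multiplied by ``isld_flexion_multiplier``
    (the extension phase compresses the transected ligament and is
    unaffected).
    """

    flexion_amplitude_deg: float = DEFAULT_FLEXION_AMPLITUDE_DEG
    extension_amplitude_deg: float = DEFAULT_EXTENSION_AMPLITUDE_DEG
    isld_flexion_multiplier: float = DEFAULT_ISLD_FLEXION_MULTIPLIER
    pivot_offset: float | None = None  # mm ventral of the DSP tip; None -> body centre
    swap_phase_labels: bool = False

    def __post_init__(self):
        if self.flexion_amplitude_deg < 0 or self.extension_amplitude_deg < 0:
            raise ValueError("joint amplitudes must be non-negative")
        if self.isld_flexion_multiplier < 1:
            raise ValueError("isld_flexion_multiplier must be >= 1")


@dataclass(frozen=True)
class SpecimenSampler:
    """Between-specimen variability of the simulated study (7 cadavers)."""

    n_specimens: int = 7
    gap_sd: float = 2.84  # mm, specimen-level resting inter-DSP spacing
    gap_space_sd: float = 0.5  # mm, extra per-space jitter
    amplitude_scale_sd: float = 0.17  # relative, common flexion/extension scale
    body_scale_sd: float = 0.03  # relative, overall vertebra size
    seed: int = 0


@dataclass
class SpinePose:
    """Ordered collection of vertebra meshes for one (specimen, phase, condition)."""

    labels: tuple
    meshes: dict  # label -> trimesh.Trimesh
    phase: str = "resting"
    condition: str = "pre"
    specimen: str = "template"
    joint_pivots: np.ndarray | None = None  # (n_spaces, 3) resting-frame pivots
    template: SpineTemplate | None = None

    def mesh_list(self) -> list:
        return [self.meshes[lb] for lb in self.labels]

    def landmarks(self, dorsal_fraction: float = 0.4, frame: str = "pca") -> list:
        return [
            kinematics.craniodorsal_landmark(self.meshes[lb], dorsal_fraction, lb, frame)
            for lb in self.labels
        ]

    def copy(self) -> "SpinePose":
        return SpinePose(
            labels=self.labels,
            meshes={lb: m.copy() for lb, m in self.meshes.items()},
            phase=self.phase,
            condition=self.condition,
            specimen=self.specimen,
            joint_pivots=None if self.joint_pivots is None else self.joint_pivots.copy(),
            template=self.template,
        )

    def transformed(self, t: RigidTransform) -> "SpinePose":
        out = self.copy()
        for m in out.meshes.values():
            m.vertices = t.apply(m.vertices)
        if out.joint_pivots is not None:
            out.joint_pivots = t.apply(out.joint_pivots)
        return out


@dataclass
class GroundTruth:
    """Exact articulation bookkeeping for one (phase, condition) pose."""

    transforms: dict  # label -> RigidTransform relative to the resting pose
    landmarks: dict  # label -> (3,) mm, after articulation
    inter_dsp: np.ndarray  # (n_spaces,) mm
    total_length: float  # mm
    joint_angles_deg: np.ndarray  # (n_spaces,) signed applied angles

    def check_self_consistent(self, resting_landmarks: dict, tol: float = 1e-9) -> None:
        labels = list(self.landmarks)
        pts = []
        for lb in labels:
            p = self.transforms[lb].apply(resting_landmarks[lb])
            if np.linalg.norm(p - self.landmarks[lb]) > tol:
                raise AssertionError(f"ground-truth landmark mismatch for {lb}")
            pts.append(p)
        d = kinematics.inter_dsp_distances(pts)
        if np.max(np.abs(d - self.inter_dsp)) > tol:
            raise AssertionError("ground-truth inter-DSP distances inconsistent")
        if abs(kinematics.total_length(pts) - self.total_length) > tol:
            raise AssertionError("ground-truth total length inconsistent")


# ---------------------------------------------------------------------------
# mesh construction


def _polygon_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _triangulate_polygon(pts: np.ndarray) -> list:
    """Ear-clipping triangulation of a simple CCW polygon (indices)."""
    n = len(pts)
    if n < 3:
        raise ValueError("polygon needs >= 3 vertices")
    idx = list(range(n))
    tris = []
    guard = 0
    while len(idx) > 3:
        guard += 1
        if guard > 10 * n * n:
            raise RuntimeError("ear clipping failed; polygon may not be simple")
        clipped = False
        for k in range(len(idx)):
            i0, i1, i2 = idx[k - 1], idx[k], idx[(k + 1) % len(idx)]
            a, b, c = pts[i0], pts[i1], pts[i2]
            cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            if cross <= 1e-12:  # reflex or degenerate corner
                continue
            # no other remaining vertex strictly inside the candidate ear
            ok = True
            for j in idx:
                if j in (i0, i1, i2):
                    continue
                p = pts[j]
                d0 = (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
                d1 = (c[0] - b[0]) * (p[1] - b[1]) - (c[1] - b[1]) * (p[0] - b[0])
                d2 = (a[0] - c[0]) * (p[1] - c[1]) - (a[1] - c[1]) * (p[0] - c[0])
                if d0 > 1e-12 and d1 > 1e-12 and d2 > 1e-12:
                    ok = False
                    break
            if ok:
                tris.append((i0, i1, i2))
                idx.pop(k)
                clipped = True
                break
        if not clipped:
            raise RuntimeError("ear clipping stalled; polygon may not be simple")
    tris.append(tuple(idx))
    return tris


def _sagittal_profile(t: SpineTemplate) -> np.ndarray:
    """CCW profile polygon in the (x, z) plane, body centred at the origin."""
    bx, _, bz = t.body_size
    hb = bz / 2.0
    lean = t.dsp_cranial_taper * t.dsp_height
    b_cr = t.blade_base_length / 2.0
    b_ca = -t.blade_base_length / 2.0
    tip_z = hb + t.dsp_height
    bevel = min(1.0, 0.1 * hb)  # keeps the top profile points non-collinear
    pts = np.array(
        [
            (-bx / 2, -hb),
            (bx / 2, -hb),
            (bx / 2, hb - bevel),
            (b_cr, hb),
            (b_cr + lean, tip_z),
            (b_cr + lean - t.blade_tip_length, tip_z),
            (b_ca, hb),
            (-bx / 2, hb - bevel),
        ],
        dtype=float,
    )
    if _polygon_area(pts) < 0:
        pts = pts[::-1]
    return pts


def build_vertebra_mesh(template: SpineTemplate) -> trimesh.Trimesh:
    """One watertight vertebra mesh in its local frame (body centre at origin)."""
    prof = _sagittal_profile(template)
    n = len(prof)
    w = template.body_size[1]
    half = w / 2.0
    # prism: bottom ring y=-half, top ring y=+half
    bottom = np.column_stack([prof[:, 0], np.full(n, -half), prof[:, 1]])
    top = np.column_stack([prof[:, 0], np.full(n, half), prof[:, 1]])
    verts = np.vstack([bottom, top])
    faces = []
    cap = _triangulate_polygon(prof)
    for (i, j, k) in cap:
        faces.append((i, j, k))  # bottom cap, outward -y
        faces.append((n + i, n + k, n + j))  # top cap, outward +y
    for i in range(n):
        j = (i + 1) % n
        faces.append((i, n + j, j))
        faces.append((i, n + i, n + j))
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    trimesh.repair.fix_normals(mesh)
    # blade deformation: mediolateral taper to a thin tip + small shear so the
    # craniodorsal landmark vertex is unique in all three coordinates
    v = mesh.vertices.copy()
    hb = template.body_size[2] / 2.0
    frac = np.clip((v[:, 2] - hb) / template.dsp_height, 0.0, 1.0)
    tip_ratio = template.blade_tip_halfwidth / half
    y0 = v[:, 1].copy()
    v[:, 1] = y0 * (1.0 - (1.0 - tip_ratio) * frac)
    v[:, 0] = v[:, 0] + template.landmark_shear * (y0 / half) * frac
    mesh.vertices = v
    if not mesh.is_watertight:
        raise RuntimeError("vertebra mesh construction produced a non-watertight mesh")
    if mesh.volume <= 0:
        mesh.invert()
    return mesh


# ---------------------------------------------------------------------------
# template assembly


def _solve_arc(gaps: np.ndarray, target: float | None) -> float:
    """Per-joint bend angle (rad) of the dorsally convex resting arc.

    Chord steps equal the inter-DSP gaps; the bend is chosen so the
    straight-line first-to-last distance equals ``target``.  A flat chain
    (bend 0) is returned when no target is set or it is not shorter than the
    summed gaps.
    """
    total = float(np.sum(gaps))
    if target is None or target >= total * (1 - 1e-12):
        return 0.0
    m = len(gaps)

    def chord(phi: float) -> float:
        beta = ((m - 1) / 2.0 - np.arange(m)) * phi
        steps = gaps[:, None] * np.column_stack([-np.cos(beta), np.sin(beta)])
        return float(np.linalg.norm(steps.sum(axis=0)))

    f = lambda phi: chord(phi) - target
    hi = 0.05
    while f(hi) > 0 and hi < np.pi / (m + 1):
        hi *= 1.5
    if f(hi) > 0:
        raise ValueError(
            f"target_total_length={target} is too short for gaps summing to {total:.1f}"
        )
    return float(brentq(f, 1e-12, hi, xtol=1e-12))


def _check_no_interpenetration(pose: SpinePose, context: str) -> None:
    labels = pose.labels
    for i in range(len(labels) - 1):
        a, b = pose.meshes[labels[i]], pose.meshes[labels[i + 1]]
        amin, amax = a.bounds
        bmin, bmax = b.bounds
        if np.any(amax < bmin) or np.any(bmax < amin):
            continue
        if (
            meshdist.points_in_mesh(a, b.vertices).any()
            or meshdist.points_in_mesh(b, a.vertices).any()
        ):
            raise ValueError(
                f"{context}: meshes {labels[i]} and {labels[i + 1]} interpenetrate"
            )


def build_template(template: SpineTemplate = SpineTemplate()) -> SpinePose:
    """Canonical resting pose: vertebrae laid along a gentle dorsal arc.

    Consecutive craniodorsal landmarks are separated by exactly the resting
    gaps (39.9 mm by default) and the straight-line T11->L1 landmark distance
    equals ``target_total_length`` (310 mm) when that is shorter than the
    summed gaps.
    """
    base = build_vertebra_mesh(template)
    local_lm = kinematics.craniodorsal_landmark(base).position
    gaps = template.gaps()
    m = template.n_spaces
    phi = _solve_arc(gaps, template.target_total_length)

    # T11 sits at the origin and the chain marches caudally along -x, keeping
    # +x cranial; the arc bulges dorsally (+z) in the middle
    beta = ((m - 1) / 2.0 - np.arange(m)) * phi  # step elevation angles
    positions = np.zeros((template.n_vertebrae, 3))
    for j in range(m):
        step = gaps[j] * np.array([-np.cos(beta[j]), 0.0, np.sin(beta[j])])
        positions[j + 1] = positions[j] + step
    alpha = (m / 2.0 - np.arange(template.n_vertebrae)) * phi  # vertebra tilts

    meshes = {}
    tilts = {}
    for i, lb in enumerate(template.labels):
        R = rotation_about_axis([0.0, 1.0, 0.0], np.degrees(alpha[i]))
        t = positions[i] - R @ local_lm
        placement = RigidTransform(R, t)
        mesh = base.copy()
        mesh.vertices = placement.apply(mesh.vertices)
        meshes[lb] = mesh
        tilts[lb] = R

    # joint pivots: ventral offset from the DSP tips down to the body centre line
    bz = template.body_size[2]
    default_offset = template.dsp_height + bz / 2.0
    pivots = np.zeros((m, 3))
    for j in range(m):
        mid = 0.5 * (positions[j] + positions[j + 1])
        dorsal = tilts[template.labels[j]] @ np.array([0.0, 0.0, 1.0])
        dorsal = dorsal + tilts[template.labels[j + 1]] @ np.array([0.0, 0.0, 1.0])
        dorsal /= np.linalg.norm(dorsal)
        pivots[j] = mid - default_offset * dorsal

    pose = SpinePose(
        labels=template.labels,
        meshes=meshes,
        phase="resting",
        condition="pre",
        joint_pivots=pivots,
        template=template,
    )
    _check_no_interpenetration(pose, "build_template")
    return pose


# ---------------------------------------------------------------------------
# articulation

_PHASES = ("resting", "flexion", "extension")
# positive rotation about +y at a ventral pivot moves the caudal DSP tip
# cranially, i.e. closes the interspinous gap (flexion under the rig reading)
_FLEXION_SIGN = 1.0


def joint_angles(
    joints: JointConfig, phase: str, condition: str, n_spaces: int
) -> np.ndarray:
    """Signed per-space rotation angles (deg) for a phase/condition."""
    if phase not in _PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    if condition not in ("pre", "post"):
        raise ValueError(f"unknown condition {condition!r}")
    effective = phase
    if joints.swap_phase_labels and phase != "resting":
        effective = "extension" if phase == "flexion" else "flexion"
    if effective == "resting":
        return np.zeros(n_spaces)
    if effective == "flexion":
        amp = joints.flexion_amplitude_deg
        if condition == "post":
            amp *= joints.isld_flexion_multiplier
        return np.full(n_spaces, _FLEXION_SIGN * amp)
    return np.full(n_spaces, -_FLEXION_SIGN * joints.extension_amplitude_deg)


def articulate(
    pose: SpinePose,
    joints: JointConfig = JointConfig(),
    phase: str = "resting",
    condition: str = "pre",
    check_interpenetration: bool = True,
) -> tuple:
    """Forward-kinematic articulation of a canonical resting pose.

    Vertebra ``i`` carries the composed product of the joint rotations of
    spaces ``0..i-1``, each about that space's mediolateral pivot in the
    resting frame (cranial-most joint outermost).  Returns the articulated
    :class:`SpinePose` and its :class:`GroundTruth`.
    """
    if pose.joint_pivots is None:
        raise ValueError("pose lacks joint pivots; articulate a built template")
    n = len(pose.labels)
    pivots = pose.joint_pivots
    angles = joint_angles(joints, phase, condition, n - 1)
    if joints.pivot_offset is not None and pose.template is not None:
        # re-derive pivots at the requested ventral offset from the DSP tips
        shift = joints.pivot_offset - (
            pose.template.dsp_height + pose.template.body_size[2] / 2.0
        )
        resting_lms = pose.landmarks()
        pivots = pivots.copy()
        for j in range(n - 1):
            mid_dir = pivots[j] - 0.5 * (
                resting_lms[j].position + resting_lms[j + 1].position
            )
            mid_dir /= np.linalg.norm(mid_dir)
            pivots[j] = pivots[j] + shift * mid_dir

    transforms = {pose.labels[0]: RigidTransform.identity()}
    acc = RigidTransform.identity()
    for i in range(1, n):
        rot = rotation_about_point([0.0, 1.0, 0.0], angles[i - 1], pivots[i - 1])
        acc = acc @ rot
        transforms[pose.labels[i]] = acc

    out = pose.copy()
    out.phase = phase
    out.condition = condition
    for lb in pose.labels:
        out.meshes[lb].vertices = transforms[lb].apply(out.meshes[lb].vertices)
    if check_interpenetration and np.any(angles != 0):
        try:
            _check_no_interpenetration(out, f"articulate(phase={phase})")
        except ValueError as err:
            raise ValueError(str(err)) from None

    resting_lms = {lm.label: lm.position for lm in pose.landmarks()}
    world_lms = {lb: transforms[lb].apply(resting_lms[lb]) for lb in pose.labels}
    pts = [world_lms[lb] for lb in pose.labels]
    gt = GroundTruth(
        transforms=transforms,
        landmarks=world_lms,
        inter_dsp=kinematics.inter_dsp_distances(pts),
        total_length=kinematics.total_length(pts),
        joint_angles_deg=angles,
    )
    return out, gt


# ---------------------------------------------------------------------------
# specimen sampling


def _mechanically_valid(t: SpineTemplate, j: JointConfig) -> bool:
    """A specimen is admissible iff no phase brings bones into contact."""
    try:
        pose = build_template(t)
        for phase, condition in (("extension", "pre"), ("flexion", "post")):
            articulate(pose, j, phase, condition)
    except (ValueError, RuntimeError):
        return False
    return True


def sample_specimens(
    sampler: SpecimenSampler = SpecimenSampler(),
    template: SpineTemplate = SpineTemplate(),
    joints: JointConfig = JointConfig(),
) -> list:
    """Draw per-specimen (template, joints) pairs; deterministic in the seed.

    Draws that produce mechanically impossible specimens (vertebrae in
    contact in any phase — a configuration a cadaver cannot reach) are
    rejected and redrawn.
    """
    rng = np.random.default_rng(sampler.seed)
    base_gaps = template.gaps()
    ratio = None
    if template.target_total_length is not None:
        ratio = template.target_total_length / float(np.sum(base_gaps))
    out = []
    attempts = 0
    while len(out) < sampler.n_specimens:
        attempts += 1
        if attempts > 100 * sampler.n_specimens:
            raise RuntimeError(
                "could not draw mechanically valid specimens; "
                "template/joint variability is too extreme"
            )
        gap_shift = rng.normal(0.0, sampler.gap_sd)
        space_jitter = rng.normal(0.0, sampler.gap_space_sd, size=template.n_spaces)
        gaps = np.clip(base_gaps + gap_shift + space_jitter, 5.0, None)
        body_scale = max(0.5, 1.0 + rng.normal(0.0, sampler.body_scale_sd))
        amp_scale = max(0.2, 1.0 + rng.normal(0.0, sampler.amplitude_scale_sd))
        t_k = replace(
            template,
            body_size=tuple(np.asarray(template.body_size) * body_scale),
            dsp_height=template.dsp_height * body_scale,
            resting_gap=template.resting_gap,
            space_gap_offsets=tuple(gaps - template.resting_gap),
            target_total_length=(
                None if ratio is None else float(ratio * np.sum(gaps))
            ),
        )
        j_k = replace(
            joints,
            flexion_amplitude_deg=joints.flexion_amplitude_deg * amp_scale,
            extension_amplitude_deg=joints.extension_amplitude_deg * amp_scale,
        )
        has_jitter = (
            sampler.gap_sd > 0
            or sampler.gap_space_sd > 0
            or sampler.body_scale_sd > 0
            or sampler.amplitude_scale_sd > 0
        )
        if has_jitter and not _mechanically_valid(t_k, j_k):
            continue
        out.append((t_k, j_k))
    return out


# ---------------------------------------------------------------------------
# serialization


def write_pose(
    pose: SpinePose,
    directory,
    ground_truth: GroundTruth | None = None,
    fmt: str = "stl",
) -> Path:
    """Write one mesh file per vertebra plus a JSON manifest.

    Ground-truth 4x4 matrices are stored row-major in mm units.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "phase": pose.phase,
        "condition": pose.condition,
        "specimen": pose.specimen,
        "labels": list(pose.labels),
        "units": "mm",
        "files": {},
    }
    for lb in pose.labels:
        fname = f"{pose.specimen}_{pose.condition}_{pose.phase}_{lb}.{fmt}"
        pose.meshes[lb].export(directory / fname)
        manifest["files"][lb] = fname
    if ground_truth is not None:
        manifest["ground_truth"] = {
            lb: [list(map(float, row)) for row in ground_truth.transforms[lb].matrix]
            for lb in pose.labels
        }
        manifest["landmarks"] = {
            lb: list(map(float, ground_truth.landmarks[lb])) for lb in pose.labels
        }
    path = directory / f"{pose.specimen}_{pose.condition}_{pose.phase}_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
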