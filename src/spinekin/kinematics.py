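"""Morphometric measurements on vertebral surfaces and rigid motions.

Everything the study reports is computed here: craniodorsal landmarks on the
dorsal spinous processes (DSPs), inter-DSP distances, total segment length,
per-space range of motion (ROM), Hausdorff surface distances, and the
decomposition of a rigid motion into anatomical translation components and
rotation angles.

Anatomical frame convention (used throughout the package):
``+x`` cranial, ``+y`` left (mediolateral), ``+z`` dorsal.  "Dorsoventral"
therefore means the z-component and "craniocaudal" the x-component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import trimesh
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation as _Rotation

from . import meshdist
from .transforms import RigidTransform

__all__ = [
    "Landmark",
    "MotionComponents",
    "KinematicsRecord",
    "craniodorsal_landmark",
    "inter_dsp_distances",
    "total_length",
    "rom_per_space",
    "hausdorff",
    "decompose_motion",
    "recompose_motion",
    "summarize_effects",
]


@dataclass(frozen=True)
class Landmark:
    """A single measurement point on a vertebra (a vertex of the mesh)."""

    label: str
    position: np.ndarray
    dorsal_fraction: float
    vertex_index: int


def _pca_axes(v: np.ndarray) -> tuple:
    """Per-vertebra (cranial, dorsal) unit axes from the vertex cloud.

    The dorsal axis is the dominant principal direction (the spinous process
    is by far the longest feature), signed toward the thin end: the blade
    tapers while the vertebral body is wide, so the extremal quartile with
    the smaller perpendicular spread is dorsal.  The cranial axis is the
    anatomical +x re-orthogonalized against it.
    """
    c = v.mean(axis=0)
    _, _, Vt = np.linalg.svd(v - c, full_matrices=False)
    u = Vt[0]
    t = (v - c) @ u
    q_lo, q_hi = np.quantile(t, [0.25, 0.75])
    perp = (v - c) - np.outer(t, u)
    spread_hi = np.linalg.norm(perp[t >= q_hi], axis=1).mean()
    spread_lo = np.linalg.norm(perp[t <= q_lo], axis=1).mean()
    dorsal = u if spread_hi <= spread_lo else -u
    x = np.array([1.0, 0.0, 0.0])
    cranial = x - (x @ dorsal) * dorsal
    norm = np.linalg.norm(cranial)
    if norm < 1e-6:
        raise ValueError("cannot orient vertebra: spinous process parallel to x")
    return cranial / norm, dorsal


def craniodorsal_landmark(
    mesh: trimesh.Trimesh,
    dorsal_fraction: float = 0.4,
    label: str = "",
    frame: str = "global",
) -> Landmark:
    """Most craniodorsal vertex of a vertebra mesh.

    The search is restricted to vertices whose dorsal coordinate lies in the
    top ``dorsal_fraction`` of the mesh's dorsal extent — i.e. on the spinous
    process — and returns the vertex maximizing the cranial coordinate.
    Ties are broken by larger dorsal coordinate, then by lowest vertex
    index.  This is the single repeatable point per vertebra from which all
    inter-DSP distances are measured; caudal prominences are deliberately
    not used.

    ``frame="global"`` takes dorsal = z and cranial = x literally and ranks
    by the cranial coordinate alone, which is stable only while the vertebra
    is tilted less than the spinous process' own cranial lean (about 15
    degrees).  ``frame="pca"`` first normalizes the vertebra's orientation
    from its own geometry (see :func:`_pca_axes`) and ranks band vertices by
    the 45-degree craniodorsal direction (cranial + dorsal), which keeps the
    process tip a strict maximum at any articulation tilt; the measurement
    pipeline uses this on articulated spines.
    """
    v = np.asarray(mesh.vertices, dtype=float)
    if v.size == 0:
        raise ValueError("cannot place a landmark on an empty mesh")
    if frame == "global":
        cranial = np.array([1.0, 0.0, 0.0])
        dorsal = np.array([0.0, 0.0, 1.0])
        score_dir = cranial
    elif frame == "pca":
        cranial, dorsal = _pca_axes(v)
        score_dir = (cranial + dorsal) / np.sqrt(2.0)
    else:
        raise ValueError("frame must be 'global' or 'pca'")
    z = v @ dorsal
    zmax, zmin = z.max(), z.min()
    cut = zmax - dorsal_fraction * (zmax - zmin)
    band = np.flatnonzero(z >= cut)
    if band.size == 0:
        raise ValueError(
            f"no vertices in the dorsal band (dorsal_fraction={dorsal_fraction})"
        )
    x = v[band] @ score_dir
    # lexsort: primary max craniodorsal score, then max dorsal, then lowest index
    order = np.lexsort((band, -z[band], -x))
    best = band[order[0]]
    return Landmark(
        label=label,
        position=v[best].copy(),
        dorsal_fraction=float(dorsal_fraction),
        vertex_index=int(best),
    )


def _positions(landmarks: Iterable) -> np.ndarray:
    pts = []
    for lm in landmarks:
        pts.append(lm.position if isinstance(lm, Landmark) else np.asarray(lm, float))
    return np.asarray(pts, dtype=float).reshape(-1, 3)


def inter_dsp_distances(landmarks: Sequence) -> np.ndarray:
    """Euclidean distances between consecutive craniodorsal landmarks.

    ``landmarks`` must be ordered cranial to caudal; accepts Landmark objects
    or bare mm positions.
    """
    p = _positions(landmarks)
    if p.shape[0] < 2:
        raise ValueError("need at least 2 landmarks for inter-DSP distances")
    return np.linalg.norm(np.diff(p, axis=0), axis=1)


def total_length(landmarks: Sequence) -> float:
    """Straight-line distance from the first to the last landmark (mm)."""
    p = _positions(landmarks)
    if p.shape[0] < 2:
        raise ValueError("need at least 2 landmarks for total length")
    return float(np.linalg.norm(p[-1] - p[0]))


def rom_per_space(d_flexion, d_extension) -> np.ndarray | float:
    """Per-space dorsoventral range of motion: |d_flexion - d_extension| (mm)."""
    df = np.asarray(d_flexion, dtype=float)
    de = np.asarray(d_extension, dtype=float)
    if np.any(df < 0) or np.any(de < 0):
        raise ValueError("inter-DSP distances must be non-negative")
    rom = np.abs(df - de)
    return float(rom) if rom.ndim == 0 else rom


def _as_points(obj) -> np.ndarray:
    if isinstance(obj, trimesh.Trimesh):
        return np.asarray(obj.vertices, dtype=float)
    return np.asarray(obj, dtype=float).reshape(-1, 3)


def _directed_hausdorff_points(a: np.ndarray, b: np.ndarray) -> float:
    d, _ = cKDTree(b).query(a)
    return float(d.max())


def _directed_hausdorff_surface(
    a: trimesh.Trimesh, b: trimesh.Trimesh, sample_n: int, seed: int
) -> float:
    pts = np.asarray(a.vertices, dtype=float)
    if sample_n > 0 and len(a.faces) > 0:
        samples, _ = trimesh.sample.sample_surface(a, sample_n, seed=seed)
        pts = np.vstack([pts, samples])
    # exact point-to-triangle distance to surface b
    _, dist = meshdist.closest_on_surface(pts, b)
    return float(np.max(dist))


def hausdorff(
    mesh_a,
    mesh_b,
    symmetric: bool = True,
    sample_n: int = 10000,
    seed: int = 0,
    mode: str = "surface",
) -> float:
    """Hausdorff distance between two bone surfaces (mm).

    ``mode="surface"`` samples points on each mesh (plus its vertices) and
    measures exact point-to-triangle distance to the other surface;
    ``mode="vertices"`` is the exact vertex-set metric (also accepts bare
    point arrays).  The directed variants are ``hausdorff(..., symmetric=False)``
    (a -> b) and the argument swap.
    """
    a_pts, b_pts = _as_points(mesh_a), _as_points(mesh_b)
    if a_pts.size == 0 or b_pts.size == 0:
        raise ValueError("hausdorff distance of an empty surface is undefined")
    surface_ok = (
        mode == "surface"
        and isinstance(mesh_a, trimesh.Trimesh)
        and isinstance(mesh_b, trimesh.Trimesh)
        and len(mesh_a.faces) > 0
        and len(mesh_b.faces) > 0
    )
    if surface_ok:
        d_ab = _directed_hausdorff_surface(mesh_a, mesh_b, sample_n, seed)
        if not symmetric:
            return d_ab
        d_ba = _directed_hausdorff_surface(mesh_b, mesh_a, sample_n, seed + 1)
        return max(d_ab, d_ba)
    d_ab = _directed_hausdorff_points(a_pts, b_pts)
    if not symmetric:
        return d_ab
    return max(d_ab, _directed_hausdorff_points(b_pts, a_pts))


@dataclass(frozen=True)
class MotionComponents:
    """Anatomical decomposition of a rigid motion at a reference point.

    Translation components are magnitudes of the displacement of the
    reference point (the moving bone's centroid by convention, because the
    raw matrix translation depends on the arbitrary coordinate origin).
    """

    dorsoventral: float
    craniocaudal: float
    mediolateral: float
    total_angle_deg: float
    ml_axis_angle_deg: float
    # signed raw quantities, sufficient to recompose the transform
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    angle_deg: float = 0.0
    displacement: np.ndarray = field(default_factory=lambda: np.zeros(3))
    reference_point: np.ndarray = field(default_factory=lambda: np.zeros(3))


def decompose_motion(
    t: RigidTransform, reference_point=(0.0, 0.0, 0.0)
) -> MotionComponents:
    """Split a rigid motion into translation components and rotation angles.

    Returns |z|, |x|, |y| displacement of ``reference_point`` (dorsoventral,
    craniocaudal, mediolateral mm), the total rotation angle
    ``arccos((trace(R)-1)/2)`` and the rotation attributable to the
    mediolateral (y) axis, ``angle * |axis . y|`` from the axis-angle form.
    """
    if not isinstance(t, RigidTransform):
        t = RigidTransform(t.rotation, t.translation)  # validates orthonormality
    c = np.asarray(reference_point, dtype=float).reshape(3)
    disp = t.apply(c) - c
    R = t.rotation
    cos_total = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    total_angle = float(np.degrees(np.arccos(cos_total)))
    rotvec = _Rotation.from_matrix(R).as_rotvec()
    angle = float(np.linalg.norm(rotvec))
    axis = rotvec / angle if angle > 0 else np.array([0.0, 1.0, 0.0])
    ml_angle = float(np.degrees(angle) * abs(axis[1]))
    return MotionComponents(
        dorsoventral=float(abs(disp[2])),
        craniocaudal=float(abs(disp[0])),
        mediolateral=float(abs(disp[1])),
        total_angle_deg=total_angle,
        ml_axis_angle_deg=ml_angle,
        axis=axis,
        angle_deg=float(np.degrees(angle)),
        displacement=disp,
        reference_point=c,
    )


def recompose_motion(components: MotionComponents) -> RigidTransform:
    """Rebuild the rigid transform from the signed axis-angle + displacement."""
    rot = _Rotation.from_rotvec(
        components.axis * np.deg2rad(components.angle_deg)
    ).as_matrix()
    c = components.reference_point
    t = components.displacement + c - rot @ c
    return RigidTransform(rot, t)


@dataclass
class KinematicsRecord:
    """Per-(specimen, phase, condition) measurement row."""

    specimen: str
    condition: str  # "pre" | "post"
    phase: str  # "resting" | "flexion" | "extension"
    inter_dsp: np.ndarray  # (n_spaces,) mm
    total_length: float  # mm
    l1_translation: np.ndarray | None = None  # (dv, cc, ml) mm
    l1_rotation_total: float | None = None  # degrees
    l1_rotation_ml_axis: float | None = None  # degrees
    hausdorff_l1: float | None = None  # mm

    def as_dict(self) -> dict:
        d = {
            "specimen": self.specimen,
            "condition": self.condition,
            "phase": self.phase,
            "total_length": self.total_length,
        }
        for i, v in enumerate(np.asarray(self.inter_dsp, float), start=1):
            d[f"inter_dsp_{i}"] = float(v)
        if self.l1_translation is not None:
            d["l1_dorsoventral"] = float(self.l1_translation[0])
            d["l1_craniocaudal"] = float(self.l1_translation[1])
            d["l1_mediolateral"] = float(self.l1_translation[2])
        if self.l1_rotation_total is not None:
            d["l1_rotation_total"] = float(self.l1_rotation_total)
        if self.l1_rotation_ml_axis is not None:
            d["l1_rotation_ml_axis"] = float(self.l1_rotation_ml_axis)
        if self.hausdorff_l1 is not None:
            d["hausdorff_l1"] = float(self.hausdorff_l1)
        return d


def records_to_frame(records: Iterable[KinematicsRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in records])


def summarize_effects(
    paired: pd.DataFrame,
    metrics: Sequence[str] | None = None,
    n_sites: int = 8,
) -> pd.DataFrame:
    """Effect summary of paired pre/post measurements.

    ``paired`` needs columns ``specimen``, ``condition`` ("pre"/"post") and
    one column per metric.  For each metric the summary gives pre/post
    mean +- sd, the mean paired change (post - pre), the per-specimen percent
    change (primary; the group-mean-ratio percent is emitted alongside) and
    the per-site effect, percent divided by the number of surgical sites
    (``n_sites``, 8 desmotomies in the study design).

    No rounding is applied; use :func:`format_effect_summary` for 1-decimal
    presentation.
    """
    if not {"specimen", "condition"}.issubset(paired.columns):
        raise ValueError("paired frame needs 'specimen' and 'condition' columns")
    if metrics is None:
        metrics = [c for c in paired.columns if c not in ("specimen", "condition", "phase")]
    pre = paired[paired["condition"] == "pre"].set_index("specimen")
    post = paired[paired["condition"] == "post"].set_index("specimen")
    unpaired = set(pre.index).symmetric_difference(post.index)
    if unpaired:
        raise ValueError(f"unpaired specimens: {sorted(unpaired)}")
    order = sorted(pre.index)
    rows = []
    for m in metrics:
        a = pre.loc[order, m].to_numpy(dtype=float)
        b = post.loc[order, m].to_numpy(dtype=float)
        diff = b - a
        with np.errstate(divide="ignore", invalid="ignore"):
            pct_each = 100.0 * diff / a
        pct = float(np.mean(pct_each)) if np.all(a > 0) else float("nan")
        pct_sd = float(np.std(pct_each, ddof=1)) if len(a) > 1 and np.all(a > 0) else float("nan")
        pre_mean = float(np.mean(a))
        rows.append(
            {
                "metric": m,
                "n": len(a),
                "pre_mean": pre_mean,
                "pre_sd": float(np.std(a, ddof=1)) if len(a) > 1 else float("nan"),
                "post_mean": float(np.mean(b)),
                "post_sd": float(np.std(b, ddof=1)) if len(b) > 1 else float("nan"),
                "change": float(np.mean(diff)),
                "change_sd": float(np.std(diff, ddof=1)) if len(a) > 1 else float("nan"),
                "percent_change": pct,
                "percent_change_sd": pct_sd,
                "percent_change_of_means": (
                    100.0 * float(np.mean(diff)) / pre_mean if pre_mean > 0 else float("nan")
                ),
                "per_site_percent": pct / n_sites if np.isfinite(pct) else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def format_effect_summary(summary: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Presentation rounding (1 decimal, as in the tables of results)."""
    out = summary.copy()
    for c in out.columns:
        if out[c].dtype.kind == "f":
            out[c] = out[c].round(decimals)
    return out
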