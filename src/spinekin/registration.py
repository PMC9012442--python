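"""Rigid alignment: Kabsch on correspondences, ICP on surfaces, and the
anchor-vertebra superimposition that expresses every phase in a common frame.

The study's "global registration" of the T11 anchor is implemented as ICP
with a centroid/principal-axes initialization: surface points sampled from
the moving mesh are matched to the fixed surface (nearest neighbour on a
dense point sampling by default, exact point-to-triangle in
``correspondence="surface"`` mode) and the Kabsch update is iterated until
the RMS residual stops decreasing.  The anchor transform is then applied to
every vertebra of its phase, which preserves all within-phase relationships
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from . import meshdist
from .transforms import RigidTransform

__all__ = [
    "RegistrationError",
    "RegistrationResult",
    "kabsch",
    "pca_init",
    "icp",
    "superimpose_anchor",
    "register_bone_across_phases",
]


class RegistrationError(RuntimeError):
    pass


@dataclass
class RegistrationResult:
    transform: RigidTransform
    rms_residual: float
    iterations: int
    converged: bool
    message: str = ""


def kabsch(src_points, dst_points, weights=None) -> RigidTransform:
    """Least-squares rigid transform mapping ``src`` onto ``dst``.

    Minimizes the weighted sum of squared correspondence distances;
    reflections are excluded by the determinant correction.  Requires at
    least 3 non-collinear correspondences.
    """
    src = np.asarray(src_points, dtype=float).reshape(-1, 3)
    dst = np.asarray(dst_points, dtype=float).reshape(-1, 3)
    if src.shape != dst.shape:
        raise ValueError("source and destination point sets must match in shape")
    n = len(src)
    if n < 3:
        raise ValueError("need at least 3 correspondences")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float).reshape(-1)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
    cs = w @ src
    cd = w @ dst
    s0 = src - cs
    d0 = dst - cd
    # collinearity check on the weighted source spread
    sv = np.linalg.svd(s0 * np.sqrt(w)[:, None], compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1e-30):
        raise ValueError("degenerate (collinear) correspondence set")
    H = (s0 * w[:, None]).T @ d0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, cd - R @ cs)


def _surface_points(mesh, sample_n: int, seed: int) -> np.ndarray:
    pts = np.asarray(mesh.vertices, dtype=float)
    if sample_n > 0 and len(mesh.faces) > 0:
        samples, _ = trimesh.sample.sample_surface(mesh, sample_n, seed=seed)
        pts = np.vstack([pts, samples])
    return pts


def pca_init(src_mesh, dst_mesh, probe_n: int = 500, seed: int = 0) -> RigidTransform:
    """Centroid + principal-axes initialization for ICP.

    The four proper sign combinations of the axes are tried and the one with
    the lowest probe RMS against the fixed surface wins.
    """
    sv = np.asarray(src_mesh.vertices, dtype=float)
    dv = np.asarray(dst_mesh.vertices, dtype=float)
    cs, cd = sv.mean(axis=0), dv.mean(axis=0)
    _, _, Vs = np.linalg.svd(sv - cs, full_matrices=False)
    _, _, Vd = np.linalg.svd(dv - cd, full_matrices=False)
    if np.linalg.det(Vs) < 0:
        Vs[2] *= -1
    if np.linalg.det(Vd) < 0:
        Vd[2] *= -1
    rng = np.random.default_rng(seed)
    probe = sv[rng.choice(len(sv), size=min(probe_n, len(sv)), replace=False)]
    tree = cKDTree(dv)
    best = None
    for f in ([1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]):
        R = Vd.T @ np.diag(f).astype(float) @ Vs
        t = cd - R @ cs
        d, _ = tree.query(probe @ R.T + t)
        rms = float(np.sqrt(np.mean(d**2)))
        if best is None or rms < best[0]:
            best = (rms, RigidTransform(R, t))
    return best[1]


def icp(
    src_mesh,
    dst_mesh,
    init: RigidTransform | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
    sample_n: int = 5000,
    trim_fraction: float = 0.0,
    seed: int = 0,
    correspondence: str = "points",
) -> RegistrationResult:
    """Iterative closest point between two surfaces.

    The RMS correspondence residual is non-increasing across iterations
    (asserted); the loop stops when it decreases by less than ``tol`` mm or
    at ``max_iter``.  Deterministic for a fixed ``seed``.
    """
    if not 0.0 <= trim_fraction < 1.0:
        raise ValueError("trim_fraction must be in [0, 1)")
    if init is None:
        init = pca_init(src_mesh, dst_mesh, seed=seed)
    src_pts = _surface_points(src_mesh, sample_n, seed)
    if correspondence == "points":
        dst_pts = _surface_points(dst_mesh, sample_n, seed)
        tree = cKDTree(dst_pts)

        def correspond(p):
            d, i = tree.query(p)
            return dst_pts[i], d

    elif correspondence == "surface":

        def correspond(p):
            q, d = meshdist.closest_on_surface(p, dst_mesh)
            return q, d

    else:
        raise ValueError("correspondence must be 'points' or 'surface'")

    T = RigidTransform.identity() if init is None else init
    keep = len(src_pts)
    if trim_fraction > 0:
        keep = max(3, int(np.ceil(len(src_pts) * (1.0 - trim_fraction))))

    prev = np.inf
    rms = np.inf
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        p = T.apply(src_pts)
        q, d = correspond(p)
        if keep < len(src_pts):
            sel = np.argsort(d, kind="stable")[:keep]
        else:
            sel = slice(None)
        rms = float(np.sqrt(np.mean(d[sel] ** 2)))
        assert rms <= prev + 1e-9, "ICP residual increased"
        if prev - rms < tol:
            converged = True
            break
        delta = kabsch(p[sel], q[sel])
        T = delta @ T
        prev = rms
    msg = ""
    dst_scale = float(np.linalg.norm(np.ptp(np.asarray(dst_mesh.vertices), axis=0)))
    if rms > 0.25 * max(dst_scale, 1e-12):
        converged = False
        msg = (
            f"residual {rms:.3g} mm is large relative to the target extent "
            f"{dst_scale:.3g} mm; surfaces may not overlap after initialization"
        )
    return RegistrationResult(T, rms, it, converged, msg)


def superimpose_anchor(
    poses: dict,
    anchor_label: str = "T11",
    reference_phase: str = "resting",
    **icp_kw,
) -> tuple:
    """Align every phase onto the reference phase via its anchor vertebra.

    The anchor transform (anchor of phase -> anchor of reference, from ICP)
    is applied to *all* vertebrae of that phase, so the spatial relationship
    between the anchor and each successive vertebra is maintained exactly.
    Returns ``(aligned {phase: SpinePose}, {phase: RigidTransform})``.
    """
    if reference_phase not in poses:
        raise ValueError(f"reference phase {reference_phase!r} missing")
    for ph, pose in poses.items():
        if anchor_label not in pose.meshes:
            raise ValueError(f"anchor {anchor_label!r} missing from phase {ph!r}")
    ref = poses[reference_phase]
    transforms = {}
    failures = []
    for ph, pose in poses.items():
        if ph == reference_phase:
            transforms[ph] = RigidTransform.identity()
            continue
        res = icp(pose.meshes[anchor_label], ref.meshes[anchor_label], **icp_kw)
        if not res.converged:
            failures.append(f"{ph}: rms={res.rms_residual:.3g} mm after {res.iterations} it ({res.message})")
        transforms[ph] = res.transform
    if failures:
        raise RegistrationError(
            "anchor registration failed for phase(s): " + "; ".join(failures)
        )
    aligned = {
        ph: (pose.copy() if ph == reference_phase else pose.transformed(transforms[ph]))
        for ph, pose in poses.items()
    }
    return aligned, transforms


def register_bone_across_phases(
    bone_label: str, pose_a, pose_b, **icp_kw
) -> RegistrationResult:
    """Motion of one bone between two (anchor-superimposed) phases.

    The returned transform maps the bone's phase-a position onto its phase-b
    position, expressed in the common anchor frame.
    """
    for pose in (pose_a, pose_b):
        if bone_label not in pose.meshes:
            raise ValueError(f"bone {bone_label!r} missing from pose")
    res = icp(pose_a.meshes[bone_label], pose_b.meshes[bone_label], **icp_kw)
    if not res.converged:
        raise RegistrationError(
            f"registration of {bone_label} did not converge: {res.message}"
        )
    return res
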