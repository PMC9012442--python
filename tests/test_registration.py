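import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from spinekin import kinematics as kin
from spinekin import registration as reg
from spinekin import segmentation as seg
from spinekin import synthetic_spine as ss
from spinekin import volume_imaging as vi
from spinekin.transforms import RigidTransform

from conftest import random_rigid


# ---------------------------------------------------------------------------
# Kabsch


def test_kabsch_identity():
    pts = np.random.default_rng(0).normal(size=(10, 3))
    t = reg.kabsch(pts, pts)
    assert t.is_identity(tol=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_kabsch_recovers_constructed_transform(seed):
    rng = np.random.default_rng(seed)
    src = rng.normal(size=(20, 3)) * 10
    truth = random_rigid(rng)
    t = reg.kabsch(src, truth.apply(src))
    assert t.almost_equals(truth, tol=1e-9)


def test_kabsch_weighted_ignores_zero_weight_outlier():
    rng = np.random.default_rng(1)
    src = rng.normal(size=(8, 3)) * 10
    truth = random_rigid(rng)
    dst = truth.apply(src)
    dst[0] += 100.0  # corrupted correspondence
    w = np.ones(8)
    w[0] = 0.0
    t = reg.kabsch(src, dst, weights=w)
    assert t.almost_equals(truth, tol=1e-9)


def test_kabsch_degenerate_inputs():
    line = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match="collinear"):
        reg.kabsch(line, line + 1.0)
    with pytest.raises(ValueError):
        reg.kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


def _objective(params, src, dst):
    R = Rotation.from_rotvec(params[:3]).as_matrix()
    t = params[3:]
    return float(np.sum((src @ R.T + t - dst) ** 2))


@pytest.mark.parametrize("seed", range(3))
def test_kabsch_matches_brute_force_minimum(seed):
    """Kabsch objective equals direct numerical minimization (5-point sets)."""
    rng = np.random.default_rng(seed)
    src = rng.normal(size=(5, 3)) * 10
    dst = random_rigid(rng, max_angle_deg=30).apply(src)
    dst += rng.normal(0, 0.5, dst.shape)  # noise so the optimum is nontrivial
    t = reg.kabsch(src, dst)
    f_kabsch = float(np.sum((t.apply(src) - dst) ** 2))
    best = np.inf
    for s in range(8):
        x0 = np.concatenate([rng.normal(0, 0.5, 3), rng.normal(0, 5, 3)])
        r = minimize(_objective, x0, args=(src, dst), method="Nelder-Mead",
                     options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        best = min(best, r.fun)
    assert f_kabsch <= best + 1e-6


def test_kabsch_noise_residual_scale():
    """Residual RMS stays below 2 sigma for Gaussian correspondence noise."""
    rng = np.random.default_rng(3)
    sigma = 0.5
    src = rng.normal(size=(500, 3)) * 20
    truth = random_rigid(rng)
    dst = truth.apply(src) + rng.normal(0, sigma, (500, 3))
    t = reg.kabsch(src, dst)
    rms = float(np.sqrt(np.mean(np.sum((t.apply(src) - dst) ** 2, axis=1)) / 3))
    assert rms < 2 * sigma


# ---------------------------------------------------------------------------
# ICP


def test_icp_same_mesh_identity(vertebra_mesh):
    res = reg.icp(vertebra_mesh, vertebra_mesh, init=RigidTransform.identity(),
                  sample_n=500)
    assert res.converged
    assert res.rms_residual < 1e-9
    assert res.transform.is_identity(tol=1e-9)


@pytest.mark.parametrize("seed", range(3))
def test_icp_recovers_displacement(vertebra_mesh, seed):
    """Known rigid displacement recovered to <0.01 mm / <0.01 degrees."""
    rng = np.random.default_rng(seed)
    truth = random_rigid(rng, max_angle_deg=25, max_t=30)
    moved = vertebra_mesh.copy()
    moved.vertices = truth.apply(moved.vertices)
    res = reg.icp(moved, vertebra_mesh, sample_n=800, correspondence="surface",
                  tol=1e-9, max_iter=200)
    assert res.converged
    err = res.transform @ truth
    angle = np.degrees(np.arccos(np.clip((np.trace(err.rotation) - 1) / 2, -1, 1)))
    assert angle < 0.01
    assert np.linalg.norm(err.apply(vertebra_mesh.centroid) - vertebra_mesh.centroid) < 0.01


def test_icp_revoxelized_copy_aligns_subvoxel(vertebra_mesh):
    """Independently re-voxelized + re-surfaced copies align near-perfectly."""
    spacing = (1.0, 1.0, 1.0)

    def surface(seed):
        class P:
            def mesh_list(self):
                return [vertebra_mesh]

        vol, _ = vi.voxelize(P(), vi.HUModel(), spacing=spacing, seed=seed)
        return seg.segment_volume(vol, expected_count=1, labels_names=("V",))["V"]

    a, b = surface(1), surface(2)
    res = reg.icp(a, b, sample_n=2000)
    assert res.converged
    assert res.rms_residual < np.linalg.norm(spacing)


def test_icp_rejects_bad_trim():
    m = ss.build_vertebra_mesh(ss.SpineTemplate())
    with pytest.raises(ValueError):
        reg.icp(m, m, trim_fraction=1.0)


# ---------------------------------------------------------------------------
# superimposition


@pytest.fixture(scope="module")
def phases(resting_pose, default_joints):
    out = {}
    for ph in ("resting", "flexion", "extension"):
        pose, _ = ss.articulate(resting_pose, default_joints, ph, "pre")
        out[ph] = pose
    return out


def test_superimpose_reference_unchanged(phases):
    aligned, transforms = reg.superimpose_anchor(phases, sample_n=800)
    assert transforms["resting"].is_identity()
    np.testing.assert_array_equal(
        aligned["resting"].meshes["T11"].vertices, phases["resting"].meshes["T11"].vertices
    )


def test_superimpose_preserves_within_phase_distances(phases):
    """Inter-DSP distances are invariant under anchor superimposition (1e-9)."""
    # displace the flexion phase globally, as a repositioned acquisition would be
    rng = np.random.default_rng(5)
    moved = dict(phases)
    g = random_rigid(rng, max_angle_deg=20, max_t=40)
    moved["flexion"] = phases["flexion"].transformed(g)
    before = kin.inter_dsp_distances(moved["flexion"].landmarks())
    aligned, _ = reg.superimpose_anchor(moved, sample_n=1500, tol=1e-7, max_iter=200)
    after = kin.inter_dsp_distances(aligned["flexion"].landmarks())
    np.testing.assert_allclose(after, before, atol=1e-9)
    # and the anchors coincide afterwards
    d = kin.hausdorff(aligned["flexion"].meshes["T11"], phases["resting"].meshes["T11"],
                      sample_n=500)
    assert d < 0.5


def test_superimpose_missing_anchor_errors(phases):
    broken = dict(phases)
    pose = phases["flexion"].copy()
    del pose.meshes["T11"]
    pose.labels = tuple(l for l in pose.labels if l != "T11")
    broken["flexion"] = pose
    with pytest.raises(ValueError, match="anchor"):
        reg.superimpose_anchor(broken)


def test_register_bone_same_phase_identity(phases):
    res = reg.register_bone_across_phases("L1", phases["resting"], phases["resting"],
                                          sample_n=500)
    assert res.transform.is_identity(tol=1e-6)


def test_register_bone_inverse_consistency(phases):
    kw = dict(sample_n=1500, tol=1e-8, max_iter=300)
    ab = reg.register_bone_across_phases("L1", phases["flexion"], phases["extension"], **kw)
    ba = reg.register_bone_across_phases("L1", phases["extension"], phases["flexion"], **kw)
    comp = ab.transform @ ba.transform
    assert comp.is_identity(tol=1e-4)


def test_register_bone_matches_ground_truth(resting_pose, default_joints):
    """Registered bone motion equals the composed ground-truth joint product."""
    fpose, fgt = ss.articulate(resting_pose, default_joints, "flexion", "pre")
    epose, egt = ss.articulate(resting_pose, default_joints, "extension", "pre")
    res = reg.register_bone_across_phases(
        "L1", fpose, epose, sample_n=2000, correspondence="surface",
        tol=1e-9, max_iter=300,
    )
    truth = egt.transforms["L1"] @ fgt.transforms["L1"].inverse()
    err = res.transform @ truth.inverse()
    angle = np.degrees(np.arccos(np.clip((np.trace(err.rotation) - 1) / 2, -1, 1)))
    assert angle < 0.05
    c = fpose.meshes["L1"].centroid
    assert np.linalg.norm(err.apply(c) - c) < 0.05


def test_superimposition_equivariance(phases, default_joints):
    """A global rigid motion of all inputs changes no metric by > 1e-6."""
    aligned, _ = reg.superimpose_anchor(phases, sample_n=800, tol=1e-8, max_iter=200)
    base = kin.inter_dsp_distances(aligned["flexion"].landmarks())
    g = random_rigid(np.random.default_rng(11), max_angle_deg=15, max_t=30)
    moved = {ph: p.transformed(g) for ph, p in phases.items()}
    aligned2, _ = reg.superimpose_anchor(moved, sample_n=800, tol=1e-8, max_iter=200)
    after = kin.inter_dsp_distances(aligned2["flexion"].landmarks())
    np.testing.assert_allclose(after, base, atol=1e-6)
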