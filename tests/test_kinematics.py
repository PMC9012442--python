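import numpy as np
import pandas as pd
import pytest
import trimesh

from spinekin import kinematics as kin
from spinekin.transforms import RigidTransform, rotation_about_axis

from conftest import random_rigid


# ---------------------------------------------------------------------------
# landmarks


def test_landmark_box_dorsal_cranial_corner():
    box = trimesh.creation.box(extents=(10, 6, 4))
    lm = kin.craniodorsal_landmark(box)
    np.testing.assert_allclose(np.abs(lm.position), [5, 3, 2])
    assert lm.position[0] > 0 and lm.position[2] > 0  # +x cranial, +z dorsal


def test_landmark_same_vertex_under_small_rotation(vertebra_mesh):
    """Rotations < 15 deg about the mediolateral axis keep the same vertex."""
    base = kin.craniodorsal_landmark(vertebra_mesh)
    for angle in (-12.0, -5.0, 5.0, 12.0):
        R = rotation_about_axis([0, 1, 0], angle)
        t = RigidTransform(R, [3.0, -1.0, 2.0])
        moved = vertebra_mesh.copy()
        moved.vertices = t.apply(moved.vertices)
        lm = kin.craniodorsal_landmark(moved)
        assert lm.vertex_index == base.vertex_index
        np.testing.assert_allclose(lm.position, t.apply(base.position), atol=1e-9)


def test_landmark_pca_frame_stable_under_large_tilt(vertebra_mesh):
    """The orientation-normalized rule survives tilts the literal rule cannot."""
    base = kin.craniodorsal_landmark(vertebra_mesh, frame="pca")
    for angle in (-30.0, 30.0):
        R = rotation_about_axis([0, 1, 0], angle)
        t = RigidTransform(R, np.zeros(3))
        moved = vertebra_mesh.copy()
        moved.vertices = t.apply(moved.vertices)
        lm = kin.craniodorsal_landmark(moved, frame="pca")
        np.testing.assert_allclose(lm.position, t.apply(base.position), atol=1e-6)


def test_landmark_degenerate_fraction_errors(vertebra_mesh):
    with pytest.raises(ValueError):
        kin.craniodorsal_landmark(vertebra_mesh, dorsal_fraction=-1.0)


# ---------------------------------------------------------------------------
# distances


def test_inter_dsp_constructed_values():
    d = kin.inter_dsp_distances([(0, 0, 0), (35.87, 0, 0), (35.87, 0, 0)])
    np.testing.assert_allclose(d, [35.87, 0.0])
    with pytest.raises(ValueError):
        kin.inter_dsp_distances([(0, 0, 0)])


def test_inter_dsp_rigid_invariance():
    rng = np.random.default_rng(2)
    pts = rng.normal(size=(9, 3)) * 40
    t = random_rigid(rng)
    np.testing.assert_allclose(
        kin.inter_dsp_distances(t.apply(pts)), kin.inter_dsp_distances(pts), atol=1e-9
    )


def test_total_length_straight_chain_and_triangle_inequality():
    chain = [(i * 39.9, 0.0, 0.0) for i in range(9)]
    assert kin.total_length(chain) == pytest.approx(8 * 39.9)
    rng = np.random.default_rng(3)
    curved = rng.normal(size=(9, 3)) * 30
    assert kin.total_length(curved) <= kin.inter_dsp_distances(curved).sum() + 1e-12
    two = [(0, 0, 0), (5, 0, 0)]
    assert kin.total_length(two) == kin.inter_dsp_distances(two)[0]


def test_rom_per_space():
    assert kin.rom_per_space(10.0, 10.0) == 0.0
    assert kin.rom_per_space(23.5, 17.9) == pytest.approx(5.6)
    np.testing.assert_allclose(kin.rom_per_space([30, 40], [48, 35]), [18, 5])
    with pytest.raises(ValueError):
        kin.rom_per_space(-1.0, 2.0)


# ---------------------------------------------------------------------------
# Hausdorff


def test_hausdorff_identical_and_345():
    assert kin.hausdorff(np.zeros((1, 3)), np.array([[3.0, 4.0, 0.0]])) == 5.0
    box = trimesh.creation.box(extents=(5, 5, 5))
    assert kin.hausdorff(box, box.copy(), sample_n=500) == pytest.approx(0.0, abs=1e-9)


def test_hausdorff_vertex_mode_matches_brute_force():
    rng = np.random.default_rng(4)
    a = rng.normal(size=(300, 3)) * 10
    b = rng.normal(size=(300, 3)) * 10 + 2
    full = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    d_ab = full.min(axis=1).max()
    d_ba = full.min(axis=0).max()
    assert kin.hausdorff(a, b, symmetric=False) == pytest.approx(d_ab, abs=0)
    assert kin.hausdorff(b, a, symmetric=False) == pytest.approx(d_ba, abs=0)
    assert kin.hausdorff(a, b) == pytest.approx(max(d_ab, d_ba), abs=0)


def test_hausdorff_symmetric_dominates_directed():
    rng = np.random.default_rng(5)
    a, b = rng.normal(size=(50, 3)), rng.normal(size=(60, 3)) + 0.5
    sym = kin.hausdorff(a, b)
    assert sym >= kin.hausdorff(a, b, symmetric=False) - 1e-12
    assert sym >= kin.hausdorff(b, a, symmetric=False) - 1e-12


@pytest.mark.parametrize("seed", range(5))
def test_hausdorff_triangle_inequality(seed):
    rng = np.random.default_rng(seed)
    a, b, c = (rng.normal(size=(40, 3)) * 5 + rng.normal(size=3) * 3 for _ in range(3))
    hab = kin.hausdorff(a, b)
    hbc = kin.hausdorff(b, c)
    hac = kin.hausdorff(a, c)
    assert hac <= hab + hbc + 1e-9


def test_hausdorff_empty_errors():
    with pytest.raises(ValueError):
        kin.hausdorff(np.zeros((0, 3)), np.zeros((3, 3)))


# ---------------------------------------------------------------------------
# motion decomposition


def test_decompose_identity_is_zero():
    mc = kin.decompose_motion(RigidTransform.identity(), (5.0, 5.0, 5.0))
    assert mc.dorsoventral == mc.craniocaudal == mc.mediolateral == 0.0
    assert mc.total_angle_deg == 0.0 and mc.ml_axis_angle_deg == 0.0


def test_decompose_pure_ml_rotation():
    t = RigidTransform(rotation_about_axis([0, 1, 0], 30.0), np.zeros(3))
    mc = kin.decompose_motion(t, (0.0, 0.0, 0.0))  # reference on the axis
    assert mc.total_angle_deg == pytest.approx(30.0, abs=1e-9)
    assert mc.ml_axis_angle_deg == pytest.approx(30.0, abs=1e-9)
    assert mc.dorsoventral == pytest.approx(0.0, abs=1e-9)


def test_decompose_reports_reference_point_displacement():
    t = RigidTransform(np.eye(3), [1.0, -2.0, 3.0])
    mc = kin.decompose_motion(t, (10.0, 20.0, 30.0))
    assert mc.dorsoventral == 3.0  # |z|
    assert mc.craniocaudal == 1.0  # |x|
    assert mc.mediolateral == 2.0  # |y|


@pytest.mark.parametrize("seed", range(3))
def test_total_angle_matches_sampled_vector_maximization(seed):
    """Rotation angle equals the max angle between v and Rv over unit vectors."""
    rng = np.random.default_rng(seed)
    t = random_rigid(rng, max_angle_deg=150)
    mc = kin.decompose_motion(t)
    v = rng.normal(size=(200000, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    w = v @ t.rotation.T
    angles = np.degrees(np.arccos(np.clip(np.einsum("ij,ij->i", v, w), -1, 1)))
    assert mc.total_angle_deg == pytest.approx(angles.max(), abs=1e-3)


@pytest.mark.parametrize("seed", range(5))
def test_decompose_recompose_round_trip(seed):
    rng = np.random.default_rng(seed)
    t = random_rigid(rng)
    mc = kin.decompose_motion(t, rng.normal(size=3) * 10)
    again = kin.recompose_motion(mc)
    assert again.almost_equals(t, tol=1e-9)


def test_decompose_rejects_non_orthonormal():
    class Fake:
        rotation = np.eye(3) * 1.5
        translation = np.zeros(3)

    with pytest.raises(ValueError):
        kin.decompose_motion(Fake())


# ---------------------------------------------------------------------------
# effect summaries


def _pair_frame(metric, pre, post):
    return pd.DataFrame(
        {
            "specimen": ["s1", "s1"],
            "condition": ["pre", "post"],
            metric: [pre, post],
        }
    )


def test_effects_printed_value_arithmetic():
    summary = kin.summarize_effects(_pair_frame("cc", 22.9, 29.8), ["cc"], n_sites=8)
    row = summary.iloc[0]
    assert row["change"] == pytest.approx(6.9, abs=1e-9)
    assert round(row["percent_change"], 1) == 30.1
    assert round(row["per_site_percent"], 1) == 3.8


def test_effects_no_change_is_zero():
    row = kin.summarize_effects(_pair_frame("m", 17.9, 17.9), ["m"]).iloc[0]
    assert row["change"] == 0.0 and row["percent_change"] == 0.0


def test_effects_unpaired_specimens_error():
    df = pd.DataFrame(
        {"specimen": ["a", "b"], "condition": ["pre", "post"], "m": [1.0, 2.0]}
    )
    with pytest.raises(ValueError, match="unpaired"):
        kin.summarize_effects(df, ["m"])


def test_effects_percent_identity_before_rounding():
    """Group-mean percent = 100 x change / pre_mean, exactly."""
    rng = np.random.default_rng(6)
    n = 7
    df = pd.DataFrame(
        {
            "specimen": [f"s{i}" for i in range(n)] * 2,
            "condition": ["pre"] * n + ["post"] * n,
            "m": np.concatenate([rng.uniform(10, 20, n), rng.uniform(15, 25, n)]),
        }
    )
    row = kin.summarize_effects(df, ["m"]).iloc[0]
    assert row["percent_change_of_means"] == pytest.approx(
        100.0 * row["change"] / row["pre_mean"], abs=1e-9
    )
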