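import json
from dataclasses import replace

import numpy as np
import pytest

from spinekin import kinematics as kin
from spinekin import synthetic_spine as ss


def test_default_template_geometry(resting_pose, default_template):
    """Nine watertight vertebrae, eight 39.9 mm gaps, 310 mm chord."""
    assert len(resting_pose.labels) == 9
    for mesh in resting_pose.mesh_list():
        assert mesh.is_watertight
        assert mesh.volume > 0
    lms = resting_pose.landmarks()
    gaps = kin.inter_dsp_distances(lms)
    np.testing.assert_allclose(gaps, 39.9, atol=1e-9)
    total = kin.total_length(lms)
    assert total == pytest.approx(default_template.target_total_length, abs=1e-6)
    assert total <= 8 * 39.9 + 1e-9  # chord never exceeds the summed links


def test_dorsal_process_is_distinguishable(vertebra_mesh, default_template):
    """The spinous process rises at least twice the body height above it."""
    zmax = vertebra_mesh.vertices[:, 2].max()
    body_top = default_template.body_size[2] / 2
    assert zmax - body_top >= 2 * default_template.body_size[2]


def test_two_vertebra_template_single_exact_gap():
    t = ss.SpineTemplate(n_vertebrae=2, target_total_length=None)
    pose = ss.build_template(t)
    gaps = kin.inter_dsp_distances(pose.landmarks())
    assert gaps.shape == (1,)
    assert gaps[0] == pytest.approx(t.resting_gap, abs=1e-9)


def test_template_rejects_bad_parameters():
    with pytest.raises(ValueError):
        ss.SpineTemplate(n_vertebrae=1)
    with pytest.raises(ValueError):
        ss.SpineTemplate(body_size=(0.0, 40.0, 44.0))
    with pytest.raises(ValueError):
        ss.SpineTemplate(labels=("A", "A", "B"), n_vertebrae=3)
    with pytest.raises(ValueError):
        # chord shorter than geometrically reachable
        ss.build_template(ss.SpineTemplate(target_total_length=150.0))


def test_resting_articulation_is_identity(resting_pose, default_joints):
    pose, gt = ss.articulate(resting_pose, default_joints, "resting", "pre")
    for t in gt.transforms.values():
        assert t.is_identity(tol=1e-12)
    np.testing.assert_allclose(
        gt.inter_dsp, kin.inter_dsp_distances(resting_pose.landmarks()), atol=1e-9
    )


def test_single_joint_displacement_closed_form():
    """Chord displacement of a landmark equals |2 sin(theta/2)| x lever arm."""
    t = ss.SpineTemplate(n_vertebrae=2, target_total_length=None)
    pose = ss.build_template(t)
    lm = pose.landmarks()[1].position
    pivot = pose.joint_pivots[0]
    lever = np.linalg.norm(lm - pivot)
    for theta in (2.0, 5.0, 10.0):
        j = ss.JointConfig(flexion_amplitude_deg=theta, extension_amplitude_deg=0.0)
        _, gt = ss.articulate(pose, j, "flexion", "pre")
        moved = gt.landmarks[t.labels[1]]
        expected = abs(2 * np.sin(np.deg2rad(theta) / 2)) * lever
        assert np.linalg.norm(moved - lm) == pytest.approx(expected, rel=1e-9)


def test_flexion_closes_extension_opens(resting_pose, default_joints):
    rest = kin.inter_dsp_distances(resting_pose.landmarks())
    _, flex = ss.articulate(resting_pose, default_joints, "flexion", "pre")
    _, ext = ss.articulate(resting_pose, default_joints, "extension", "pre")
    assert np.all(flex.inter_dsp < rest)
    assert np.all(ext.inter_dsp > rest)


def test_swap_phase_labels_swaps_conventions(resting_pose, default_joints):
    swapped = replace(default_joints, swap_phase_labels=True)
    _, flex = ss.articulate(resting_pose, swapped, "flexion", "pre")
    _, ext = ss.articulate(resting_pose, swapped, "extension", "pre")
    rest = kin.inter_dsp_distances(resting_pose.landmarks())
    assert np.all(flex.inter_dsp > rest)
    assert np.all(ext.inter_dsp < rest)


def test_post_condition_moves_every_space_more(resting_pose, default_joints):
    """Desmotomy multiplies the flexion amplitude: |delta| grows at all 8 spaces."""
    rest = kin.inter_dsp_distances(resting_pose.landmarks())
    _, pre = ss.articulate(resting_pose, default_joints, "flexion", "pre")
    _, post = ss.articulate(resting_pose, default_joints, "flexion", "post")
    assert np.all(np.abs(post.inter_dsp - rest) > np.abs(pre.inter_dsp - rest))


def test_articulation_preserves_internal_distances(resting_pose, default_joints):
    """Rigid motion: within-vertebra vertex distances unchanged (1e-9 rel)."""
    pose, _ = ss.articulate(resting_pose, default_joints, "flexion", "post")
    rng = np.random.default_rng(0)
    for lb in ("T11", "T15", "L1"):
        v0 = resting_pose.meshes[lb].vertices
        v1 = pose.meshes[lb].vertices
        i, j = rng.integers(0, len(v0), size=(2, 50))
        d0 = np.linalg.norm(v0[i] - v0[j], axis=1)
        d1 = np.linalg.norm(v1[i] - v1[j], axis=1)
        np.testing.assert_allclose(d1, d0, rtol=1e-9)


def test_ground_truth_self_consistent(resting_pose, default_joints):
    resting_lms = {lm.label: lm.position for lm in resting_pose.landmarks()}
    for phase, cond in (("flexion", "pre"), ("extension", "post")):
        _, gt = ss.articulate(resting_pose, default_joints, phase, cond)
        gt.check_self_consistent(resting_lms, tol=1e-9)


def test_ground_truth_matches_mesh_measurements(resting_pose, default_joints):
    """Oracle equivalence: stored GT equals kinematics on the meshes (1e-6)."""
    pose, gt = ss.articulate(resting_pose, default_joints, "flexion", "post")
    lms = pose.landmarks()
    np.testing.assert_allclose(
        gt.inter_dsp, kin.inter_dsp_distances(lms), atol=1e-6
    )
    assert gt.total_length == pytest.approx(kin.total_length(lms), abs=1e-6)


def test_isld_multiplier_monotonic(resting_pose, default_joints):
    """Per-space ROM and L1 excursion grow strictly with the multiplier."""
    roms, excursions = [], []
    for mult in (1.0, 1.15, 1.3, 1.45, 1.6):
        j = replace(default_joints, isld_flexion_multiplier=mult)
        _, flex = ss.articulate(resting_pose, j, "flexion", "post")
        _, ext = ss.articulate(resting_pose, j, "extension", "post")
        roms.append(np.abs(flex.inter_dsp - ext.inter_dsp))
        t_fe = ext.transforms["L1"] @ flex.transforms["L1"].inverse()
        centroid = resting_pose.meshes["L1"].centroid
        mc = kin.decompose_motion(t_fe, centroid)
        excursions.append((mc.dorsoventral, mc.craniocaudal, mc.ml_axis_angle_deg))
    roms = np.array(roms)
    assert np.all(np.diff(roms, axis=0) > 0)  # every space, every step
    exc = np.array(excursions)
    assert np.all(np.diff(exc, axis=0) > 0)


def test_excessive_amplitude_raises(resting_pose):
    j = ss.JointConfig(flexion_amplitude_deg=10.0, extension_amplitude_deg=0.0)
    with pytest.raises(ValueError, match="interpenetrate"):
        ss.articulate(resting_pose, j, "flexion", "post")


def test_sampler_deterministic_and_sized(default_template, default_joints):
    s = ss.SpecimenSampler(n_specimens=7, seed=1)
    a = ss.sample_specimens(s, default_template, default_joints)
    b = ss.sample_specimens(s, default_template, default_joints)
    assert len(a) == 7
    for (ta, ja), (tb, jb) in zip(a, b):
        assert ta == tb and ja == jb


def test_sampler_zero_sd_returns_template(default_template, default_joints):
    s = ss.SpecimenSampler(n_specimens=3, gap_sd=0, gap_space_sd=0,
                           amplitude_scale_sd=0, body_scale_sd=0, seed=9)
    for t, j in ss.sample_specimens(s, default_template, default_joints):
        np.testing.assert_allclose(t.gaps(), default_template.gaps(), atol=1e-12)
        assert j.flexion_amplitude_deg == default_joints.flexion_amplitude_deg


def test_write_pose_manifest(tmp_path, resting_pose, default_joints):
    pose, gt = ss.articulate(resting_pose, default_joints, "flexion", "pre")
    path = ss.write_pose(pose, tmp_path, ground_truth=gt)
    manifest = json.loads(path.read_text())
    assert manifest["labels"] == list(pose.labels)
    for lb in pose.labels:
        assert (tmp_path / manifest["files"][lb]).exists()
        m = np.array(manifest["ground_truth"][lb])
        assert m.shape == (4, 4)
        np.testing.assert_allclose(m, gt.transforms[lb].matrix, atol=1e-12)
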