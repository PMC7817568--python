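"""Spherical registration: reference building, optimisation, warp application."""

import warnings

import numpy as np
import pytest

from sulcmorph.errors import DataError
from sulcmorph.mesh import LabelSet, ScalarField
from sulcmorph.registration import (
    RegistrationConfig,
    SphericalWarp,
    apply_warp,
    build_depth_reference,
    build_reference,
    channel_dice,
    depth_channel,
    label_channels,
    register,
    warp_vertices,
)
from sulcmorph.simulate import CohortSpec, evaluate_labels, sample_participant


def _rot_z(deg):
    a = np.radians(deg)
    return np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1.0]])


@pytest.fixture(scope="module")
def template(template_left):
    return template_left


@pytest.fixture(scope="module")
def reference(template_left):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_reference([template_left.labels, template_left.labels],
                               template_left.mesh, 0.4)


# ---------------------------------------------------------------- reference


def test_reference_identical_cohort_is_the_label(template, reference):
    assert np.array_equal(reference.channels, label_channels(template.labels))


def test_reference_two_disjoint_participants_half_everywhere(ico3):
    n = ico3.n_vertices
    a = np.zeros(n, np.int32)
    b = np.zeros(n, np.int32)
    a[:5] = 1
    b[5:10] = 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ref = build_reference([LabelSet(values=a), LabelSet(values=b)], ico3, 0.4)
    # mean is 0.5 in the union, > 0.4 -> retained
    assert np.array_equal(np.flatnonzero(ref.channels[:, 0]), np.arange(10))


def test_reference_matches_hand_thresholded_mean(ico3):
    n = ico3.n_vertices
    rng = np.random.default_rng(7)
    sets = [LabelSet(values=(rng.random(n) < 0.4).astype(np.int32)) for _ in range(5)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ref = build_reference(sets, ico3, 0.4)
    mean = sum((s.values == 1).astype(float) for s in sets) / 5.0
    assert np.array_equal(ref.channels[:, 0], (mean > 0.4).astype(float))
    with pytest.raises(DataError):
        build_reference(sets[:1], ico3)


def test_depth_reference_is_mean_normalised_depth(ico3):
    rng = np.random.default_rng(8)
    ds = [ScalarField(values=rng.normal(size=ico3.n_vertices), meaning="depth") for _ in range(3)]
    ref = build_depth_reference(ds, ico3)
    expected = sum(depth_channel(d) for d in ds) / 3.0
    assert np.allclose(ref.channels, expected)
    assert ref.channels.min() >= 0.0 and ref.channels.max() <= 1.0


# ----------------------------------------------------------------- register


def test_register_fixed_point(template, reference):
    warp, diag = register(label_channels(template.labels), template.mesh, reference,
                          RegistrationConfig.fast())
    assert warp.mean_displacement() <= 1e-12
    for trace in diag["cost_traces"]:
        assert trace[-1] == pytest.approx(trace[0], abs=1e-12)


def test_register_cost_non_increasing(template, reference):
    spec = CohortSpec(n_struct=2, n_func=0)
    p = sample_participant(template, spec, "left", seed=3)
    _, diag = register(label_channels(p.labels), p.mesh, reference, RegistrationConfig.fast())
    for trace in diag["cost_traces"]:
        diffs = np.diff(trace)
        assert (diffs <= 1e-12).all()
        assert trace[-1] <= trace[0] + 1e-12


def test_register_rotation_recovery_dice(template, reference):
    """A 5-degree rotated label set registers back to Dice >= 0.9 per channel."""
    mesh = template.mesh
    rot = LabelSet(values=evaluate_labels(mesh.sphere_coords @ _rot_z(5.0)), hemisphere="left")
    cfg = RegistrationConfig(levels=3, sigma_in=(10, 5, 2), sigma_ref=(10, 5, 2),
                             lambda_=(0.1, 0.01, 0.01), iterations=(10, 10, 5),
                             cp_grid=(2, 3, 4), data_grid=(4, 5, 5))
    warp, _ = register(label_channels(rot), mesh, reference, cfg)
    warped = apply_warp(warp, mesh, rot, reference.mesh)
    dice = channel_dice(label_channels(warped) > 0.5, reference.channels > 0.5)
    assert dice.min() >= 0.9, dice


def test_register_improves_dice_for_warped_cohort(template):
    spec = CohortSpec(n_struct=12, n_func=0)
    parts = [sample_participant(template, spec, "left",
                                seed=np.random.SeedSequence([3, i, 0]), participant_id=i)
             for i in range(12)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ref = build_reference([p.labels for p in parts], template.mesh, 0.4)
    cfg = RegistrationConfig.fast()
    improved = 0
    for p in parts:
        ch = label_channels(p.labels)
        pre = channel_dice(ch > 0.5, ref.channels > 0.5).mean()
        warp, _ = register(ch, p.mesh, ref, cfg)
        post = channel_dice(label_channels(apply_warp(warp, p.mesh, p.labels, ref.mesh)) > 0.5,
                            ref.channels > 0.5).mean()
        improved += post >= pre
    assert improved >= 0.95 * len(parts)


def test_regularisation_monotonicity(template, reference):
    """Stronger smoothness penalty never increases the mean displacement."""
    spec = CohortSpec(n_struct=2, n_func=0)
    p = sample_participant(template, spec, "left", seed=4)
    ch = label_channels(p.labels)
    disps = []
    for lam in (0.0, 0.01, 1.0, 100.0):
        cfg = RegistrationConfig.fast()
        cfg.lambda_ = (lam, lam)
        warp, _ = register(ch, p.mesh, reference, cfg)
        disps.append(warp.mean_displacement())
    assert all(a >= b - 1e-12 for a, b in zip(disps, disps[1:]))


def test_no_folding_after_registration(template, reference):
    spec = CohortSpec(n_struct=2, n_func=0, warp_sd=3.0)
    p = sample_participant(template, spec, "left", seed=5)
    warp, _ = register(label_channels(p.labels), p.mesh, reference, RegistrationConfig.fast())
    warped = warp.transform(template.mesh.sphere_coords)
    warped /= np.linalg.norm(warped, axis=1, keepdims=True)
    F = template.mesh.faces
    orient0 = np.sign(np.linalg.det(template.mesh.sphere_coords[F]))
    orient1 = np.sign(np.linalg.det(warped[F]))
    assert (orient0 == orient1).all()


# --------------------------------------------------------------- apply_warp


def test_apply_warp_identity(template):
    warp = SphericalWarp.identity()
    out = apply_warp(warp, template.mesh, template.labels, template.mesh)
    assert np.array_equal(out.values, template.labels.values)
    v = warp_vertices(warp, template.mesh, [10, 20], template.mesh)
    assert list(v) == [10, 20]


def test_apply_warp_known_rotation_moves_points(template):
    """A warp built from a known rotation maps a point to its rotated image
    (within one vertex spacing)."""
    mesh = template.mesh
    R = _rot_z(5.0)
    cp = SphericalWarp.identity(subdiv=3)
    cp.displacements = cp.cp_points @ R.T - cp.cp_points
    src = 123
    out = warp_vertices(cp, mesh, [src], mesh)[0]
    target = mesh.sphere_coords[src] @ R.T
    ang_err = np.degrees(np.arccos(np.clip(mesh.sphere_coords[out] @ target, -1, 1)))
    spacing = np.degrees(mesh.mean_edge_length() / 100.0)
    assert ang_err <= spacing


def test_warp_preserves_containment(template):
    """A label and a peak inside it, transported by the same warp, keep
    their containment relation."""
    spec = CohortSpec(n_struct=2, n_func=0)
    rng = np.random.default_rng(17)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ref = build_reference([template.labels, template.labels], template.mesh, 0.4)
    for seed in range(3):
        p = sample_participant(template, spec, "left", seed=seed)
        warp, _ = register(label_channels(p.labels), p.mesh, ref, RegistrationConfig.fast())
        moved = apply_warp(warp, p.mesh, p.labels, ref.mesh)
        for seg in ("cs_2", "cs_3"):
            inside = np.flatnonzero(p.labels.mask(seg))
            pick = int(rng.choice(inside))
            out_v = warp_vertices(warp, p.mesh, [pick], ref.mesh)[0]
            # the transported vertex lands in (or immediately at the border
            # of) the transported label
            d = np.degrees(np.arccos(np.clip(
                ref.mesh.sphere_coords[moved.mask(seg)] @ ref.mesh.sphere_coords[out_v], -1, 1)))
            assert d.min() <= 1.5 * np.degrees(ref.mesh.mean_edge_length() / 100.0)
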