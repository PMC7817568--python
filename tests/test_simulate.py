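"""Synthetic cohort generator: template, morphotypes, activation volumes."""

import numpy as np
import pytest
from scipy.sparse.csgraph import connected_components

import sulcmorph.tables as tables
from sulcmorph.errors import ConfigError
from sulcmorph.mesh import BACKGROUND, SEGMENTS
from sulcmorph.morphometry import classify_morphotype
from sulcmorph.peaks import extract_peak
from sulcmorph.simulate import (
    EFFECTORS,
    CohortSpec,
    make_cohort,
    make_template,
    sample_participant,
    simulate_activation,
)


def _segment_connected(participant, segment):
    mesh = participant.mesh
    mask = participant.labels.mask(segment)
    idx = np.flatnonzero(mask)
    if idx.size <= 1:
        return True
    sub = mesh.edge_graph()[np.ix_(idx, idx)]
    ncomp, _ = connected_components(sub, directed=False)
    return ncomp == 1


# ------------------------------------------------------------------ template


def test_template_has_all_segments_disjoint_and_canonical(template_left):
    p = template_left
    counts = {s: int(p.labels.mask(s).sum()) for s in SEGMENTS}
    assert all(c > 0 for c in counts.values())
    # one ID per vertex by construction; cs_2 is the largest segment
    assert max(counts, key=counts.get) == "cs_2"
    assert classify_morphotype(p.labels, p.mesh, p.depth).type == 1
    # depth negative inside every label, positive at the crowns
    lab = p.labels.values
    assert (p.depth.values[lab != BACKGROUND] < 0).all()
    assert (p.depth.values[lab == BACKGROUND] > 0).all()
    # thickness increases dorsal -> ventral
    z = p.mesh.sphere_coords[:, 2]
    assert p.thickness.values[z < -0.2].mean() > p.thickness.values[z > 0.2].mean()


def test_template_deterministic(template_left):
    again = make_template("left")
    assert np.array_equal(again.labels.values, template_left.labels.values)
    assert np.array_equal(again.depth.values, template_left.depth.values)


# -------------------------------------------------------------- participants


def test_forced_types_classify_back_at_zero_warp(template_left):
    spec = CohortSpec(n_struct=2, n_func=0, warp_sd=0.0)
    for t in (1, 2, 3, 4, 5):
        p = sample_participant(template_left, spec, "left", seed=t, force_type=t)
        assert classify_morphotype(p.labels, p.mesh, p.depth).type == t


def test_type1_at_zero_warp_matches_template_up_to_offset(template_left):
    spec = CohortSpec(n_struct=2, n_func=0, warp_sd=0.0, hemi_offset=0.0)
    p = sample_participant(template_left, spec, "left", seed=0, force_type=1)
    assert np.array_equal(p.labels.values, template_left.labels.values)


def test_sample_participant_deterministic(template_left):
    spec = CohortSpec(n_struct=2, n_func=0)
    a = sample_participant(template_left, spec, "left", seed=42)
    b = sample_participant(template_left, spec, "left", seed=42)
    assert np.array_equal(a.labels.values, b.labels.values)
    assert a.morphotype_true == b.morphotype_true
    assert a.peak_true == b.peak_true


def test_labels_partition_and_connected_at_zero_warp(template_left):
    spec = CohortSpec(n_struct=2, n_func=0, warp_sd=0.0)
    for t in (1, 2, 3, 4, 5):
        p = sample_participant(template_left, spec, "left", seed=t, force_type=t)
        for seg in SEGMENTS:
            assert _segment_connected(p, seg), (t, seg)


def test_invalid_spec_rejected():
    with pytest.raises(ConfigError):
        CohortSpec(n_struct=2, n_func=5)
    with pytest.raises(ConfigError):
        CohortSpec(warp_sd=-1.0)
    with pytest.raises(ConfigError):
        CohortSpec(type_probs={"left": [1, 0, 0, 0, 0], "right": [0.5, 0.5, 0.5, 0, 0]})


# -------------------------------------------------------------------- cohort


def test_cohort_shape_and_functional_subset():
    spec = CohortSpec(n_struct=3, n_func=1, mesh_subdivisions=4, voxel_size=3.0)
    cohort = make_cohort(spec)
    assert len(cohort) == 6  # participants x hemispheres
    func = [p for p in cohort if p.is_functional]
    assert {p.participant_id for p in func} == {0}
    assert all(set(p.stat_volumes) == set(EFFECTORS) for p in func)
    none = CohortSpec(n_struct=2, n_func=0, mesh_subdivisions=4)
    assert all(p.stat_volumes is None for p in make_cohort(none))


def test_default_type_frequencies_match_reference_proportions():
    """Empirical morphotype draws stay inside a wide binomial CI of the
    published per-hemisphere proportions (n = 200 draws/hemisphere)."""
    from scipy.stats import binom

    spec = CohortSpec(n_struct=2, n_func=0)
    tpl = {h: make_template(h) for h in ("left", "right")}
    n = 200
    for hemi in ("left", "right"):
        draws = np.array([
            sample_participant(tpl[hemi], spec, hemi,
                               seed=np.random.SeedSequence([99, i, 0 if hemi == "left" else 1])).morphotype_true
            for i in range(n)
        ])
        probs = tables.default_type_probs().loc[hemi].to_numpy()
        for t in range(1, 6):
            k = int((draws == t).sum())
            lo, hi = binom.ppf([0.0005, 0.9995], n, probs[t - 1])
            assert lo <= k <= hi, (hemi, t, k)


# ---------------------------------------------------------------- activation


def test_noiseless_activation_recovers_anchor(template_left):
    spec = CohortSpec(n_struct=1, n_func=1, warp_sd=0.0, peak_noise_sd=0.0, noise_sd=0.0)
    p = sample_participant(template_left, spec, "left", seed=0, force_type=1)
    for eff in EFFECTORS:
        stat, roi = simulate_activation(p, eff, seed=0, spec=spec)
        pk = extract_peak(stat, roi, p.mesh, eff, "left")
        assert pk.vertex == p.anchors[eff], eff


def test_hand_roi_covers_all_central_sulcus_voxels(template_left):
    from sulcmorph.mesh import surface_to_volume
    from sulcmorph.simulate import _strip_grid

    spec = CohortSpec(n_struct=1, n_func=1, warp_sd=0.0)
    p = sample_participant(template_left, spec, "left", seed=0, force_type=1)
    _, roi = simulate_activation(p, "hand", seed=0, spec=spec)
    grid = _strip_grid(p, spec.voxel_size)
    segvols = surface_to_volume(p.mesh, p.labels, grid)
    for seg in ("cs_1", "cs_2", "cs_3", "cs_4", "cs_5"):
        assert np.all(roi.data[segvols[seg].data > 0] > 0)


def test_ventral_larynx_anchor_mixing_follows_configured_ratio(template_left):
    """Anchor segment draws across seeds are binomial with the 14/40 ratio."""
    from scipy.stats import binom

    spec = CohortSpec(n_struct=2, n_func=2)
    n = 300
    k = 0
    for i in range(n):
        p = sample_participant(template_left, spec, "left", seed=np.random.SeedSequence([55, i]))
        k += p.anchor_segment["larynx_ventral"] == "ascs_lat"
    frac = tables.ventral_larynx_ascs_lat_fraction()
    lo, hi = binom.ppf([0.0005, 0.9995], n, frac)
    assert lo <= k <= hi


def test_unknown_effector_rejected(template_left):
    spec = CohortSpec(n_struct=1, n_func=1)
    p = sample_participant(template_left, spec, "left", seed=0)
    with pytest.raises(ConfigError):
        simulate_activation(p, "elbow", seed=0, spec=spec)
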