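"""Synthetic cortical cohort generator.

The generator emulates the statistical structure the analysis pipeline
assumes: a cohort of participant hemispheres, each carrying a cortical
mesh, per-vertex labels for the five central-sulcus segments (``cs_1`` …
``cs_5``), the two anterior subcentral segments (``ascs_lat``,
``ascs_op``) and the posterior subcentral sulcus (``pscs``), sulcal depth
and cortical thickness fields, and — for a functional subset — simulated
task-activation volumes for five effectors.

The cortical sheet is an icosphere (no folding geometry; see the methods
note).  Labels are bands and discs in spherical coordinates: azimuth
``a = atan2(y, x)`` (degrees, +y anterior) and elevation ``e = asin(z)``
(degrees, +z dorsal).  The central sulcus is a dorso-ventral strip split
into five bands; ``cs_2`` is the widest (the "hand-knob" segment is the
largest segment of the real sulcus).  The five subcentral morphotypes
differ only in the placement of the ``ascs_lat`` disc:

* Type 1 — canonical: separate from every neighbour,
* Type 2 — overlapping/contiguous with the central sulcus (``cs_5``),
* Type 3 — shifted opercularly, contiguous with ``ascs_op``,
* Type 4 — shifted anteriorly, contiguous with the ``iprs`` proxy band,
* Type 5 — anterior to ``ascs_op`` without merging with anything.

Inter-individual variability has three sources, all seeded: a smooth
band-limited tangential warp of the evaluation coordinates (``warp_sd``
degrees RMS), an independent positional jitter of the ``ascs_lat`` disc
centre (``ascs_jitter_factor × warp_sd``), and a constant posterior
azimuth offset for left hemispheres (hemispheric torque stand-in).
Setting ``warp_sd = 0`` therefore switches off all positional
variability.

All randomness flows from ``CohortSpec.seed`` via explicit
``numpy.random.SeedSequence`` splitting: participant ``i`` / hemisphere
``h`` uses ``SeedSequence([seed, i, h])`` and its activation volumes
``SeedSequence([seed, i, h, 1000 + effector_index])``, so any participant
can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import tables
from .errors import ConfigError
from .mesh import (
    BACKGROUND,
    IPRS,
    SEGMENT_IDS,
    LabelSet,
    ScalarField,
    TriangleMesh,
    VolumeGrid,
    icosphere,
    surface_to_volume,
)

__all__ = [
    "EFFECTORS",
    "ANCHOR_SEGMENTS",
    "CohortSpec",
    "ParticipantData",
    "make_template",
    "sample_participant",
    "simulate_activation",
    "make_cohort",
    "segment_centroid_vertex",
]

EFFECTORS = ("hand", "lip", "tongue", "larynx_dorsal", "larynx_ventral")

#: Deterministic effector -> anchor segment map; the ventral larynx anchor is
#: sampled between cs_5 and ascs_lat (see CohortSpec.ventral_larynx_ascs_fraction).
ANCHOR_SEGMENTS: Mapping[str, str] = {
    "hand": "cs_2",
    "larynx_dorsal": "cs_3",
    "lip": "cs_3",
    "tongue": "cs_4",
}

# ---------------------------------------------------------------------------
# template geometry (degrees).  cs_3 spans elevation asin(0.3)..asin(0.5) so
# that at the 100 mm template radius its z-range is exactly the 30-50 mm slab
# used for the dorsal-larynx ROI.
# ---------------------------------------------------------------------------

_CS3_LO = float(np.degrees(np.arcsin(0.3)))  # 17.4576
# central-sulcus bands: (half arc-width across the strip, elevation range);
# the strip runs along the meridian and its width is constant in arc length
# (an azimuth band would thin toward the pole)
_CS_BANDS = {
    "cs_1": (5.0, (58.0, 80.0)),
    "cs_2": (5.0, (30.0, 58.0)),
    "cs_3": (5.0, (_CS3_LO, 30.0)),
    "cs_4": (3.0, (8.0, _CS3_LO)),
    "cs_5": (3.0, (0.0, 8.0)),
}
_RECT_BANDS = {
    "ascs_op": ((18.0, 40.0), (-24.0, -15.0)),
    "pscs": ((-36.0, -14.0), (-24.0, -15.0)),
    "iprs": ((38.0, 48.0), (2.0, 25.0)),
}
_ASCS_RADIUS = 5.0
#: ascs_lat disc centre (azimuth, elevation) per morphotype.
_ASCS_CENTERS = {
    1: (17.0, -5.0),
    2: (5.0, 2.0),
    3: (26.0, -14.0),
    4: (37.0, 6.0),
    5: (34.0, -6.0),
}

#: Signed sulcal depth assigned inside each label (normalised units,
#: negative at the fundus); background sits at the gyral crown value.
_DEPTH = {
    SEGMENT_IDS["cs_1"]: -1.15,
    SEGMENT_IDS["cs_2"]: -1.30,
    SEGMENT_IDS["cs_3"]: -1.10,
    SEGMENT_IDS["cs_4"]: -0.70,
    SEGMENT_IDS["cs_5"]: -0.60,
    SEGMENT_IDS["ascs_lat"]: -0.35,
    SEGMENT_IDS["ascs_op"]: -0.85,
    SEGMENT_IDS["pscs"]: -0.80,
    IPRS: -0.65,
}
_DEPTH_CROWN = 0.5


def _angles(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(azimuth, elevation) in degrees for unit vectors."""
    p = np.atleast_2d(points)
    az = np.degrees(np.arctan2(p[:, 1], p[:, 0]))
    el = np.degrees(np.arcsin(np.clip(p[:, 2], -1.0, 1.0)))
    return az, el


def _unit(a: np.ndarray, e: np.ndarray | float) -> np.ndarray:
    a = np.radians(np.asarray(a, dtype=float))
    e = np.radians(np.asarray(e, dtype=float))
    return np.stack([np.cos(e) * np.cos(a), np.cos(e) * np.sin(a), np.sin(e) * np.ones_like(a)], axis=-1)


def _rotate_z(points: np.ndarray, deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return points @ R.T


def evaluate_labels(
    points: np.ndarray,
    morphotype: int = 1,
    ascs_center: tuple[float, float] | None = None,
    azimuth_shift: float = 0.0,
) -> np.ndarray:
    """Template label field evaluated at unit-sphere points.

    ``azimuth_shift`` (degrees, >0) moves every label posteriorly.  Fixed
    bands are assigned first; the ``ascs_lat`` disc takes the remaining
    vertices, so overlap configurations produce contiguous (merged) but
    disjoint patches.
    """
    if morphotype not in _ASCS_CENTERS:
        raise ConfigError(f"unknown morphotype {morphotype}")
    q = _rotate_z(np.atleast_2d(points), azimuth_shift)
    az, el = _angles(q)
    out = np.zeros(len(q), dtype=np.int32)
    arc = az * np.cos(np.radians(el))  # arc distance from the strip meridian
    for name, (half_w, (e0, e1)) in _CS_BANDS.items():
        m = (out == 0) & (np.abs(arc) <= half_w) & (el >= e0) & (el <= e1)
        out[m] = SEGMENT_IDS[name]
    for name, ((a0, a1), (e0, e1)) in _RECT_BANDS.items():
        sid = IPRS if name == "iprs" else SEGMENT_IDS[name]
        m = (out == 0) & (az >= a0) & (az <= a1) & (el >= e0) & (el <= e1)
        out[m] = sid
    ca, ce = _ASCS_CENTERS[morphotype] if ascs_center is None else ascs_center
    c = _unit(np.array(ca), np.array(ce)).ravel()
    ang = np.degrees(np.arccos(np.clip(q @ c, -1.0, 1.0)))
    out[(out == 0) & (ang <= _ASCS_RADIUS)] = SEGMENT_IDS["ascs_lat"]
    return out


def _depth_from_labels(label_values: np.ndarray) -> np.ndarray:
    d = np.full(len(label_values), _DEPTH_CROWN)
    for sid, v in _DEPTH.items():
        d[label_values == sid] = v
    return d


def _thickness_from_elevation(elevation_deg: np.ndarray) -> np.ndarray:
    # cortical thickness increases dorsal -> ventral (mm)
    return 2.6 - 0.012 * elevation_deg


# ---------------------------------------------------------------------------
# cohort specification
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Study-condition parameters of the synthetic cohort.

    Defaults are the reference study's conditions: 50 structural
    participants, the first 20 of which are functional; per-hemisphere
    morphotype probabilities from the published 100-hemisphere contingency
    table; and a 14/40 ascs_lat share for the ventral-larynx anchor.
    """

    n_struct: int = 50
    n_func: int = 20
    type_probs: Mapping[str, Sequence[float]] | None = None  # hemisphere -> 5 probs
    warp_sd: float = 2.0  # degrees RMS of the smooth spherical warp
    ventral_gradient: float = 1.0  # dorsal->ventral amplification of the warp
    ascs_jitter_factor: float = 1.0  # ascs_lat centre jitter sd = factor * warp_sd
    hemi_offset: float = 3.0  # posterior azimuth offset of left-hemisphere labels (deg)
    peak_noise_sd: float = 2.0  # mm jitter of activation centres
    ventral_larynx_ascs_fraction: float | None = None  # default from reference table
    mesh_subdivisions: int = 5
    radius: float = 100.0  # template sphere radius, mm
    voxel_size: float = 1.5  # activation-grid resolution, mm
    blob_fwhm: float = 7.0  # activation blob FWHM, mm
    noise_sd: float = 0.05  # background noise in stat volumes
    dorsal_larynx_z: tuple[float, float] = (30.0, 50.0)  # ROI slab, world mm
    attach_volumes: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.type_probs is None:
            tp = tables.default_type_probs()
            self.type_probs = {h: tp.loc[h].to_numpy() for h in ("left", "right")}
        else:
            self.type_probs = {h: np.asarray(p, dtype=float) for h, p in self.type_probs.items()}
        for h in ("left", "right"):
            if h not in self.type_probs:
                raise ConfigError(f"type_probs missing hemisphere {h!r}")
            p = np.asarray(self.type_probs[h], dtype=float)
            if p.shape != (5,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-8:
                raise ConfigError("type_probs rows must be 5 nonnegative values summing to 1")
        if self.ventral_larynx_ascs_fraction is None:
            self.ventral_larynx_ascs_fraction = tables.ventral_larynx_ascs_lat_fraction()
        if not 0 <= self.n_func <= self.n_struct:
            raise ConfigError("need 0 <= n_func <= n_struct")
        for name in ("warp_sd", "ascs_jitter_factor", "peak_noise_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 <= self.ventral_larynx_ascs_fraction <= 1:
            raise ConfigError("ventral_larynx_ascs_fraction must be in [0, 1]")


@dataclass
class ParticipantData:
    """Everything simulated for one participant hemisphere."""

    participant_id: int
    hemisphere: str
    mesh: TriangleMesh
    labels: LabelSet
    depth: ScalarField
    thickness: ScalarField
    morphotype_true: int
    anchors: dict[str, int] = field(default_factory=dict)  # effector -> anchor vertex
    peak_true: dict[str, int] = field(default_factory=dict)  # effector -> jittered vertex
    anchor_segment: dict[str, str] = field(default_factory=dict)
    stat_volumes: dict[str, VolumeGrid] | None = None
    roi_volumes: dict[str, VolumeGrid] | None = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def is_functional(self) -> bool:
        return self.stat_volumes is not None


# ---------------------------------------------------------------------------
# warps
# ---------------------------------------------------------------------------


class SmoothSphereWarp:
    """Band-limited random tangential deformation of the unit sphere.

    A sum of ``n_bumps`` Gaussian bumps (angular width ``width_deg``) with
    random 3D amplitudes, projected to the tangent plane and scaled so the
    RMS angular displacement over the template mesh equals ``sd_deg``.
    ``ventral_gradient`` amplifies the displacement toward the ventral
    (-z) pole by the factor ``1 + g * (1 - z) / 2`` on top of that
    normalisation (``warp_sd`` is the dorsal baseline): the ventral
    central-sulcus segments and the subcentral sulci are the anatomically
    more variable ones.
    """

    def __init__(self, rng: np.random.Generator, sd_deg: float, probe_points: np.ndarray,
                 n_bumps: int = 10, width_deg: float = 30.0, ventral_gradient: float = 0.0) -> None:
        self.width = np.radians(width_deg)
        self.gradient = float(ventral_gradient)
        v = rng.normal(size=(n_bumps, 3))
        self.centers = v / np.linalg.norm(v, axis=1, keepdims=True)
        self.amps = rng.normal(size=(n_bumps, 3))
        self.scale = 0.0
        if sd_deg > 0:
            d = self._raw(probe_points, graded=False)  # normalise the baseline field
            rms = float(np.sqrt((d**2).sum(axis=1).mean()))
            if rms > 0:
                self.scale = np.radians(sd_deg) / rms

    def _raw(self, p: np.ndarray, graded: bool = True) -> np.ndarray:
        ang = np.arccos(np.clip(p @ self.centers.T, -1.0, 1.0))
        w = np.exp(-0.5 * (ang / self.width) ** 2)
        d = w @ self.amps
        d -= (np.einsum("ij,ij->i", d, p))[:, None] * p  # tangential part
        if graded and self.gradient > 0:
            d *= (1.0 + self.gradient * (1.0 - p[:, 2]) / 2.0)[:, None]
        return d

    def __call__(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        if self.scale == 0.0:
            return p.copy()
        q = p + self.scale * self._raw(p)
        return q / np.linalg.norm(q, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# participants
# ---------------------------------------------------------------------------

_template_mesh_cache: dict[tuple[int, float], TriangleMesh] = {}


def _shared_mesh(subdivisions: int, radius: float) -> TriangleMesh:
    key = (subdivisions, radius)
    if key not in _template_mesh_cache:
        _template_mesh_cache[key] = icosphere(subdivisions, radius)
    return _template_mesh_cache[key]


def _fields_for(mesh: TriangleMesh, eval_points: np.ndarray, morphotype: int,
                ascs_center: tuple[float, float] | None, azimuth_shift: float,
                hemisphere: str) -> tuple[LabelSet, ScalarField, ScalarField]:
    values = evaluate_labels(eval_points, morphotype, ascs_center, azimuth_shift)
    _, el = _angles(_rotate_z(eval_points, azimuth_shift))
    labels = LabelSet(values=values, hemisphere=hemisphere)
    depth = ScalarField(values=_depth_from_labels(values), meaning="depth")
    thickness = ScalarField(values=_thickness_from_elevation(el), meaning="thickness")
    return labels, depth, thickness


def make_template(hemisphere: str = "left", subdivisions: int = 5, radius: float = 100.0) -> ParticipantData:
    """Canonical (Type 1) hemisphere: deterministic, no warp, no offset."""
    mesh = _shared_mesh(subdivisions, radius)
    labels, depth, thickness = _fields_for(mesh, mesh.sphere_coords, 1, None, 0.0, hemisphere)
    p = ParticipantData(
        participant_id=-1, hemisphere=hemisphere, mesh=mesh, labels=labels,
        depth=depth, thickness=thickness, morphotype_true=1,
    )
    _assign_anchors(p, rng=None, peak_noise_sd=0.0, ascs_fraction=0.0)
    return p


def sample_participant(
    template: ParticipantData,
    spec: CohortSpec,
    hemisphere: str,
    seed: int | np.random.SeedSequence | np.random.Generator,
    participant_id: int = 0,
    force_type: int | None = None,
) -> ParticipantData:
    """Draw one participant hemisphere from the cohort distribution."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = np.asarray(spec.type_probs[hemisphere], dtype=float)
    morphotype = int(force_type) if force_type is not None else int(rng.choice(5, p=probs) + 1)
    if morphotype not in _ASCS_CENTERS:
        raise ConfigError(f"morphotype must be 1-5, got {morphotype}")
    jitter_sd = spec.ascs_jitter_factor * spec.warp_sd
    ca, ce = _ASCS_CENTERS[morphotype]
    center = (ca + rng.normal(0.0, jitter_sd), ce + rng.normal(0.0, jitter_sd)) if jitter_sd > 0 else (ca, ce)
    mesh = template.mesh
    warp = SmoothSphereWarp(rng, spec.warp_sd, mesh.sphere_coords,
                            ventral_gradient=spec.ventral_gradient)
    eval_points = warp(mesh.sphere_coords)
    shift = spec.hemi_offset if hemisphere == "left" else 0.0
    labels, depth, thickness = _fields_for(mesh, eval_points, morphotype, center, shift, hemisphere)
    if not labels.mask("ascs_lat").any():
        # a strongly compressive warp can shrink the disc's preimage below
        # the vertex spacing; keep a minimal one-vertex patch so the
        # hemisphere stays classifiable
        c = _rotate_z(_unit(np.array(center[0]), np.array(center[1]))[None, :], -shift)[0]
        bg = labels.values == BACKGROUND
        idx = np.flatnonzero(bg) if bg.any() else np.arange(len(labels.values))
        v = idx[np.argmax(eval_points[idx] @ c)]
        labels.values[v] = SEGMENT_IDS["ascs_lat"]
        depth.values[v] = _DEPTH[SEGMENT_IDS["ascs_lat"]]
    p = ParticipantData(
        participant_id=participant_id, hemisphere=hemisphere, mesh=mesh, labels=labels,
        depth=depth, thickness=thickness, morphotype_true=morphotype,
    )
    _assign_anchors(p, rng=rng, peak_noise_sd=spec.peak_noise_sd,
                    ascs_fraction=spec.ventral_larynx_ascs_fraction)
    return p


def segment_centroid_vertex(mesh: TriangleMesh, labels: LabelSet, segment: str,
                            subset: np.ndarray | None = None) -> int:
    """Vertex of the segment nearest its spherical centroid."""
    m = labels.mask(segment)
    if subset is not None:
        m = m & subset
    idx = np.flatnonzero(m)
    if idx.size == 0:
        raise ValueError(f"segment {segment} is empty")
    c = mesh.sphere_coords[idx].mean(axis=0)
    c /= np.linalg.norm(c)
    return int(idx[np.argmax(mesh.sphere_coords[idx] @ c)])


def _assign_anchors(p: ParticipantData, rng: np.random.Generator | None,
                    peak_noise_sd: float, ascs_fraction: float) -> None:
    mesh = p.mesh
    radius = float(np.linalg.norm(mesh.vertices[0]))
    for eff in EFFECTORS:
        if eff == "larynx_ventral":
            use_ascs = bool(rng.random() < ascs_fraction) if rng is not None else False
            seg = "ascs_lat" if use_ascs else "cs_5"
            if not p.labels.mask(seg).any():
                seg = "cs_5" if seg == "ascs_lat" else "ascs_lat"  # coarse meshes can drop a patch
        elif eff == "lip":
            seg = "cs_3"
        else:
            seg = ANCHOR_SEGMENTS[eff]
        if not p.labels.mask(seg).any():
            continue  # very coarse meshes can lack a narrow band entirely
        if eff == "lip":
            cs3 = p.labels.mask("cs_3")
            z = mesh.sphere_coords[:, 2]
            ventral = z <= np.median(z[cs3])
            v = segment_centroid_vertex(mesh, p.labels, seg, subset=ventral)
        else:
            v = segment_centroid_vertex(mesh, p.labels, seg)
        p.anchors[eff] = v
        p.anchor_segment[eff] = seg
        if rng is not None and peak_noise_sd > 0:
            sph = mesh.sphere_coords[v]
            t = rng.normal(size=3)
            t -= (t @ sph) * sph
            t /= np.linalg.norm(t)
            ang = abs(rng.normal(0.0, peak_noise_sd)) / radius
            q = np.cos(ang) * sph + np.sin(ang) * t
            _, jv = mesh.sphere_kdtree().query(q)
            p.peak_true[eff] = int(jv)
        else:
            p.peak_true[eff] = v


# ---------------------------------------------------------------------------
# activation volumes
# ---------------------------------------------------------------------------


def _strip_grid(p: ParticipantData, voxel_size: float, margin: float = 10.0) -> VolumeGrid:
    """Empty grid covering the labelled strip's bounding box."""
    key = ("grid", voxel_size)
    if key in p._cache:
        return p._cache[key]
    labelled = p.labels.values != BACKGROUND
    pts = p.mesh.vertices[labelled]
    lo = pts.min(axis=0) - margin
    hi = pts.max(axis=0) + margin
    shape = np.maximum(np.ceil((hi - lo) / voxel_size).astype(int) + 1, 2)
    affine = np.eye(4)
    affine[:3, :3] *= voxel_size
    affine[:3, 3] = lo
    affine = affine.astype(np.float32).astype(float)  # NIfTI sform is float32
    g = VolumeGrid(data=np.zeros(tuple(shape), dtype=np.float32), affine=affine)
    p._cache[key] = g
    return g


def _segment_volumes(p: ParticipantData, grid: VolumeGrid) -> dict[str, VolumeGrid]:
    key = ("segvols", grid.data.shape, grid.affine.tobytes())
    if key not in p._cache:
        p._cache[key] = surface_to_volume(p.mesh, p.labels, grid)
    return p._cache[key]


def _roi_volume(p: ParticipantData, effector: str, grid: VolumeGrid,
                dorsal_larynx_z: tuple[float, float]) -> VolumeGrid:
    from scipy import ndimage

    segvols = _segment_volumes(p, grid)
    cs = np.zeros(grid.shape, dtype=bool)
    for s in ("cs_1", "cs_2", "cs_3", "cs_4", "cs_5"):
        cs |= segvols[s].data > 0
    if effector in ("hand", "lip", "tongue"):
        roi = cs
    elif effector == "larynx_dorsal":
        z = grid.voxel_centers_world()[:, 2].reshape(grid.shape)
        lo, hi = min(dorsal_larynx_z), max(dorsal_larynx_z)
        roi = cs & (z >= lo) & (z <= hi)
    elif effector == "larynx_ventral":
        base = (segvols["cs_5"].data > 0) | (segvols["ascs_lat"].data > 0)
        it = max(1, int(np.ceil(3.0 / grid.voxel_sizes().max())))
        roi = ndimage.binary_dilation(base, iterations=it)
    else:
        raise ConfigError(f"unknown effector {effector!r}")
    return grid.copy_with(roi.astype(np.uint8))


def simulate_activation(
    participant: ParticipantData,
    effector: str,
    seed: int | np.random.SeedSequence | np.random.Generator,
    spec: CohortSpec | None = None,
) -> tuple[VolumeGrid, VolumeGrid]:
    """Simulated z-statistic volume and ROI mask for one effector.

    The blob centre is the participant's (already jittered) true peak
    vertex; with ``peak_noise_sd = 0`` and ``noise_sd = 0`` the voxel of
    maximal intensity inside the ROI therefore maps back to the anchor.
    """
    if effector not in EFFECTORS:
        raise ConfigError(f"unknown effector {effector!r}")
    if effector not in participant.peak_true:
        raise ConfigError("participant has no peak information")
    spec = spec or CohortSpec(n_struct=1, n_func=1)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = _strip_grid(participant, spec.voxel_size)
    roi = _roi_volume(participant, effector, grid, spec.dorsal_larynx_z)
    center = participant.mesh.vertices[participant.peak_true[effector]]
    pts = grid.voxel_centers_world()
    sigma = spec.blob_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    d2 = ((pts - center) ** 2).sum(axis=1)
    stat = 8.0 * np.exp(-0.5 * d2 / sigma**2)
    if spec.noise_sd > 0:
        stat = stat + rng.normal(0.0, spec.noise_sd, size=stat.shape)
    return grid.copy_with(stat.reshape(grid.shape).astype(np.float32)), roi


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


def participant_seed(seed: int, participant_id: int, hemisphere: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([seed, participant_id, 0 if hemisphere == "left" else 1])


def activation_seed(seed: int, participant_id: int, hemisphere: str, effector: str) -> np.random.SeedSequence:
    h = 0 if hemisphere == "left" else 1
    return np.random.SeedSequence([seed, participant_id, h, 1000 + EFFECTORS.index(effector)])


def make_cohort(spec: CohortSpec) -> list[ParticipantData]:
    """Full cohort: n_struct participants x both hemispheres, reproducible.

    The first ``n_func`` participants also carry stat/ROI volumes for the
    five effectors when ``spec.attach_volumes`` is set (volumes can always
    be regenerated later with :func:`simulate_activation`).
    """
    template = {h: make_template(h, spec.mesh_subdivisions, spec.radius) for h in ("left", "right")}
    cohort: list[ParticipantData] = []
    for pid in range(spec.n_struct):
        for hemi in ("left", "right"):
            rng = np.random.default_rng(participant_seed(spec.seed, pid, hemi))
            p = sample_participant(template[hemi], spec, hemi, rng, participant_id=pid)
            if pid < spec.n_func and spec.attach_volumes:
                p.stat_volumes, p.roi_volumes = {}, {}
                for eff in EFFECTORS:
                    if eff not in p.peak_true:
                        continue
                    arng = np.random.default_rng(activation_seed(spec.seed, pid, hemi, eff))
                    stat, roi = simulate_activation(p, eff, arng, spec)
                    p.stat_volumes[eff] = stat
                    p.roi_volumes[eff] = roi
            elif pid < spec.n_func:
                p.stat_volumes, p.roi_volumes = {}, {}  # functional, volumes on demand
            cohort.append(p)
    return cohort
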