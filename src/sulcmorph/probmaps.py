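"""Spatial probability maps of sulcal segments, in surface and volume space.

Surface maps: per-vertex percentage of participants whose label covers the
vertex, after nearest-neighbour resampling of every participant's labels
to a common mesh.  Volume maps follow the cohort pipeline: per participant
nearest-vertex projection into a common grid, 3D Gaussian smoothing
(FWHM 2 mm), threshold strictly above 0.1, binarise, then voxelwise sum
across participants.  Both raw counts and per-n fractions are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .mesh import (
    LabelSet,
    TriangleMesh,
    VolumeGrid,
    gaussian_smooth_volume,
    resample_nearest,
    surface_to_volume,
)
from .simulate import ParticipantData

__all__ = [
    "SurfaceProbMap",
    "VolumeProbMap",
    "surface_probability",
    "volume_probability",
    "summarize",
]


@dataclass
class SurfaceProbMap:
    """Per-vertex overlap percentage (0-100) for one segment."""

    values: np.ndarray  # percent
    segment: str
    n_participants: int
    mesh: TriangleMesh


@dataclass
class VolumeProbMap:
    """Per-voxel overlap count (0..n) for one segment."""

    counts: VolumeGrid
    segment: str
    n_participants: int

    def fraction(self) -> VolumeGrid:
        """Per-n normalisation of the counts, in [0, 1]."""
        return self.counts.copy_with(self.counts.data / float(self.n_participants))


def surface_probability(
    label_sets: list[LabelSet],
    segment: str,
    mesh: TriangleMesh,
    source_meshes: list[TriangleMesh] | None = None,
) -> SurfaceProbMap:
    """Binarise, sum and normalise the cohort's labels at each vertex.

    ``source_meshes`` (parallel to ``label_sets``) triggers spherical
    resampling to the common mesh first; omit it when the labels already
    live on ``mesh``.
    """
    if not label_sets:
        raise DataError("empty cohort")
    acc = np.zeros(mesh.n_vertices, dtype=float)
    for i, ls in enumerate(label_sets):
        if source_meshes is not None:
            ls = resample_nearest(source_meshes[i], ls, mesh)
        if len(ls.values) != mesh.n_vertices:
            raise DataError("label set does not match the common mesh (vertex count)")
        acc += ls.mask(segment)
    pct = 100.0 * acc / len(label_sets)
    return SurfaceProbMap(values=pct, segment=segment, n_participants=len(label_sets), mesh=mesh)


def volume_probability(
    participants: list[ParticipantData],
    segment: str,
    grid: VolumeGrid,
    fwhm: float = 2.0,
    threshold: float = 0.1,
) -> VolumeProbMap:
    """Smoothed-thresholded-binarised label volumes, summed per voxel.

    Per participant: nearest-vertex surface-to-volume projection, Gaussian
    smoothing (FWHM ``fwhm`` mm), keep strictly greater than ``threshold``,
    binarise; the cohort map is the voxelwise sum of those binary volumes.
    """
    if not participants:
        raise DataError("empty cohort")
    acc = np.zeros(grid.shape, dtype=np.int32)
    for p in participants:
        vol = surface_to_volume(p.mesh, p.labels, grid, segments=[segment])[segment]
        sm = gaussian_smooth_volume(vol, fwhm)
        acc += (sm.data > threshold).astype(np.int32)
    return VolumeProbMap(counts=grid.copy_with(acc), segment=segment, n_participants=len(participants))


def summarize(prob_map: SurfaceProbMap | VolumeProbMap) -> dict:
    """Maximum, its location, and the intensity-weighted centre of gravity.

    Ties at the maximum resolve to the lowest vertex/linear voxel index.
    The centre of gravity is computed on the unthresholded map.
    """
    if isinstance(prob_map, SurfaceProbMap):
        v = prob_map.values
        if not np.any(v > 0):
            raise DataError("empty probability map")
        imax = int(np.argmax(v))  # argmax returns the first (lowest) index on ties
        w = v / v.sum()
        cog = (prob_map.mesh.vertices * w[:, None]).sum(axis=0)
        return {
            "max_value": float(v[imax]),
            "max_vertex": imax,
            "max_location": prob_map.mesh.vertices[imax].copy(),
            "center_of_gravity": cog,
        }
    data = np.asarray(prob_map.counts.data, dtype=float)
    if not np.any(data > 0):
        raise DataError("empty probability map")
    flat = data.ravel()
    imax = int(np.argmax(flat))
    ijk = np.unravel_index(imax, data.shape)
    centers = prob_map.counts.voxel_centers_world()
    w = flat / flat.sum()
    cog = (centers * w[:, None]).sum(axis=0)
    return {
        "max_value": float(flat[imax]),
        "max_voxel": tuple(int(k) for k in ijk),
        "max_location": prob_map.counts.voxel_to_world(np.array(ijk))[0],
        "center_of_gravity": cog,
    }
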