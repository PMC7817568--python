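"""GIFTI / NIfTI serialisation and cohort directory trees.

Surface geometry travels as ``.surf.gii`` (POINTSET + TRIANGLE arrays,
with the unit-sphere embedding written as a separate sphere surface),
scalar fields as ``.func.gii`` / ``.shape.gii``, labels as ``.label.gii``
with an integer key table naming the eight segments, and volumes as
NIfTI-1 ``.nii.gz`` (affine preserved exactly on round-trip).

A simulated cohort is written as an HCP-like tree::

    <root>/manifest.json
    <root>/sub-XX/hemi-{L,R}/
        midthickness.surf.gii  sphere.surf.gii
        labels.label.gii  depth.shape.gii  thickness.shape.gii
        stat_<effector>.nii.gz  roi_<effector>.nii.gz   (functional only)

with true generator parameters (morphotype, anchors, peaks) recorded in
the manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
from nibabel import gifti

from .errors import DataError
from .mesh import (
    BACKGROUND,
    LABEL_NAMES,
    LabelSet,
    ScalarField,
    TriangleMesh,
    VolumeGrid,
)
from .simulate import ParticipantData

def _ensure_parent(path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)


__all__ = [
    "save_surface_gifti",
    "load_surface_gifti",
    "save_scalar_gifti",
    "load_scalar_gifti",
    "save_label_gifti",
    "load_label_gifti",
    "save_volume",
    "load_volume",
    "write_cohort",
    "load_cohort",
]

_SPHERE_RADIUS = 100.0  # written sphere surfaces use a 100 mm radius convention

_STRUCTURE = {"left": "CortexLeft", "right": "CortexRight"}


def save_surface_gifti(path, mesh: TriangleMesh, hemisphere: str = "left", sphere: bool = False) -> None:
    """Write geometry (or the unit-sphere embedding scaled to 100 mm)."""
    if sphere:
        if mesh.sphere_coords is None:
            raise DataError("mesh has no sphere_coords")
        pts = (_SPHERE_RADIUS * mesh.sphere_coords).astype(np.float32)
    else:
        pts = mesh.vertices.astype(np.float32)
    g = gifti.GiftiImage()
    meta = {"AnatomicalStructurePrimary": _STRUCTURE[hemisphere]}
    g.add_gifti_data_array(
        gifti.GiftiDataArray(pts, intent="NIFTI_INTENT_POINTSET", datatype="NIFTI_TYPE_FLOAT32",
                             meta=meta)
    )
    g.add_gifti_data_array(
        gifti.GiftiDataArray(mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE",
                             datatype="NIFTI_TYPE_INT32")
    )
    _ensure_parent(path)
    nib.save(g, str(path))


def load_surface_gifti(path, sphere_path=None) -> TriangleMesh:
    from nibabel.nifti1 import intent_codes

    g = nib.load(str(path))
    pts = faces = None
    for arr in g.darrays:
        if arr.intent == intent_codes.code["NIFTI_INTENT_POINTSET"]:
            pts = np.asarray(arr.data, dtype=float)
        elif arr.intent == intent_codes.code["NIFTI_INTENT_TRIANGLE"]:
            faces = np.asarray(arr.data, dtype=np.int64)
    if pts is None or faces is None:
        raise DataError(f"{path} is not a surface GIFTI")
    sph = None
    if sphere_path is not None:
        s = load_surface_gifti(sphere_path)
        sph = s.vertices / np.linalg.norm(s.vertices, axis=1, keepdims=True)
    return TriangleMesh(vertices=pts, faces=faces, sphere_coords=sph)


def save_scalar_gifti(path, field: ScalarField, hemisphere: str = "left") -> None:
    g = gifti.GiftiImage()
    g.add_gifti_data_array(
        gifti.GiftiDataArray(field.values.astype(np.float32), intent="NIFTI_INTENT_NONE",
                             datatype="NIFTI_TYPE_FLOAT32",
                             meta={"AnatomicalStructurePrimary": _STRUCTURE[hemisphere],
                                   "Name": field.meaning})
    )
    _ensure_parent(path)
    nib.save(g, str(path))


def load_scalar_gifti(path) -> ScalarField:
    g = nib.load(str(path))
    arr = g.darrays[0]
    meaning = dict(arr.meta).get("Name", "statistic")
    return ScalarField(values=np.asarray(arr.data, dtype=float), meaning=meaning)


def save_label_gifti(path, labels: LabelSet) -> None:
    g = gifti.GiftiImage()
    table = gifti.GiftiLabelTable()
    rng = np.random.default_rng(12345)  # fixed palette
    for key in sorted(LABEL_NAMES):
        r, g_, b = rng.random(3).tolist()
        lab = gifti.GiftiLabel(key=key, red=r, green=g_, blue=b,
                               alpha=0.0 if key == BACKGROUND else 1.0)
        lab.label = LABEL_NAMES[key]
        table.labels.append(lab)
    g.labeltable = table
    g.add_gifti_data_array(
        gifti.GiftiDataArray(labels.values.astype(np.int32), intent="NIFTI_INTENT_LABEL",
                             datatype="NIFTI_TYPE_INT32",
                             meta={"AnatomicalStructurePrimary": _STRUCTURE[labels.hemisphere]})
    )
    _ensure_parent(path)
    nib.save(g, str(path))


def load_label_gifti(path) -> LabelSet:
    g = nib.load(str(path))
    arr = g.darrays[0]
    meta = dict(arr.meta)
    hemi = "right" if meta.get("AnatomicalStructurePrimary") == "CortexRight" else "left"
    return LabelSet(values=np.asarray(arr.data, dtype=np.int32), hemisphere=hemi)


def save_volume(path, vol: VolumeGrid) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data), vol.affine)
    img.set_sform(vol.affine, code=1)
    img.set_qform(vol.affine, code=1)
    _ensure_parent(path)
    nib.save(img, str(path))


def load_volume(path) -> VolumeGrid:
    img = nib.load(str(path))
    affine = img.get_sform() if img.get_sform(coded=True)[1] else img.affine
    return VolumeGrid(data=np.asarray(img.dataobj), affine=affine)


# ---------------------------------------------------------------------------
# cohort trees
# ---------------------------------------------------------------------------

_HEMI_DIR = {"left": "hemi-L", "right": "hemi-R"}
_HEMI_FROM_DIR = {v: k for k, v in _HEMI_DIR.items()}


def write_cohort(cohort: list[ParticipantData], root, with_volumes: bool = True) -> None:
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    manifest = {"participants": []}
    for p in cohort:
        sub = root / f"sub-{p.participant_id:02d}" / _HEMI_DIR[p.hemisphere]
        sub.mkdir(parents=True, exist_ok=True)
        save_surface_gifti(sub / "midthickness.surf.gii", p.mesh, p.hemisphere)
        save_surface_gifti(sub / "sphere.surf.gii", p.mesh, p.hemisphere, sphere=True)
        save_label_gifti(sub / "labels.label.gii", p.labels)
        save_scalar_gifti(sub / "depth.shape.gii", p.depth, p.hemisphere)
        save_scalar_gifti(sub / "thickness.shape.gii", p.thickness, p.hemisphere)
        entry = {
            "participant_id": p.participant_id,
            "hemisphere": p.hemisphere,
            "morphotype_true": p.morphotype_true,
            "anchors": p.anchors,
            "peak_true": p.peak_true,
            "anchor_segment": p.anchor_segment,
            "functional": bool(p.is_functional),
            "path": str(sub.relative_to(root)),
        }
        if with_volumes and p.stat_volumes:
            for eff, vol in p.stat_volumes.items():
                save_volume(sub / f"stat_{eff}.nii.gz", vol)
                save_volume(sub / f"roi_{eff}.nii.gz", p.roi_volumes[eff])
            entry["effectors"] = sorted(p.stat_volumes)
        manifest["participants"].append(entry)
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def load_cohort(root) -> list[ParticipantData]:
    root = Path(root)
    manifest = json.loads((root / "manifest.json").read_text())
    out: list[ParticipantData] = []
    for entry in manifest["participants"]:
        sub = root / entry["path"]
        mesh = load_surface_gifti(sub / "midthickness.surf.gii", sub / "sphere.surf.gii")
        p = ParticipantData(
            participant_id=int(entry["participant_id"]),
            hemisphere=entry["hemisphere"],
            mesh=mesh,
            labels=load_label_gifti(sub / "labels.label.gii"),
            depth=load_scalar_gifti(sub / "depth.shape.gii"),
            thickness=load_scalar_gifti(sub / "thickness.shape.gii"),
            morphotype_true=int(entry["morphotype_true"]),
            anchors={k: int(v) for k, v in entry["anchors"].items()},
            peak_true={k: int(v) for k, v in entry["peak_true"].items()},
            anchor_segment=dict(entry["anchor_segment"]),
        )
        if entry.get("functional"):
            p.stat_volumes, p.roi_volumes = {}, {}
            for eff in entry.get("effectors", []):
                p.stat_volumes[eff] = load_volume(sub / f"stat_{eff}.nii.gz")
                p.roi_volumes[eff] = load_volume(sub / f"roi_{eff}.nii.gz")
        out.append(p)
    return out
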