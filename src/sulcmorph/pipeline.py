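"""End-to-end orchestration of the synthetic study.

``run_full_study`` chains every stage: cohort simulation, surface and
volume probability maps with their summaries, per-segment morphometry,
morphotype classification with frequency/asymmetry tables, group
reference construction, label- and depth-driven registration, peak
extraction and the spread comparison across registration methods.  Every
table is written as TSV, maps as GIFTI/NIfTI, plus a JSON manifest with
the seed, a config hash and stage timings.  All stages are plain
functions so they can be called individually (the CLI maps one
subcommand to each).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .errors import ConfigError
from .mesh import SEGMENTS, ScalarField, VolumeGrid
from .morphometry import (
    classify_morphotype,
    cohort_metrics_table,
    hemispheric_shares,
    type_frequency_table,
)
from .peaks import assign_label, assignment_table, compare_registrations, extract_peak
from .probmaps import summarize, surface_probability, volume_probability
from .registration import RegistrationConfig, build_depth_reference, build_reference
from .simulate import EFFECTORS, CohortSpec, ParticipantData, make_cohort, make_template

__all__ = ["PipelineConfig", "run_full_study"]

log = logging.getLogger("sulcmorph")


@dataclass
class PipelineConfig:
    """Every numeric constant of the pipeline in one place."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    grid_resolution: float = 2.0  # probability-map voxel size, mm
    volume_fwhm: float = 2.0  # label smoothing before thresholding, mm
    peak_patch_fwhm: float = 1.0  # surface peak patch smoothing, mm
    reference_threshold: float = 0.4
    volume_label_threshold: float = 0.1
    assign_radius: float = 3.0  # peak-to-label search radius, mm
    z_threshold: float = 3.1
    registration: RegistrationConfig = field(default_factory=RegistrationConfig.fast)
    out_dir: str = "sulcmorph_out"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("reference_threshold", "volume_label_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must be in (0, 1)")
        for name in ("grid_resolution", "volume_fwhm", "peak_patch_fwhm", "assign_radius"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        self.cohort.seed = self.seed

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        cohort = CohortSpec(**raw.pop("cohort", {}))
        reg = RegistrationConfig(**raw.pop("registration", {})) if "registration" in raw else RegistrationConfig.fast()
        return cls(cohort=cohort, registration=reg, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["type_probs"] = {k: list(map(float, v)) for k, v in self.cohort.type_probs.items()}
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True, default=str).encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=True)


def _probmap_grid(cfg: PipelineConfig) -> VolumeGrid:
    tpl = make_template("left", cfg.cohort.mesh_subdivisions, cfg.cohort.radius)
    labelled = tpl.labels.values != 0
    pts = tpl.mesh.vertices[labelled]
    lo = pts.min(axis=0) - 12.0
    hi = pts.max(axis=0) + 12.0
    shape = np.maximum(np.ceil((hi - lo) / cfg.grid_resolution).astype(int) + 1, 2)
    affine = np.eye(4)
    affine[:3, :3] *= cfg.grid_resolution
    affine[:3, 3] = lo
    affine = affine.astype(np.float32).astype(float)
    return VolumeGrid(data=np.zeros(tuple(shape), dtype=np.float32), affine=affine)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: PipelineConfig) -> list[ParticipantData]:
    return make_cohort(cfg.cohort)


def stage_probmaps(cfg: PipelineConfig, cohort: list[ParticipantData], out: Path) -> pd.DataFrame:
    """Surface + volume probability maps and the coordinate summary table."""
    grid = _probmap_grid(cfg)
    rows = []
    for hemi in ("left", "right"):
        parts = [p for p in cohort if p.hemisphere == hemi]
        if not parts:
            continue
        mesh = parts[0].mesh
        for seg in SEGMENTS:
            sp = surface_probability([p.labels for p in parts], seg, mesh)
            vp = volume_probability(parts, seg, grid, fwhm=cfg.volume_fwhm,
                                    threshold=cfg.volume_label_threshold)
            _io.save_scalar_gifti(out / "probmaps" / f"surface_{hemi}_{seg}.func.gii",
                                  ScalarField(values=sp.values, meaning="probability"), hemi)
            _io.save_volume(out / "probmaps" / f"volume_{hemi}_{seg}.nii.gz", vp.counts)
            ssum = summarize(sp)
            vsum = summarize(vp) if np.any(vp.counts.data > 0) else None
            row = dict(segment=seg, hemisphere=hemi, surface_max_pct=ssum["max_value"])
            if vsum is not None:
                row.update(
                    max_value=vsum["max_value"],
                    max_x=vsum["max_location"][0], max_y=vsum["max_location"][1], max_z=vsum["max_location"][2],
                    cog_x=vsum["center_of_gravity"][0], cog_y=vsum["center_of_gravity"][1],
                    cog_z=vsum["center_of_gravity"][2],
                )
            rows.append(row)
    df = pd.DataFrame(rows)
    _write_tsv(df, out / "probmap_summary.tsv")
    return df


def stage_metrics(cfg: PipelineConfig, cohort: list[ParticipantData], out: Path) -> pd.DataFrame:
    df = cohort_metrics_table(cohort)
    _write_tsv(df, out / "segment_metrics.tsv")
    return df


def stage_classify(cfg: PipelineConfig, cohort: list[ParticipantData], out: Path) -> pd.DataFrame:
    calls = []
    evid = []
    for p in cohort:
        c = classify_morphotype(p.labels, p.mesh, p.depth)
        calls.append((p.hemisphere, c.type))
        evid.append(dict(participant=p.participant_id, hemisphere=p.hemisphere,
                         morphotype=c.type, morphotype_true=p.morphotype_true,
                         evidence=json.dumps(c.evidence, default=str)))
    freq = type_frequency_table(calls)
    _write_tsv(freq, out / "type_frequency.tsv")
    _write_tsv(pd.DataFrame(evid), out / "classification_evidence.tsv")
    shares = []
    for t in range(1, 6):
        try:
            lh, rh = hemispheric_shares(freq, t)
            shares.append(dict(morphotype=t, lh_share_pct=lh, rh_share_pct=rh))
        except Exception:
            pass
    _write_tsv(pd.DataFrame(shares), out / "hemispheric_shares.tsv")
    return freq


def stage_reference(cfg: PipelineConfig, cohort: list[ParticipantData], out: Path) -> dict:
    refs = {}
    for hemi in ("left", "right"):
        parts = [p for p in cohort if p.hemisphere == hemi]
        if not parts:
            continue
        mesh = parts[0].mesh
        ref = build_reference([p.labels for p in parts], mesh, cfg.reference_threshold)
        dref = build_depth_reference([p.depth for p in parts], mesh)
        refs[hemi] = (ref, dref)
        for j, seg in enumerate(ref.channel_names):
            _io.save_scalar_gifti(
                out / "reference" / f"reference_{hemi}_{seg}.func.gii",
                ScalarField(values=100.0 * ref.channels[:, j], meaning="probability"), hemi)
    return refs


def stage_peaks(cfg: PipelineConfig, cohort: list[ParticipantData], out: Path) -> pd.DataFrame:
    rows = []
    for p in cohort:
        if not p.is_functional:
            continue
        for eff in EFFECTORS:
            if p.stat_volumes and eff in p.stat_volumes:
                pk = extract_peak(p.stat_volumes[eff], p.roi_volumes[eff], p.mesh,
                                  eff, p.hemisphere, cfg.z_threshold)
                vertex, voxel, value, supra = pk.vertex, pk.voxel, pk.value, pk.suprathreshold
            elif eff in p.peak_true:
                vertex, voxel, value, supra = p.peak_true[eff], None, np.nan, True
            else:
                continue
            seg = assign_label(vertex, p.labels, p.mesh, cfg.assign_radius)
            rows.append(dict(participant=p.participant_id, hemisphere=p.hemisphere,
                             effector=eff, voxel=json.dumps(voxel), vertex=vertex,
                             label=seg, value=value, suprathreshold=bool(supra)))
    df = pd.DataFrame(rows)
    _write_tsv(df, out / "peaks.tsv")
    if len(df):
        tab = assignment_table([(r.hemisphere, r.effector, r.label) for r in df.itertuples()])
        _write_tsv(tab, out / "peak_label_counts.tsv")
    return df


def stage_spread(cfg: PipelineConfig, cohort: list[ParticipantData],
                 refs: dict, out: Path) -> pd.DataFrame:
    frames = []
    for hemi, (ref, dref) in refs.items():
        df = compare_registrations(cohort, ref, depth_reference=dref, config=cfg.registration,
                                   hemispheres=(hemi,), z_threshold=cfg.z_threshold)
        frames.append(df)
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    _write_tsv(df, out / "spread.tsv")
    return df


def run_full_study(cfg: PipelineConfig) -> dict:
    """Run every stage, write all outputs, return the tables."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    timings = {}

    def timed(name, fn, *args):
        t0 = time.time()
        log.info("stage %s ...", name)
        try:
            r = fn(*args)
        except Exception as exc:  # halt with stage-tagged error, keep partials
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        timings[name] = round(time.time() - t0, 3)
        log.info("stage %s done in %.1fs", name, timings[name])
        return r

    cohort = timed("simulate", stage_simulate, cfg)
    results["probmaps"] = timed("probmap", stage_probmaps, cfg, cohort, out)
    results["metrics"] = timed("metrics", stage_metrics, cfg, cohort, out)
    results["types"] = timed("classify", stage_classify, cfg, cohort, out)
    refs = timed("reference", stage_reference, cfg, cohort, out)
    has_func = any(p.is_functional for p in cohort)
    if has_func:
        results["peaks"] = timed("peaks", stage_peaks, cfg, cohort, out)
        results["spread"] = timed("spread", stage_spread, cfg, cohort, refs, out)
    else:
        log.info("no functional participants: peaks/spread stages skipped")
    import sulcmorph

    manifest = dict(
        package_version=getattr(sulcmorph, "__version__", "unknown"),
        numpy_version=np.__version__,
        seed=cfg.seed,
        config=cfg.to_dict(),
        config_hash=cfg.config_hash(),
        timings=timings,
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    results["manifest"] = manifest
    return results
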