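"""Per-segment anatomical descriptors and morphotype classification.

Descriptors per sulcal segment: the minimum of the (normalised, signed)
sulcal depth field over the label, the mean cortical thickness in the
label, and the label's vertex count as a sulcal-area proxy.

The subcentral region is classified into five morphotypes from the
configuration of ``ascs_lat``.  Two segments count as *merged* when a
vertex of one is edge-adjacent to a vertex of the other and both
endpoints lie below a depth threshold (continuation through the sulcal
bed, not across a gyral crown; threshold 0 by default since depth is
negative in sulci).  Precedence when several predicates fire:
Type 2 (merge with any central-sulcus segment) > Type 3 (merge with
ascs_op, or the rarer posterior variant merging with pscs, flagged in the
evidence) > Type 4 (merge with the iprs proxy band) > Type 5 (ascs_lat
centroid anterior to the ascs_op centroid) > Type 1 (default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .mesh import LABEL_NAMES, SEGMENTS, LabelSet, ScalarField, TriangleMesh, _segment_id
from .simulate import ParticipantData

__all__ = [
    "SegmentMetrics",
    "MorphotypeCall",
    "segment_metrics",
    "cohort_metrics_table",
    "merge_relations",
    "classify_morphotype",
    "type_frequency_table",
    "hemispheric_shares",
]

#: Anterior direction of the template frame (+y); used for the Type 5
#: positional predicate.
ANTERIOR_AXIS = np.array([0.0, 1.0, 0.0])


@dataclass
class SegmentMetrics:
    segment: str
    hemisphere: str
    min_depth: float
    mean_thickness: float
    vertex_count: int


@dataclass
class MorphotypeCall:
    type: int
    evidence: dict = field(default_factory=dict)


def segment_metrics(participant: ParticipantData, segment: str) -> SegmentMetrics:
    """Min depth / mean thickness / vertex count of one segment label."""
    m = participant.labels.mask(segment)
    if not m.any():
        raise DataError(f"segment {segment!r} has no vertices (missing label)")
    return SegmentMetrics(
        segment=segment,
        hemisphere=participant.labels.hemisphere,
        min_depth=float(participant.depth.values[m].min()),
        mean_thickness=float(participant.thickness.values[m].mean()),
        vertex_count=int(m.sum()),
    )


def cohort_metrics_table(cohort: list[ParticipantData]) -> pd.DataFrame:
    """Long-format per-participant, per-segment descriptor table."""
    rows = []
    for p in cohort:
        for seg in SEGMENTS:
            if not p.labels.mask(seg).any():
                continue
            sm = segment_metrics(p, seg)
            rows.append(
                dict(participant=p.participant_id, hemisphere=sm.hemisphere, segment=seg,
                     min_depth=sm.min_depth, mean_thickness=sm.mean_thickness,
                     vertex_count=sm.vertex_count)
            )
    return pd.DataFrame(rows)


def merge_relations(
    labels: LabelSet,
    mesh: TriangleMesh,
    depth: ScalarField,
    depth_threshold: float = 0.0,
) -> set[tuple[str, str]]:
    """Pairs of labels joined through the sulcal bed.

    A pair (A, B) is merged iff some edge of the mesh connects a vertex of
    A to a vertex of B and both endpoints have depth below
    ``depth_threshold``.  Pair names are sorted; the iprs proxy band is
    reported as ``"iprs"``.
    """
    e = mesh.edges_unique()
    la, lb = labels.values[e[:, 0]], labels.values[e[:, 1]]
    deep = (depth.values[e[:, 0]] < depth_threshold) & (depth.values[e[:, 1]] < depth_threshold)
    cross = (la != lb) & (la != 0) & (lb != 0) & deep
    pairs = set()
    for i, j in zip(la[cross], lb[cross]):
        pairs.add(tuple(sorted((LABEL_NAMES[int(i)], LABEL_NAMES[int(j)]))))
    return pairs


def classify_morphotype(
    labels: LabelSet,
    mesh: TriangleMesh,
    depth: ScalarField,
    depth_threshold: float = 0.0,
) -> MorphotypeCall:
    """Five-type classification of the subcentral region from ascs_lat."""
    if not labels.mask("ascs_lat").any():
        raise DataError("ascs_lat label is empty: hemisphere cannot be classified")
    merges = merge_relations(labels, mesh, depth, depth_threshold)
    with_ascs = {frozenset(p) for p in merges if "ascs_lat" in p}

    def merged_with(other: str) -> bool:
        return frozenset(("ascs_lat", other)) in with_ascs

    evidence: dict = {"merges": sorted(tuple(sorted(p)) for p in with_ascs)}
    cs_merge = any(merged_with(f"cs_{k}") for k in range(1, 6))
    if cs_merge:
        return MorphotypeCall(2, evidence)
    if merged_with("ascs_op"):
        return MorphotypeCall(3, evidence)
    if merged_with("pscs"):
        # posterior variant: merged with pscs rather than ascs_op; kept in the
        # Type 3 slot but flagged
        evidence["pscs_variant"] = True
        return MorphotypeCall(3, evidence)
    if merged_with("iprs"):
        return MorphotypeCall(4, evidence)
    # positional predicate along the anterior axis
    def centroid_y(seg: str | int) -> float:
        m = labels.values == _segment_id(seg)
        if not m.any():
            return np.nan
        c = mesh.sphere_coords[m].mean(axis=0)
        c /= np.linalg.norm(c)
        return float(c @ ANTERIOR_AXIS)

    y_lat, y_op = centroid_y("ascs_lat"), centroid_y("ascs_op")
    evidence["anterior_coords"] = (y_lat, y_op)
    if np.isfinite(y_op) and y_lat > y_op:
        return MorphotypeCall(5, evidence)
    return MorphotypeCall(1, evidence)


def type_frequency_table(cohort_or_calls) -> pd.DataFrame:
    """Contingency table of morphotype calls: hemispheres x types 1-5 + totals.

    Accepts a list of ParticipantData (classified on the fly) or of
    (hemisphere, type) pairs.
    """
    counts = pd.DataFrame(0, index=pd.Index(["left", "right"], name="hemisphere"),
                          columns=pd.Index([1, 2, 3, 4, 5], name="morphotype"))
    for item in cohort_or_calls:
        if isinstance(item, ParticipantData):
            call = classify_morphotype(item.labels, item.mesh, item.depth)
            hemi, t = item.hemisphere, call.type
        else:
            hemi, t = item
        counts.loc[hemi, t] += 1
    counts.loc["total"] = counts.sum(axis=0)
    return counts


def hemispheric_shares(table: pd.DataFrame, morphotype: int) -> tuple[float, float]:
    """(LH share %, RH share %) of one morphotype's occurrences."""
    lh = float(table.loc["left", morphotype])
    rh = float(table.loc["right", morphotype])
    tot = lh + rh
    if tot == 0:
        raise DataError(f"morphotype {morphotype} has zero occurrences: share undefined")
    return 100.0 * lh / tot, 100.0 * rh / tot
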