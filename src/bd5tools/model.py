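"""In-memory document model for BD5 quantitative biological dynamics data.

A :class:`BD5Document` holds everything one BD5 file stores: a
:class:`ScaleUnit` declaring dimensionality and physical scales, definition
tables for biological objects and features, a time-ordered list of
:class:`TimeGroup` containers with the spatial and feature records of each
time point, and a list of :class:`TrackEdge` links expressing continuation,
division and fusion of objects between time points.

Coordinates and times are stored in *scaled* units: multiplying a stored
value by the matching scale factor of the ScaleUnit yields the physical
quantity (see :func:`resolve_physical`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import DimensionMismatchError

__all__ = [
    "DIMENSIONS",
    "ENTITY_KINDS",
    "ScaleUnit",
    "ObjectDef",
    "FeatureDef",
    "SpatialRecord",
    "FeatureRecord",
    "TrackEdge",
    "TimeGroup",
    "BD5Document",
    "Violation",
    "PhysicalPoint",
    "assign_time_groups",
    "validate_document",
    "resolve_physical",
]

#: Legal values of ``scaleUnit.dimension``.
DIMENSIONS = ("0D", "1D", "2D", "3D", "0D+T", "1D+T", "2D+T", "3D+T")

#: The five geometric entity kinds a numbered object dataset may hold.
ENTITY_KINDS = ("point", "circle", "line", "sphere", "face")


@dataclass(frozen=True)
class ScaleUnit:
    """Dimensionality, spatial/temporal scale factors and unit names.

    ``x_scale``/``y_scale``/``z_scale`` give physical length per stored
    coordinate unit; ``t_scale`` gives physical time per stored t unit.
    ``z_scale`` must be present exactly for "3D" dimensions, ``t_scale`` and
    ``t_unit`` exactly for "+T" dimensions.
    """

    dimension: str
    x_scale: float | None = None
    y_scale: float | None = None
    z_scale: float | None = None
    s_unit: str | None = None
    t_scale: float | None = None
    t_unit: str | None = None

    def __post_init__(self):
        if self.dimension not in DIMENSIONS:
            raise ValueError(f"unknown dimension {self.dimension!r}; expected one of {DIMENSIONS}")
        if self.has_z != (self.z_scale is not None):
            raise ValueError(f"z_scale must be present iff dimension is 3D (got {self.dimension})")
        if self.has_t != (self.t_scale is not None) or self.has_t != (self.t_unit is not None):
            raise ValueError(f"t_scale/t_unit must be present iff dimension ends in +T (got {self.dimension})")
        for name in ("x_scale", "y_scale", "z_scale", "t_scale"):
            v = getattr(self, name)
            if v is not None and not (v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v}")

    @property
    def has_z(self) -> bool:
        return self.dimension.startswith("3D")

    @property
    def has_t(self) -> bool:
        return self.dimension.endswith("+T")


@dataclass(frozen=True)
class ObjectDef:
    """Definition of one biological object class.

    ``oID`` is the reference number naming the numbered datasets under the
    per-time-point ``object``/``feature`` groups; ``entity`` is the geometric
    kind those datasets hold (one of :data:`ENTITY_KINDS`).
    """

    oID: int
    name: str
    entity: str = "point"

    def __post_init__(self):
        if self.oID < 0:
            raise ValueError(f"oID must be non-negative, got {self.oID}")
        if self.entity not in ENTITY_KINDS:
            raise ValueError(f"unknown entity kind {self.entity!r}; expected one of {ENTITY_KINDS}")


@dataclass(frozen=True)
class FeatureDef:
    """Definition of one feature of interest (e.g. "total GFP signal")."""

    fID: int
    name: str

    def __post_init__(self):
        if self.fID < 0:
            raise ValueError(f"fID must be non-negative, got {self.fID}")


@dataclass(frozen=True)
class SpatialRecord:
    """One row of a numbered object dataset.

    ``ID`` identifies the biological object instance; within one dataset at
    one time point, rows sharing an ID and carrying distinct sequential
    indices ``sID`` form one line/face entity, while point/circle/sphere
    entities occupy exactly one row (``sID`` unset).  ``z`` is set only for
    3D data, ``radius`` only for circle/sphere rows.
    """

    ID: str
    t: float
    x: float
    y: float
    sID: int | None = None
    z: float | None = None
    radius: float | None = None
    label: str | None = None


@dataclass(frozen=True)
class FeatureRecord:
    """One row of a numbered feature dataset: a feature value of one object.

    An object need not carry rows for every fID defined in featureDef —
    features are sparse.
    """

    ID: str
    fID: int
    value: float


@dataclass(frozen=True)
class TrackEdge:
    """A directed tracking link from an object at an earlier time to one at
    a later time (stored as the from/to columns of trackInfo)."""

    src: str
    dst: str


@dataclass
class TimeGroup:
    """All spatial and feature records of one time point.

    ``index`` is the numbered-group name; ``t`` the stored time value shared
    by every record in the group; ``objects``/``features`` map oID reference
    numbers to record lists (the numbered datasets).
    """

    index: int
    t: float
    objects: dict[int, list[SpatialRecord]] = field(default_factory=dict)
    features: dict[int, list[FeatureRecord]] = field(default_factory=dict)


@dataclass
class BD5Document:
    """A full in-memory BD5 dataset."""

    scale_unit: ScaleUnit
    object_defs: list[ObjectDef] = field(default_factory=list)
    feature_defs: list[FeatureDef] = field(default_factory=list)
    time_groups: list[TimeGroup] = field(default_factory=list)
    track_info: list[TrackEdge] = field(default_factory=list)

    def object_def(self, oID: int) -> ObjectDef:
        for d in self.object_defs:
            if d.oID == oID:
                return d
        raise KeyError(f"oID {oID} not in objectDef")

    def occurrences(self, ID: str) -> list[int]:
        """Ascending time-group indices in which ``ID`` has a spatial record."""
        out = []
        for g in self.time_groups:
            if any(r.ID == ID for recs in g.objects.values() for r in recs):
                out.append(g.index)
        return out


@dataclass(frozen=True)
class Violation:
    """One broken document invariant, as data rather than an exception."""

    rule: str
    subject: str
    key: str
    message: str

    def __str__(self):
        return f"[{self.rule}] {self.subject} {self.key}: {self.message}"


@dataclass(frozen=True)
class PhysicalPoint:
    """Physical-unit coordinates and time of one record."""

    x: float
    y: float
    z: float | None
    t: float | None
    s_unit: str | None
    t_unit: str | None


def assign_time_groups(
    records: Iterable[SpatialRecord],
    oids: int | Sequence[int] = 0,
) -> list[TimeGroup]:
    """Bucket records into numbered time groups by ascending distinct t.

    Group indices run 0..n-1 over the distinct stored t values, so a
    time-ordered sequence is preserved even for irregular intervals (times
    {0, 2, 7} yield groups 0, 1, 2 holding t=0, 2 and 7).

    Parameters
    ----------
    records:
        Spatial records with arbitrary finite t values.
    oids:
        Either one oID applied to every record, or a sequence parallel to
        ``records`` giving the numbered dataset each record belongs to.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to assign")
    if isinstance(oids, int):
        oid_list = [oids] * len(records)
    else:
        oid_list = list(oids)
        if len(oid_list) != len(records):
            raise ValueError(f"{len(records)} records but {len(oid_list)} oIDs")
    for r in records:
        if not math.isfinite(r.t):
            raise ValueError(f"non-finite t in record ID={r.ID!r} (t={r.t})")
    times = sorted({r.t for r in records})
    index_of = {t: k for k, t in enumerate(times)}
    groups = [TimeGroup(index=k, t=t) for k, t in enumerate(times)]
    for r, oid in zip(records, oid_list):
        groups[index_of[r.t]].objects.setdefault(oid, []).append(r)
    return groups


def _check_entity_rows(su, oid, kind, recs, gidx, out):
    """Per-dataset invariants: ID/sID discipline, radius and z presence."""
    where = f"group {gidx}, object {oid}"
    by_id: dict[str, list[SpatialRecord]] = {}
    for r in recs:
        by_id.setdefault(r.ID, []).append(r)
    sequenced = kind in ("line", "face")
    minimum = {"line": 2, "face": 3}.get(kind, 1)
    for ID, rows in by_id.items():
        if not sequenced:
            if len(rows) > 1:
                out.append(Violation("duplicate-id", "SpatialRecord", ID,
                                     f"{kind} ID {ID!r} appears {len(rows)} times in {where}"))
            if any(r.sID is not None for r in rows):
                out.append(Violation("sid-presence", "SpatialRecord", ID,
                                     f"{kind} record {ID!r} carries an sID in {where}"))
        else:
            sids = sorted(r.sID for r in rows if r.sID is not None)
            if len(sids) != len(rows) or sids != list(range(len(rows))):
                out.append(Violation("sid-run", "SpatialRecord", ID,
                                     f"sIDs of {ID!r} in {where} are not the contiguous run 0..k-1"))
            elif len(rows) < minimum:
                out.append(Violation("entity-arity", "SpatialRecord", ID,
                                     f"{kind} {ID!r} has {len(rows)} vertices (< {minimum}) in {where}"))
        needs_radius = kind in ("circle", "sphere")
        for r in rows:
            if needs_radius and (r.radius is None or not (r.radius > 0)):
                out.append(Violation("radius", "SpatialRecord", ID,
                                     f"{kind} {ID!r} lacks a positive radius in {where}"))
            if not needs_radius and r.radius is not None:
                out.append(Violation("radius", "SpatialRecord", ID,
                                     f"{kind} {ID!r} carries a radius in {where}"))
            if su.has_z != (r.z is not None):
                out.append(Violation("dimension", "SpatialRecord", ID,
                                     f"record {ID!r} in {where} has z={'set' if r.z is not None else 'unset'} "
                                     f"but dimension is {su.dimension}"))


def validate_document(doc: BD5Document) -> list[Violation]:
    """Check every document invariant; return violations as data.

    An empty list means the document is valid.  Each violation names the
    offending type, key (oID/fID/ID/group index) and broken rule.
    """
    out: list[Violation] = []
    su = doc.scale_unit

    oids = [d.oID for d in doc.object_defs]
    if len(set(oids)) != len(oids):
        dup = sorted({o for o in oids if oids.count(o) > 1})
        out.append(Violation("unique-oid", "ObjectDef", str(dup), f"duplicate oIDs {dup} in objectDef"))
    fids = [d.fID for d in doc.feature_defs]
    if len(set(fids)) != len(fids):
        dup = sorted({f for f in fids if fids.count(f) > 1})
        out.append(Violation("unique-fid", "FeatureDef", str(dup), f"duplicate fIDs {dup} in featureDef"))
    kind_of = {d.oID: d.entity for d in doc.object_defs}

    prev_t = None
    for pos, g in enumerate(doc.time_groups):
        if g.index != pos:
            out.append(Violation("group-index", "TimeGroup", str(g.index),
                                 f"group at position {pos} has index {g.index}; indices must run 0..n-1"))
        if prev_t is not None and not (g.t > prev_t):
            out.append(Violation("time-order", "TimeGroup", str(g.index),
                                 f"group {g.index} t={g.t} is not greater than previous t={prev_t}"))
        prev_t = g.t
        if not any(g.objects.values()):
            out.append(Violation("empty-group", "TimeGroup", str(g.index),
                                 f"group {g.index} holds no spatial records"))
        for oid, recs in g.objects.items():
            if oid not in kind_of:
                out.append(Violation("unknown-oid", "TimeGroup", str(oid),
                                     f"group {g.index} uses oID {oid} absent from objectDef"))
                continue
            for r in recs:
                if r.t != g.t:
                    out.append(Violation("group-time", "SpatialRecord", r.ID,
                                         f"record {r.ID!r} has t={r.t} but group {g.index} has t={g.t}"))
            _check_entity_rows(su, oid, kind_of[oid], recs, g.index, out)
        for oid, frecs in g.features.items():
            if oid not in kind_of:
                out.append(Violation("unknown-oid", "TimeGroup", str(oid),
                                     f"group {g.index} has features for oID {oid} absent from objectDef"))
                continue
            present = {r.ID for r in g.objects.get(oid, [])}
            for fr in frecs:
                if fr.fID not in fids:
                    out.append(Violation("unknown-fid", "FeatureRecord", str(fr.fID),
                                         f"feature row for {fr.ID!r} in group {g.index} uses fID {fr.fID} "
                                         f"absent from featureDef"))
                if fr.ID not in present:
                    out.append(Violation("feature-ref", "FeatureRecord", fr.ID,
                                         f"feature row names ID {fr.ID!r} with no spatial record in "
                                         f"group {g.index}, object {oid}"))

    t_of_group = {g.index: g.t for g in doc.time_groups}
    occurrences: dict[str, list[int]] = {}
    for g in doc.time_groups:
        for recs in g.objects.values():
            for r in recs:
                at = occurrences.setdefault(r.ID, [])
                if not at or at[-1] != g.index:
                    at.append(g.index)
    for e in doc.track_info:
        src_at = occurrences.get(e.src, [])
        dst_at = occurrences.get(e.dst, [])
        if not src_at or not dst_at:
            missing = e.src if not src_at else e.dst
            out.append(Violation("dangling-edge", "TrackEdge", missing,
                                 f"edge {e.src!r}->{e.dst!r} endpoint {missing!r} has no spatial record"))
            continue
        t_src = t_of_group[src_at[-1]]
        t_dst = t_of_group[dst_at[0]]
        if not (t_src < t_dst):
            out.append(Violation("edge-order", "TrackEdge", f"{e.src}->{e.dst}",
                                 f"edge {e.src!r}->{e.dst!r} does not move forward in time "
                                 f"(t_from={t_src}, t_to={t_dst})"))
    return out


def resolve_physical(record: SpatialRecord, su: ScaleUnit) -> PhysicalPoint:
    """Map a record's stored coordinates and time to physical units.

    Scaling is linear and componentwise: physical x is ``x * x_scale`` and
    physical time is ``t * t_scale`` (so with a 2-minute interval, stored
    t=1 under tScale=2 means 2 minutes).
    """
    if (record.z is not None) and not su.has_z:
        raise DimensionMismatchError(
            f"record {record.ID!r} has a z coordinate but dimension is {su.dimension}")
    if (record.z is None) and su.has_z:
        raise DimensionMismatchError(
            f"record {record.ID!r} lacks a z coordinate but dimension is {su.dimension}")
    return PhysicalPoint(
        x=record.x * (su.x_scale if su.x_scale is not None else 1.0),
        y=record.y * (su.y_scale if su.y_scale is not None else 1.0),
        z=None if record.z is None else record.z * su.z_scale,
        t=record.t * su.t_scale if su.has_t else None,
        s_unit=su.s_unit,
        t_unit=su.t_unit,
    )
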