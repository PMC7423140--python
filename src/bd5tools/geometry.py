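"""The five geometric entity kinds and their tabular row representation.

A biological object at one time point is stored as one of five entities:
point, circle and sphere occupy a single table row; line and face spread an
ordered vertex list over several rows sharing one ID, with the sequential
index sID (0..k-1) recording the connection order "from the top".  Faces are
open vertex rings: the closing segment back to vertex 0 is implied by the
kind, and vertex order is preserved exactly as given.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import EntityArityError, MalformedEntityError
from .model import ENTITY_KINDS, SpatialRecord

__all__ = ["EntityGeometry", "make_entity", "assemble_entities", "centroid"]

_MIN_VERTICES = {"point": 1, "circle": 1, "sphere": 1, "line": 2, "face": 3}
_HAS_RADIUS = {"circle", "sphere"}
_SEQUENCED = {"line", "face"}


@dataclass
class EntityGeometry:
    """One geometric entity: kind, identity, time and ordered vertices."""

    kind: str
    ID: str
    t: float
    vertices: list[tuple]
    radius: float | None = None
    label: str | None = None

    @property
    def is_3d(self) -> bool:
        return len(self.vertices[0]) == 3


def _check_arity(kind, vertices, radius):
    if kind not in ENTITY_KINDS:
        raise EntityArityError(f"unknown entity kind {kind!r}; expected one of {ENTITY_KINDS}")
    n = len(vertices)
    if kind in _SEQUENCED:
        if n < _MIN_VERTICES[kind]:
            raise EntityArityError(f"a {kind} needs at least {_MIN_VERTICES[kind]} vertices, got {n}")
    elif n != 1:
        raise EntityArityError(f"a {kind} has exactly one vertex, got {n}")
    if kind in _HAS_RADIUS:
        if radius is None or not (radius > 0):
            raise EntityArityError(f"a {kind} needs a positive radius, got {radius}")
    elif radius is not None:
        raise EntityArityError(f"a {kind} does not carry a radius")
    dims = {len(v) for v in vertices}
    if not dims <= {2, 3} or len(dims) != 1:
        raise EntityArityError(f"vertices must all be 2D or all 3D tuples, got lengths {sorted(dims)}")


def make_entity(
    kind: str,
    ID: str,
    t: float,
    vertices: Sequence[tuple],
    radius: float | None = None,
    label: str | None = None,
) -> list[SpatialRecord]:
    """Emit the table rows of one entity.

    Point/circle/sphere yield one row without sID; line/face yield one row
    per vertex with sID = 0..k-1 in input order.
    """
    vertices = [tuple(v) for v in vertices]
    _check_arity(kind, vertices, radius)
    sequenced = kind in _SEQUENCED
    rows = []
    for i, v in enumerate(vertices):
        rows.append(SpatialRecord(
            ID=ID, t=t,
            x=float(v[0]), y=float(v[1]),
            z=float(v[2]) if len(v) == 3 else None,
            sID=i if sequenced else None,
            radius=radius,
            label=label,
        ))
    return rows


def assemble_entities(records: Iterable[SpatialRecord], kind: str) -> list[EntityGeometry]:
    """Reassemble entities from the rows of one dataset at one time point.

    Rows are grouped by ID (first-appearance order preserved) and vertices
    ordered by ascending sID; this is the inverse of :func:`make_entity`
    under any row permutation.  A duplicate (ID, sID) pair or a gap in an
    sID run raises :class:`MalformedEntityError` naming the ID.
    """
    if kind not in ENTITY_KINDS:
        raise EntityArityError(f"unknown entity kind {kind!r}")
    by_id: dict[str, list[SpatialRecord]] = {}
    for r in records:
        by_id.setdefault(r.ID, []).append(r)
    sequenced = kind in _SEQUENCED
    out = []
    for ID, rows in by_id.items():
        if sequenced:
            sids = [r.sID for r in rows]
            if None in sids:
                raise MalformedEntityError(f"{kind} {ID!r}: row without sID")
            if len(set(sids)) != len(sids):
                raise MalformedEntityError(f"{kind} {ID!r}: duplicate sID")
            if sorted(sids) != list(range(len(rows))):
                raise MalformedEntityError(f"{kind} {ID!r}: sID run has gaps (got {sorted(sids)})")
            rows = sorted(rows, key=lambda r: r.sID)
        elif len(rows) != 1:
            raise MalformedEntityError(f"{kind} {ID!r}: {len(rows)} rows for a single-row kind")
        first = rows[0]
        vertices = [
            (r.x, r.y) if r.z is None else (r.x, r.y, r.z)
            for r in rows
        ]
        if len(vertices) < _MIN_VERTICES[kind]:
            raise MalformedEntityError(
                f"{kind} {ID!r}: only {len(vertices)} vertices (needs {_MIN_VERTICES[kind]})")
        out.append(EntityGeometry(
            kind=kind, ID=ID, t=first.t, vertices=vertices,
            radius=first.radius, label=first.label,
        ))
    return out


def centroid(entity: EntityGeometry) -> tuple:
    """Arithmetic mean of the entity's vertices (the vertex itself for
    single-vertex kinds)."""
    n = len(entity.vertices)
    dims = len(entity.vertices[0])
    return tuple(sum(v[d] for v in entity.vertices) / n for d in range(dims))
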