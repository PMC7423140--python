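"""HDF5 persistence of BD5 documents with random access to time groups.

Layout (one HDF5 file)::

    /data                     group
    /data/scaleUnit           1-row compound dataset
    /data/objectDef           rows: oID, name, entity
    /data/featureDef          rows: fID, name
    /data/trackInfo           rows: from, to        (omitted when no edges)
    /data/<k>/object/<oID>    spatial-record rows, attribute "entity"
    /data/<k>/feature/<oID>   feature-record rows   (omitted when empty)

Numbered groups are unpadded decimal names ("0", "1", ..., "10"); readers
sort them numerically, never lexicographically.  Record-table strings (ID,
label, trackInfo endpoints) are fixed-width UTF-8 sized per dataset — a
variable-length string costs ~40 bytes of HDF5 heap machinery per value,
which would roughly double the size of coordinate-heavy files and defeat
the format's compactness; the reader accepts either representation.
Numeric payloads are 64-bit IEEE floats / 64-bit signed ints, written
without chunking or compression filters so that time-group access stays a
single contiguous read.

Absent columns are genuinely absent: z exists only in 3D files, sID only
for line/face datasets, radius only for circle/sphere, label only when some
row has one.  The single-row scaleUnit dataset instead keeps one dtype for
all dimensionalities, storing NaN / empty string for absent axes, which
keeps the dimension check in the linter simple.

Writes are byte-reproducible: identical documents yield identical files
(object timestamps are disabled).
"""

from __future__ import annotations

import math
from typing import Iterator

import h5py
import numpy as np

from .errors import StructureError, ValidationFailedError
from .model import (
    BD5Document,
    FeatureDef,
    FeatureRecord,
    ObjectDef,
    ScaleUnit,
    SpatialRecord,
    TimeGroup,
    TrackEdge,
    validate_document,
)

__all__ = ["write_bd5", "read_bd5", "BD5File"]

_VSTR = h5py.string_dtype(encoding="utf-8")


def _fixed_str(values: list[str]) -> np.dtype:
    """Fixed-width UTF-8 dtype sized to the longest encoded value."""
    width = max((len(v.encode("utf-8")) for v in values), default=1)
    return h5py.string_dtype(encoding="utf-8", length=max(width, 1))


def _spatial_dtype(kind: str, has_z: bool, with_label: bool, ids, labels) -> np.dtype:
    fields = [("ID", _fixed_str(ids)), ("t", "<f8")]
    if kind in ("line", "face"):
        fields.append(("sID", "<i8"))
    fields += [("x", "<f8"), ("y", "<f8")]
    if has_z:
        fields.append(("z", "<f8"))
    if kind in ("circle", "sphere"):
        fields.append(("radius", "<f8"))
    if with_label:
        fields.append(("label", _fixed_str(labels)))
    return np.dtype(fields)


def _write_spatial(parent: h5py.Group, name: str, kind: str, has_z: bool,
                   recs: list[SpatialRecord]) -> None:
    ids = [r.ID for r in recs]
    labels = [r.label or "" for r in recs]
    with_label = any(r.label is not None for r in recs)
    dt = _spatial_dtype(kind, has_z, with_label, ids, labels)
    arr = np.empty(len(recs), dtype=dt)
    arr["ID"] = [i.encode("utf-8") for i in ids]
    arr["t"] = [r.t for r in recs]
    arr["x"] = [r.x for r in recs]
    arr["y"] = [r.y for r in recs]
    if "sID" in dt.names:
        arr["sID"] = [r.sID for r in recs]
    if "z" in dt.names:
        arr["z"] = [r.z for r in recs]
    if "radius" in dt.names:
        arr["radius"] = [r.radius for r in recs]
    if "label" in dt.names:
        arr["label"] = [s.encode("utf-8") for s in labels]
    ds = parent.create_dataset(name, data=arr, track_times=False)
    ds.attrs["entity"] = str(kind)


def _write_features(parent: h5py.Group, name: str, recs: list[FeatureRecord]) -> None:
    dt = np.dtype([("ID", _fixed_str([r.ID for r in recs])), ("fID", "<i8"), ("value", "<f8")])
    arr = np.empty(len(recs), dtype=dt)
    arr["ID"] = [r.ID.encode("utf-8") for r in recs]
    arr["fID"] = [r.fID for r in recs]
    arr["value"] = [r.value for r in recs]
    parent.create_dataset(name, data=arr, track_times=False)


def write_bd5(doc: BD5Document, path) -> "BD5File":
    """Serialize a valid document to ``path`` and return a read handle.

    Refuses invalid documents (raises :class:`ValidationFailedError` listing
    the violations).  trackInfo is written only when edges exist; feature
    datasets only for non-empty feature lists.
    """
    violations = validate_document(doc)
    if violations:
        raise ValidationFailedError(violations)
    su = doc.scale_unit
    with h5py.File(path, "w", libver="latest") as f:
        data = f.create_group("data")

        su_dt = np.dtype([
            ("dimension", _fixed_str([su.dimension])),
            ("xScale", "<f8"), ("yScale", "<f8"), ("zScale", "<f8"),
            ("sUnit", _VSTR), ("tScale", "<f8"), ("tUnit", _VSTR),
        ])
        row = np.empty(1, dtype=su_dt)
        row["dimension"] = su.dimension.encode("utf-8")
        row["xScale"] = su.x_scale if su.x_scale is not None else np.nan
        row["yScale"] = su.y_scale if su.y_scale is not None else np.nan
        row["zScale"] = su.z_scale if su.z_scale is not None else np.nan
        row["sUnit"] = su.s_unit or ""
        row["tScale"] = su.t_scale if su.t_scale is not None else np.nan
        row["tUnit"] = su.t_unit or ""
        data.create_dataset("scaleUnit", data=row, track_times=False)

        od_dt = np.dtype([("oID", "<i8"), ("name", _VSTR), ("entity", _VSTR)])
        od = np.empty(len(doc.object_defs), dtype=od_dt)
        for i, d in enumerate(doc.object_defs):
            od[i] = (d.oID, d.name, d.entity)
        data.create_dataset("objectDef", data=od, track_times=False)

        fd_dt = np.dtype([("fID", "<i8"), ("name", _VSTR)])
        fd = np.empty(len(doc.feature_defs), dtype=fd_dt)
        for i, d in enumerate(doc.feature_defs):
            fd[i] = (d.fID, d.name)
        data.create_dataset("featureDef", data=fd, track_times=False)

        if doc.track_info:
            endpoints = [e.src for e in doc.track_info] + [e.dst for e in doc.track_info]
            ti_dt = np.dtype([("from", _fixed_str(endpoints)), ("to", _fixed_str(endpoints))])
            ti = np.empty(len(doc.track_info), dtype=ti_dt)
            ti["from"] = [e.src.encode("utf-8") for e in doc.track_info]
            ti["to"] = [e.dst.encode("utf-8") for e in doc.track_info]
            data.create_dataset("trackInfo", data=ti, track_times=False)

        kind_of = {d.oID: d.entity for d in doc.object_defs}
        for g in doc.time_groups:
            grp = data.create_group(str(g.index))
            obj = grp.create_group("object")
            for oid in g.objects:
                _write_spatial(obj, str(oid), kind_of[oid], su.has_z, g.objects[oid])
            nonempty = {oid: recs for oid, recs in g.features.items() if recs}
            if nonempty:
                feat = grp.create_group("feature")
                for oid, recs in nonempty.items():
                    _write_features(feat, str(oid), recs)
    return BD5File(path)


def _as_str(value) -> str:
    return value.decode("utf-8") if isinstance(value, bytes) else str(value)


def _opt(value: float) -> float | None:
    return None if math.isnan(value) else float(value)


def _read_scale_unit(data: h5py.Group) -> ScaleUnit:
    row = data["scaleUnit"][0]
    names = row.dtype.names
    s_unit = _as_str(row["sUnit"]) if "sUnit" in names else ""
    t_unit = _as_str(row["tUnit"]) if "tUnit" in names else ""
    return ScaleUnit(
        dimension=_as_str(row["dimension"]),
        x_scale=_opt(row["xScale"]),
        y_scale=_opt(row["yScale"]),
        z_scale=_opt(row["zScale"]),
        s_unit=s_unit or None,
        t_scale=_opt(row["tScale"]),
        t_unit=t_unit or None,
    )


def _read_spatial(ds: h5py.Dataset) -> list[SpatialRecord]:
    arr = ds[()]
    names = arr.dtype.names
    out = []
    for row in arr:
        label = _as_str(row["label"]) if "label" in names else ""
        out.append(SpatialRecord(
            ID=_as_str(row["ID"]),
            t=float(row["t"]),
            x=float(row["x"]),
            y=float(row["y"]),
            sID=int(row["sID"]) if "sID" in names else None,
            z=float(row["z"]) if "z" in names else None,
            radius=float(row["radius"]) if "radius" in names else None,
            label=label or None,
        ))
    return out


def _read_features(ds: h5py.Dataset) -> list[FeatureRecord]:
    return [
        FeatureRecord(ID=_as_str(row["ID"]), fID=int(row["fID"]), value=float(row["value"]))
        for row in ds[()]
    ]


def _numbered(names) -> list[int]:
    return sorted(int(n) for n in names if n.isdigit())


class BD5File:
    """Read handle over a BD5 file with per-time-group random access.

    Opening enumerates the numbered group names only; no record arrays (and
    no per-group times) are read until asked for, so the cost of
    :meth:`read_time_group` depends on that group's payload, not on how many
    time points the file holds.
    """

    def __init__(self, path, mode: str = "r"):
        self.path = str(path)
        try:
            self._f = h5py.File(path, mode)
        except OSError as exc:
            raise StructureError(f"{path}: not a readable HDF5 file ({exc})") from exc
        if "data" not in self._f:
            self._f.close()
            raise StructureError(f"{path}: missing required group 'data'")
        self._data = self._f["data"]
        for required in ("scaleUnit", "objectDef", "featureDef"):
            if required not in self._data:
                self._f.close()
                raise StructureError(f"{path}: missing required dataset 'data/{required}'")
        self.group_indices = _numbered(self._data.keys())
        if self.group_indices != list(range(len(self.group_indices))):
            self._f.close()
            raise StructureError(
                f"{path}: numbered groups {self.group_indices} are not the contiguous run 0..n-1")
        self._times: dict[int, float] = {}

    def __enter__(self) -> "BD5File":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def close(self) -> None:
        self._f.close()

    @property
    def n_groups(self) -> int:
        return len(self.group_indices)

    def scale_unit(self) -> ScaleUnit:
        return _read_scale_unit(self._data)

    def object_defs(self) -> list[ObjectDef]:
        return [
            ObjectDef(oID=int(r["oID"]), name=_as_str(r["name"]), entity=_as_str(r["entity"]))
            for r in self._data["objectDef"][()]
        ]

    def feature_defs(self) -> list[FeatureDef]:
        return [
            FeatureDef(fID=int(r["fID"]), name=_as_str(r["name"]))
            for r in self._data["featureDef"][()]
        ]

    def track_info(self) -> list[TrackEdge]:
        if "trackInfo" not in self._data:
            return []
        return [
            TrackEdge(src=_as_str(r["from"]), dst=_as_str(r["to"]))
            for r in self._data["trackInfo"][()]
        ]

    def group_time(self, index: int) -> float:
        """Stored t of one numbered group (reads a single element)."""
        if index not in self._times:
            grp = self._group(index)
            obj = grp["object"]
            first = obj[next(iter(obj.keys()))]
            self._times[index] = float(first[0]["t"])
        return self._times[index]

    def _group(self, index: int) -> h5py.Group:
        if index not in self.group_indices:
            raise IndexError(
                f"time group {index} out of range; available indices 0..{self.n_groups - 1}")
        return self._data[str(index)]

    def list_times(self) -> list[tuple[int, float]]:
        """Ordered (group index, stored t) pairs, ascending in both."""
        return [(k, self.group_time(k)) for k in self.group_indices]

    def read_time_group(self, index: int) -> TimeGroup:
        """Load exactly one numbered group's spatial and feature records."""
        grp = self._group(index)
        if "object" not in grp:
            raise StructureError(f"{self.path}: group data/{index} lacks an 'object' subgroup")
        objects = {
            oid: _read_spatial(grp["object"][str(oid)])
            for oid in _numbered(grp["object"].keys())
        }
        features = {}
        if "feature" in grp:
            features = {
                oid: _read_features(grp["feature"][str(oid)])
                for oid in _numbered(grp["feature"].keys())
            }
        ts = {r.t for recs in objects.values() for r in recs}
        t = ts.pop() if len(ts) == 1 else self.group_time(index)
        self._times[index] = t
        return TimeGroup(index=index, t=t, objects=objects, features=features)

    def iter_time_groups(self) -> Iterator[TimeGroup]:
        for k in self.group_indices:
            yield self.read_time_group(k)


def read_bd5(path) -> BD5Document:
    """Load a whole BD5 file into a document.

    Inverse of :func:`write_bd5`: the round trip is exact, with
    floating-point payloads bit-identical.  Missing required datasets raise
    :class:`StructureError` naming the missing path.
    """
    with BD5File(path) as h:
        return BD5Document(
            scale_unit=h.scale_unit(),
            object_defs=h.object_defs(),
            feature_defs=h.feature_defs(),
            time_groups=[h.read_time_group(k) for k in h.group_indices],
            track_info=h.track_info(),
        )
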