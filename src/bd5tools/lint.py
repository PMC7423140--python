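"""File-level BD5 validator with structure, reference, dimension and type checks.

The linter works directly on the HDF5 file (not through the document
reader), so it can report on files the reader would refuse.  Four check
classes:

structure
    /data with scaleUnit/objectDef/featureDef present; every numbered group
    has an ``object`` subgroup.  ``feature`` subgroups and ``trackInfo``
    are optional.
reference
    numbered dataset names under object/ and feature/ appear as oIDs in
    objectDef; fID values in feature rows appear in featureDef.
dimension
    the declared scaleUnit dimension agrees with the data: 3D files carry
    finite z values, non-3D files carry no z column; scale factors for
    declared axes are present and positive.
type
    column dtypes match the dialect (string ID/label, float coordinates
    and values, integer sID/oID/fID), radius values are positive, sID runs
    are contiguous from 0 per ID, and the "entity" attribute names one of
    the five kinds.

All four classes report errors; unknown extra datasets or attributes are
warnings only, so future format extensions do not fail old linters.  A
report is ``passed`` iff it holds no error-severity issues, and identical
files always yield identical reports.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import h5py
import numpy as np

from .model import DIMENSIONS, ENTITY_KINDS

__all__ = ["Issue", "LintReport", "lint", "check_structure", "check_references",
           "check_dimensions", "check_types"]

_CHECK_ORDER = {"structure": 0, "reference": 1, "dimension": 2, "type": 3}
_REQUIRED = ("scaleUnit", "objectDef", "featureDef")
_KNOWN_TOP = set(_REQUIRED) | {"trackInfo"}

_STRING, _FLOAT, _INT = "string", "float", "integer"
_COLUMN_KINDS = {
    "ID": _STRING, "label": _STRING, "from": _STRING, "to": _STRING,
    "t": _FLOAT, "x": _FLOAT, "y": _FLOAT, "z": _FLOAT, "radius": _FLOAT, "value": _FLOAT,
    "sID": _INT, "oID": _INT, "fID": _INT,
}


@dataclass(frozen=True)
class Issue:
    severity: str  # "error" | "warning"
    check: str     # "structure" | "reference" | "dimension" | "type"
    path: str      # HDF5 path
    message: str

    def __str__(self):
        return f"{self.severity}[{self.check}] {self.path}: {self.message}"


@dataclass
class LintReport:
    issues: list[Issue] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def sorted(self) -> "LintReport":
        return LintReport(sorted(
            self.issues, key=lambda i: (_CHECK_ORDER.get(i.check, 9), i.path, i.message)))

    def to_json(self) -> str:
        return json.dumps({
            "passed": self.passed,
            "issues": [vars(i) for i in self.issues],
        }, indent=2)

    def __str__(self):
        if not self.issues:
            return "OK: no issues"
        head = "PASSED (warnings only)" if self.passed else "FAILED"
        return "\n".join([head] + [str(i) for i in self.issues])


def _err(issues, check, path, message):
    issues.append(Issue("error", check, path, message))


def _warn(issues, check, path, message):
    issues.append(Issue("warning", check, path, message))


def _numbered_groups(data: h5py.Group) -> list[str]:
    return sorted((n for n in data if n.isdigit()), key=int)


def _dtype_class(dt: np.dtype) -> str:
    if h5py.check_string_dtype(dt):
        return _STRING
    if dt.kind == "f":
        return _FLOAT
    if dt.kind in "iu":
        return _INT
    return dt.kind


def check_structure(f: h5py.File) -> list[Issue]:
    issues: list[Issue] = []
    if "data" not in f or not isinstance(f["data"], h5py.Group):
        _err(issues, "structure", "/data", "missing required group")
        return issues
    data = f["data"]
    for name in _REQUIRED:
        if name not in data or not isinstance(data[name], h5py.Dataset):
            _err(issues, "structure", f"/data/{name}", "missing required dataset")
    for name in data:
        if not name.isdigit() and name not in _KNOWN_TOP:
            _warn(issues, "structure", f"/data/{name}", "unknown entry (ignored)")
    for k in _numbered_groups(data):
        grp = data[k]
        if not isinstance(grp, h5py.Group):
            _err(issues, "structure", f"/data/{k}", "numbered entry is not a group")
            continue
        if "object" not in grp or not isinstance(grp["object"], h5py.Group):
            _err(issues, "structure", f"/data/{k}/object", "numbered group lacks an object subgroup")
        for name in grp:
            if name not in ("object", "feature"):
                _warn(issues, "structure", f"/data/{k}/{name}", "unknown entry (ignored)")
    return issues


def _defined_ids(data: h5py.Group, dataset: str, column: str) -> set[int] | None:
    if dataset not in data:
        return None
    try:
        arr = data[dataset][()]
        return {int(v) for v in arr[column]}
    except (KeyError, ValueError, TypeError):
        return None


def check_references(f: h5py.File) -> list[Issue]:
    issues: list[Issue] = []
    data = f["data"]
    oids = _defined_ids(data, "objectDef", "oID")
    fids = _defined_ids(data, "featureDef", "fID")
    for k in _numbered_groups(data):
        grp = data[k]
        for sub in ("object", "feature"):
            if sub not in grp:
                continue
            for name in grp[sub]:
                if not name.isdigit():
                    _warn(issues, "reference", f"/data/{k}/{sub}/{name}",
                          "dataset name is not a reference number")
                    continue
                if oids is not None and int(name) not in oids:
                    _err(issues, "reference", f"/data/{k}/{sub}/{name}",
                         f"dataset name {name} is not an oID defined in objectDef")
        if "feature" in grp and fids is not None:
            for name in grp["feature"]:
                ds = grp["feature"][name]
                if isinstance(ds, h5py.Dataset) and ds.dtype.names and "fID" in ds.dtype.names:
                    bad = sorted({int(v) for v in ds["fID"]} - fids)
                    if bad:
                        _err(issues, "reference", f"/data/{k}/feature/{name}",
                             f"fID value(s) {bad} not defined in featureDef")
    return issues


def check_dimensions(f: h5py.File) -> list[Issue]:
    issues: list[Issue] = []
    data = f["data"]
    if "scaleUnit" not in data:
        return issues
    su = data["scaleUnit"]
    names = su.dtype.names or ()
    if "dimension" not in names or su.shape[0] != 1:
        _err(issues, "dimension", "/data/scaleUnit",
             "scaleUnit must be a one-row table with a dimension column")
        return issues
    row = su[0]
    dim = row["dimension"]
    dim = dim.decode("utf-8") if isinstance(dim, bytes) else str(dim)
    if dim not in DIMENSIONS:
        _err(issues, "dimension", "/data/scaleUnit",
             f"dimension {dim!r} is not one of {DIMENSIONS}")
        return issues
    has_z = dim.startswith("3D")
    has_t = dim.endswith("+T")

    def scale_ok(col):
        return col in names and math.isfinite(row[col]) and row[col] > 0

    if has_z and not scale_ok("zScale"):
        _err(issues, "dimension", "/data/scaleUnit",
             f"dimension {dim} requires a positive zScale")
    if not has_z and "zScale" in names and math.isfinite(row["zScale"]):
        _err(issues, "dimension", "/data/scaleUnit",
             f"dimension {dim} must not declare a zScale")
    if has_t and not scale_ok("tScale"):
        _err(issues, "dimension", "/data/scaleUnit",
             f"dimension {dim} requires a positive tScale")

    for k in _numbered_groups(data):
        grp = data[k]
        if "object" not in grp:
            continue
        for name, ds in grp["object"].items():
            if not isinstance(ds, h5py.Dataset) or not ds.dtype.names:
                continue
            path = f"/data/{k}/object/{name}"
            cols = ds.dtype.names
            if has_z:
                if "z" not in cols:
                    _err(issues, "dimension", path, f"dimension {dim} requires a z column")
                elif ds.shape[0] and not np.isfinite(ds["z"]).all():
                    _err(issues, "dimension", path,
                         f"dimension {dim} requires finite z values in every row")
            elif "z" in cols and ds.shape[0] and np.isfinite(ds["z"]).any():
                _err(issues, "dimension", path,
                     f"dimension {dim} but rows carry finite z values")
            if "t" in cols and ds.shape[0] and not np.isfinite(ds["t"]).all():
                _err(issues, "dimension", path, "non-finite t values")
    return issues


def _check_record_types(path, ds, issues, expect_entity: bool):
    cols = ds.dtype.names
    if cols is None:
        _err(issues, "type", path, "dataset is not a compound table")
        return
    for col in cols:
        want = _COLUMN_KINDS.get(col)
        if want is None:
            _warn(issues, "type", path, f"unknown column {col!r} (ignored)")
            continue
        got = _dtype_class(ds.dtype[col])
        if got != want:
            _err(issues, "type", path, f"column {col!r} stored as {got}, expected {want}")
    if not expect_entity:
        return
    entity = ds.attrs.get("entity")
    if entity is None:
        _err(issues, "type", path, "object dataset lacks an 'entity' attribute")
        return
    entity = entity.decode("utf-8") if isinstance(entity, bytes) else str(entity)
    if entity not in ENTITY_KINDS:
        _err(issues, "type", path,
             f"entity attribute {entity!r} is not one of {ENTITY_KINDS}")
        return
    if ds.shape[0] == 0:
        return
    if entity in ("circle", "sphere"):
        if "radius" not in cols:
            _err(issues, "type", path, f"{entity} dataset lacks a radius column")
        elif (("radius" in cols) and _dtype_class(ds.dtype["radius"]) == _FLOAT
              and not (ds["radius"] > 0).all()):
            _err(issues, "type", path, "radius values must be strictly positive")
    if entity in ("line", "face"):
        if "sID" not in cols or _dtype_class(ds.dtype["sID"]) != _INT:
            if "sID" not in cols:
                _err(issues, "type", path, f"{entity} dataset lacks an sID column")
            return
        if h5py.check_string_dtype(ds.dtype["ID"]):
            runs: dict = {}
            for row in ds[()]:
                runs.setdefault(row["ID"], []).append(int(row["sID"]))
            for ID, sids in runs.items():
                if sorted(sids) != list(range(len(sids))):
                    name = ID.decode("utf-8") if isinstance(ID, bytes) else ID
                    _err(issues, "type", path,
                         f"sID run for ID {name!r} is not the contiguous sequence 0..k-1")


def check_types(f: h5py.File) -> list[Issue]:
    issues: list[Issue] = []
    data = f["data"]
    for name, col in (("objectDef", "oID"), ("featureDef", "fID")):
        if name not in data:
            continue
        ds = data[name]
        if ds.dtype.names and col in ds.dtype.names:
            if _dtype_class(ds.dtype[col]) != _INT:
                _err(issues, "type", f"/data/{name}", f"column {col!r} must be integer")
        else:
            _err(issues, "type", f"/data/{name}", f"missing {col!r} column")
    if "trackInfo" in data:
        _check_record_types("/data/trackInfo", data["trackInfo"], issues, expect_entity=False)
    for k in _numbered_groups(data):
        grp = data[k]
        for sub in ("object", "feature"):
            if sub not in grp or not isinstance(grp[sub], h5py.Group):
                continue
            for name, ds in grp[sub].items():
                if isinstance(ds, h5py.Dataset):
                    _check_record_types(f"/data/{k}/{sub}/{name}", ds, issues,
                                        expect_entity=(sub == "object"))
    return issues


def lint(path) -> LintReport:
    """Run all four check classes on a file and return the ordered report.

    Only an unreadable (non-HDF5) file short-circuits, yielding a single
    fatal structural error; otherwise reference/dimension/type checks run
    whenever the pieces they inspect exist.
    """
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        return LintReport([Issue("error", "structure", str(path),
                                 f"not a readable HDF5 file ({exc})")])
    with f:
        issues = check_structure(f)
        if "data" in f and isinstance(f["data"], h5py.Group):
            issues += check_references(f)
            issues += check_dimensions(f)
            issues += check_types(f)
    return LintReport(issues).sorted()
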