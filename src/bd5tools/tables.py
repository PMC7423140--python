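"""CSV import/export of spatial records.

The importer maps user-named columns onto the record fields through a
column map (``{"ID": "cell", "t": "frame", "x": "pos_x", ...}``), builds
records of one entity kind for one object class, and buckets them into
time groups.  The exporter writes one CSV row per spatial record with all
dialect columns plus ``oID`` and ``entity``, RFC-style quoted; a document
with a single object class round-trips losslessly through
``import_csv(export_csv(doc))``.
"""

from __future__ import annotations

import io
import math

import numpy as np
import pandas as pd

from .errors import CSVImportError
from .model import (
    BD5Document,
    ENTITY_KINDS,
    FeatureDef,
    ObjectDef,
    ScaleUnit,
    SpatialRecord,
    assign_time_groups,
)

__all__ = ["import_csv", "export_csv"]

_NUMERIC = ("t", "x", "y", "z", "radius")
_OPTIONAL = ("z", "radius", "sID", "label")


def _cell_float(value, line: int, column: str) -> float:
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise CSVImportError(
            f"line {line}: column {column!r} value {value!r} is not numeric") from None
    if math.isnan(out):
        raise CSVImportError(f"line {line}: column {column!r} is empty or NaN")
    return out


def _cell_opt(value):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return value


def import_csv(
    table,
    column_map: dict[str, str],
    kind: str,
    oID: int = 0,
    scale_unit: ScaleUnit | None = None,
    object_name: str = "object",
    feature_defs: list[FeatureDef] | None = None,
) -> BD5Document:
    """Build a single-object-class document from a CSV table.

    ``table`` is a path, file object, or DataFrame.  ``column_map`` maps
    record fields (ID, t, x, y and optionally z, radius, sID, label) to the
    table's column names.  Cell errors name the 1-based CSV line (header is
    line 1).  Without an explicit ``scale_unit``, a unit-scale 2D+T or 3D+T
    one is inferred from the presence of a z mapping.
    """
    if kind not in ENTITY_KINDS:
        raise CSVImportError(f"unknown entity kind {kind!r}; expected one of {ENTITY_KINDS}")
    if isinstance(table, pd.DataFrame):
        df = table.reset_index(drop=True)
    else:
        df = pd.read_csv(table, dtype={column_map.get("ID", "ID"): str,
                                       column_map.get("label", "label"): str},
                         float_precision="round_trip")
    for field in ("ID", "t", "x", "y"):
        if field not in column_map:
            raise CSVImportError(f"column map lacks required field {field!r}")
    missing = [col for col in column_map.values() if col not in df.columns]
    if missing:
        raise CSVImportError(f"mapped column(s) {missing} not present in table")

    records: list[SpatialRecord] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        get = lambda field: row[column_map[field]] if field in column_map else None
        z = _cell_opt(get("z"))
        radius = _cell_opt(get("radius"))
        sid = _cell_opt(get("sID"))
        label = _cell_opt(get("label"))
        records.append(SpatialRecord(
            ID=str(get("ID")),
            t=_cell_float(get("t"), line, column_map["t"]),
            x=_cell_float(get("x"), line, column_map["x"]),
            y=_cell_float(get("y"), line, column_map["y"]),
            z=None if z is None else _cell_float(z, line, column_map["z"]),
            radius=None if radius is None else _cell_float(radius, line, column_map["radius"]),
            sID=None if sid is None else int(sid),
            label=None if label is None else str(label),
        ))

    has_z = any(r.z is not None for r in records)
    if scale_unit is None:
        scale_unit = ScaleUnit(
            dimension="3D+T" if has_z else "2D+T",
            x_scale=1.0, y_scale=1.0, z_scale=1.0 if has_z else None,
            s_unit="pixel", t_scale=1.0, t_unit="frame",
        )
    return BD5Document(
        scale_unit=scale_unit,
        object_defs=[ObjectDef(oID=oID, name=object_name, entity=kind)],
        feature_defs=list(feature_defs or []),
        time_groups=assign_time_groups(records, oID),
    )


def export_csv(doc: BD5Document, path=None) -> pd.DataFrame:
    """Flatten a document's spatial records into one table.

    One row per record, with oID and entity columns so multi-class
    documents stay distinguishable.  Writes RFC-quoted CSV to ``path``
    when given and returns the DataFrame either way.
    """
    kind_of = {d.oID: d.entity for d in doc.object_defs}
    rows = []
    for g in doc.time_groups:
        for oid, recs in g.objects.items():
            for r in recs:
                rows.append({
                    "oID": oid, "entity": kind_of.get(oid),
                    "ID": r.ID, "t": r.t, "sID": r.sID,
                    "x": r.x, "y": r.y, "z": r.z,
                    "radius": r.radius, "label": r.label,
                })
    df = pd.DataFrame(rows, columns=["oID", "entity", "ID", "t", "sID",
                                     "x", "y", "z", "radius", "label"])
    if path is not None:
        # 17 significant digits: every double round-trips through the text
        df.to_csv(path, index=False, float_format="%.17g")
    return df
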