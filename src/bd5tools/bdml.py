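"""BDML (v3.0 subset) parsing, emission, and BDML <-> BD5 conversion.

BDML is the XML companion format: it describes the same quantitative data
in a flat sequence of ``component`` elements (one biological object
instance at one time point), plus meta-information (title, summary,
methods, multiple contact persons with optional ORCID).  Version 3.0 can
instead point at an external BD5 file through ``extFile/bd5File`` and keep
only meta-information inline.

Correspondence with BD5:

======================  =============================================
BDML                    BD5
======================  =============================================
scaleUnit element       /data/scaleUnit dataset
object / feature        /data/objectDef, /data/featureDef
component/componentID   row ID in a numbered object dataset
component/componentName row label
component/time          the time group the rows land in
component/prevID        a trackInfo row (from=prevID, to=componentID)
======================  =============================================

A single prevID per component expresses continuation and division (two
components naming the same prevID).  Fusion needs several parents for one
component; the emitter writes multiple prevID children and the parser
accepts them, but the conversion report counts such constructs since
consumers of single-prevID BDML cannot represent them.

The element vocabulary used here (``bdml``, ``info``, ``summary``,
``methods``, ``contact``, ``data``, ``scaleUnit``, ``object``, ``feature``,
``component``, ``componentID``, ``componentName``, ``prevID``,
``measurement``, ``objectRef``, ``extFile``, ``bd5File``, ...) is a fixed
normative subset; unknown elements in input are warned about and ignored.
Floats are serialized with ``repr`` (shortest exact round-trip), so
coordinates survive BDML -> BD5 -> BDML bit-identically.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

from lxml import etree

from .errors import BDMLParseError
from .geometry import assemble_entities, make_entity
from .model import (
    BD5Document,
    FeatureDef,
    FeatureRecord,
    ObjectDef,
    ScaleUnit,
    TimeGroup,
    TrackEdge,
)

__all__ = [
    "Contact",
    "BDMLMeta",
    "Measurement",
    "Component",
    "BDMLDocument",
    "ConversionReport",
    "parse_bdml",
    "write_bdml",
    "bdml_to_bd5",
    "bd5_to_bdml",
    "write_bdml_meta",
]

_SINGLE_VERTEX = ("point", "circle", "sphere")
_ENTITY_TAGS = ("point", "circle", "line", "sphere", "face")


@dataclass
class Contact:
    name: str
    orcid: str | None = None


@dataclass
class BDMLMeta:
    title: str = ""
    summary: str = ""
    methods: str = ""
    contacts: list[Contact] = field(default_factory=list)
    license: str | None = None


@dataclass
class Measurement:
    """One geometric measurement of a component against one object class."""

    object_ref: int
    kind: str
    vertices: list[tuple]
    radius: float | None = None
    features: list[tuple[int, float]] = field(default_factory=list)


@dataclass
class Component:
    """One biological object instance at one time point."""

    component_id: str
    time: float
    component_name: str | None = None
    prev_ids: list[str] = field(default_factory=list)
    measurements: list[Measurement] = field(default_factory=list)


@dataclass
class BDMLDocument:
    meta: BDMLMeta = field(default_factory=BDMLMeta)
    scale_unit: ScaleUnit | None = None
    object_defs: list[ObjectDef] = field(default_factory=list)
    feature_defs: list[FeatureDef] = field(default_factory=list)
    components: list[Component] = field(default_factory=list)
    ext_file: str | None = None


@dataclass
class ConversionReport:
    """What a conversion dropped or had to bend to express."""

    dropped_edges: list[TrackEdge] = field(default_factory=list)
    multi_parent_components: int = 0
    warnings: list[str] = field(default_factory=list)


def _fmt(x: float) -> str:
    return repr(float(x))


def _sub(parent, tag, text=None):
    el = etree.SubElement(parent, tag)
    if text is not None:
        el.text = text
    return el


def _emit_scale_unit(parent, su: ScaleUnit) -> None:
    el = _sub(parent, "scaleUnit")
    _sub(el, "dimension", su.dimension)
    if su.x_scale is not None:
        _sub(el, "xScale", _fmt(su.x_scale))
    if su.y_scale is not None:
        _sub(el, "yScale", _fmt(su.y_scale))
    if su.z_scale is not None:
        _sub(el, "zScale", _fmt(su.z_scale))
    if su.s_unit is not None:
        _sub(el, "sUnit", su.s_unit)
    if su.t_scale is not None:
        _sub(el, "tScale", _fmt(su.t_scale))
    if su.t_unit is not None:
        _sub(el, "tUnit", su.t_unit)


def _emit_info(parent, meta: BDMLMeta) -> None:
    info = _sub(parent, "info")
    _sub(info, "title", meta.title)
    _sub(info, "summary", meta.summary)
    _sub(info, "methods", meta.methods)
    for c in meta.contacts:
        contact = _sub(info, "contact")
        _sub(contact, "name", c.name)
        if c.orcid is not None:
            _sub(contact, "orcid", c.orcid)
    if meta.license is not None:
        _sub(info, "license", meta.license)


def write_bdml(doc: BDMLDocument, path=None) -> bytes:
    """Serialize a BDML document to pretty-printed UTF-8 XML.

    Returns the bytes; additionally writes them to ``path`` when given.
    """
    root = etree.Element("bdml", version="3.0")
    _emit_info(root, doc.meta)
    has_payload = bool(doc.components) or doc.scale_unit is not None
    if has_payload:
        data = _sub(root, "data")
        if doc.scale_unit is not None:
            _emit_scale_unit(data, doc.scale_unit)
        for d in doc.object_defs:
            obj = _sub(data, "object")
            _sub(obj, "oID", str(d.oID))
            _sub(obj, "name", d.name)
            _sub(obj, "entity", d.entity)
        for d in doc.feature_defs:
            feat = _sub(data, "feature")
            _sub(feat, "fID", str(d.fID))
            _sub(feat, "name", d.name)
        for comp in doc.components:
            c = _sub(data, "component")
            _sub(c, "componentID", comp.component_id)
            if comp.component_name is not None:
                _sub(c, "componentName", comp.component_name)
            _sub(c, "time", _fmt(comp.time))
            for p in comp.prev_ids:
                _sub(c, "prevID", p)
            for m in comp.measurements:
                meas = _sub(c, "measurement")
                _sub(meas, "objectRef", str(m.object_ref))
                ent = _sub(meas, m.kind)
                if m.kind in _SINGLE_VERTEX:
                    v = m.vertices[0]
                    _sub(ent, "x", _fmt(v[0]))
                    _sub(ent, "y", _fmt(v[1]))
                    if len(v) == 3:
                        _sub(ent, "z", _fmt(v[2]))
                    if m.radius is not None:
                        _sub(ent, "radius", _fmt(m.radius))
                else:
                    for i, v in enumerate(m.vertices):
                        vx = _sub(ent, "vertex")
                        vx.set("sID", str(i))
                        _sub(vx, "x", _fmt(v[0]))
                        _sub(vx, "y", _fmt(v[1]))
                        if len(v) == 3:
                            _sub(vx, "z", _fmt(v[2]))
                for fid, value in m.features:
                    prop = _sub(meas, "property")
                    _sub(prop, "fID", str(fid))
                    _sub(prop, "value", _fmt(value))
    if doc.ext_file is not None:
        ext = _sub(root, "extFile")
        _sub(ext, "bd5File", doc.ext_file)
    payload = etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")
    if path is not None:
        with open(path, "wb") as fh:
            fh.write(payload)
    return payload


def _text(el, tag, default=None):
    child = el.find(tag)
    if child is None:
        return default
    return child.text or ""


def _warn_unknown(el, known: set[str]) -> None:
    for child in el:
        if isinstance(child.tag, str) and child.tag not in known:
            warnings.warn(
                f"ignoring unknown BDML element <{child.tag}> at line {child.sourceline}",
                stacklevel=3,
            )


def _parse_scale_unit(el) -> ScaleUnit:
    _warn_unknown(el, {"dimension", "xScale", "yScale", "zScale", "sUnit", "tScale", "tUnit"})
    opt = lambda tag: (None if _text(el, tag) is None else float(_text(el, tag)))
    return ScaleUnit(
        dimension=_text(el, "dimension", ""),
        x_scale=opt("xScale"),
        y_scale=opt("yScale"),
        z_scale=opt("zScale"),
        s_unit=_text(el, "sUnit"),
        t_scale=opt("tScale"),
        t_unit=_text(el, "tUnit"),
    )


def _parse_measurement(el) -> Measurement:
    _warn_unknown(el, {"objectRef", "property", *_ENTITY_TAGS})
    ref = _text(el, "objectRef")
    if ref is None:
        raise BDMLParseError(f"measurement at line {el.sourceline} lacks an objectRef")
    ent = None
    for tag in _ENTITY_TAGS:
        found = el.find(tag)
        if found is not None:
            ent = found
            kind = tag
            break
    if ent is None:
        raise BDMLParseError(f"measurement at line {el.sourceline} lacks an entity element")
    radius = None
    if kind in _SINGLE_VERTEX:
        x, y, z = _text(ent, "x"), _text(ent, "y"), _text(ent, "z")
        if x is None or y is None:
            raise BDMLParseError(f"<{kind}> at line {ent.sourceline} lacks x/y coordinates")
        vertices = [(float(x), float(y)) if z is None else (float(x), float(y), float(z))]
        r = _text(ent, "radius")
        radius = None if r is None else float(r)
    else:
        vertices = []
        for i, vx in enumerate(ent.findall("vertex")):
            sid = vx.get("sID")
            if sid is not None and int(sid) != i:
                raise BDMLParseError(
                    f"vertex at line {vx.sourceline} has sID={sid}, expected {i}")
            x, y, z = _text(vx, "x"), _text(vx, "y"), _text(vx, "z")
            if x is None or y is None:
                raise BDMLParseError(f"vertex at line {vx.sourceline} lacks x/y coordinates")
            vertices.append((float(x), float(y)) if z is None else (float(x), float(y), float(z)))
    features = []
    for prop in el.findall("property"):
        fid, value = _text(prop, "fID"), _text(prop, "value")
        if fid is None or value is None:
            raise BDMLParseError(f"property at line {prop.sourceline} lacks fID/value")
        features.append((int(fid), float(value)))
    return Measurement(object_ref=int(ref), kind=kind, vertices=vertices,
                       radius=radius, features=features)


def parse_bdml(source) -> BDMLDocument:
    """Parse BDML XML from a path, bytes, or file object.

    Malformed XML raises :class:`BDMLParseError` carrying the line number;
    so does a document with neither a ``data`` payload nor an ``extFile``
    pointer.  Unknown elements produce warnings and are skipped.
    """
    try:
        if isinstance(source, bytes):
            root = etree.fromstring(source)
        else:
            root = etree.parse(source).getroot()
    except etree.XMLSyntaxError as exc:
        raise BDMLParseError(f"malformed XML: {exc}") from exc
    if root.tag != "bdml":
        raise BDMLParseError(f"root element is <{root.tag}>, expected <bdml>")
    _warn_unknown(root, {"info", "data", "extFile"})

    doc = BDMLDocument()
    info = root.find("info")
    if info is not None:
        _warn_unknown(info, {"title", "summary", "methods", "contact", "license"})
        doc.meta.title = _text(info, "title", "")
        doc.meta.summary = _text(info, "summary", "")
        doc.meta.methods = _text(info, "methods", "")
        doc.meta.license = _text(info, "license")
        for c in info.findall("contact"):
            _warn_unknown(c, {"name", "orcid"})
            doc.meta.contacts.append(Contact(name=_text(c, "name", ""), orcid=_text(c, "orcid")))

    data = root.find("data")
    if data is not None:
        _warn_unknown(data, {"scaleUnit", "object", "feature", "component"})
        su = data.find("scaleUnit")
        if su is not None:
            doc.scale_unit = _parse_scale_unit(su)
        for obj in data.findall("object"):
            doc.object_defs.append(ObjectDef(
                oID=int(_text(obj, "oID")),
                name=_text(obj, "name", ""),
                entity=_text(obj, "entity", "point"),
            ))
        for feat in data.findall("feature"):
            doc.feature_defs.append(FeatureDef(
                fID=int(_text(feat, "fID")),
                name=_text(feat, "name", ""),
            ))
        for comp in data.findall("component"):
            _warn_unknown(comp, {"componentID", "componentName", "time", "prevID", "measurement"})
            cid = _text(comp, "componentID")
            time = _text(comp, "time")
            if cid is None or time is None:
                raise BDMLParseError(
                    f"component at line {comp.sourceline} lacks componentID/time")
            doc.components.append(Component(
                component_id=cid,
                time=float(time),
                component_name=_text(comp, "componentName"),
                prev_ids=[p.text or "" for p in comp.findall("prevID")],
                measurements=[_parse_measurement(m) for m in comp.findall("measurement")],
            ))

    ext = root.find("extFile")
    if ext is not None:
        doc.ext_file = _text(ext, "bd5File")

    if data is None and ext is None:
        raise BDMLParseError("document has neither a <data> payload nor an <extFile> pointer")
    return doc


def bdml_to_bd5(bdml: BDMLDocument) -> tuple[BD5Document, ConversionReport]:
    """Convert an inline-payload BDML document to a BD5 document.

    Components are bucketed into numbered time groups by ascending distinct
    time; componentID becomes the record ID, componentName the label, and
    each prevID a trackInfo edge.  A prevID naming an unknown component is
    dropped and reported.
    """
    if bdml.scale_unit is None:
        raise BDMLParseError("BDML document has no inline payload (missing scaleUnit)")
    report = ConversionReport()
    times = sorted({c.time for c in bdml.components})
    index_of = {t: k for k, t in enumerate(times)}
    groups = [TimeGroup(index=k, t=t) for k, t in enumerate(times)]

    known_ids = {c.component_id for c in bdml.components}
    edges: list[TrackEdge] = []
    for comp in bdml.components:
        g = groups[index_of[comp.time]]
        if len(comp.prev_ids) > 1:
            report.multi_parent_components += 1
        for p in comp.prev_ids:
            if p not in known_ids:
                edge = TrackEdge(src=p, dst=comp.component_id)
                report.dropped_edges.append(edge)
                report.warnings.append(
                    f"dropped edge {p!r}->{comp.component_id!r}: prevID names no component")
                continue
            edges.append(TrackEdge(src=p, dst=comp.component_id))
        for m in comp.measurements:
            rows = make_entity(m.kind, comp.component_id, comp.time, m.vertices,
                               radius=m.radius, label=comp.component_name)
            g.objects.setdefault(m.object_ref, []).extend(rows)
            for fid, value in m.features:
                g.features.setdefault(m.object_ref, []).append(
                    FeatureRecord(ID=comp.component_id, fID=fid, value=value))

    doc = BD5Document(
        scale_unit=bdml.scale_unit,
        object_defs=list(bdml.object_defs),
        feature_defs=list(bdml.feature_defs),
        time_groups=groups,
        track_info=edges,
    )
    return doc, report


def bd5_to_bdml(doc: BD5Document, meta: BDMLMeta | None = None) -> tuple[BDMLDocument, ConversionReport]:
    """Convert a BD5 document to inline-payload BDML.

    Semantic inverse of :func:`bdml_to_bd5`.  Track edges become prevID
    children on the target component; a fusion (several parents for one
    target) forces multiple prevID children, which single-prevID consumers
    cannot express — such components are counted in the report.
    """
    report = ConversionReport()
    kind_of = {d.oID: d.entity for d in doc.object_defs}

    # Resolve each edge target to (earliest occurrence group, ID).
    first_at: dict[str, int] = {}
    for g in doc.time_groups:
        for recs in g.objects.values():
            for r in recs:
                first_at.setdefault(r.ID, g.index)
    parents_of: dict[tuple[int, str], list[str]] = {}
    for e in doc.track_info:
        key = (first_at[e.dst], e.dst)
        parents_of.setdefault(key, []).append(e.src)

    components: list[Component] = []
    for g in doc.time_groups:
        by_id: dict[str, Component] = {}
        for oid, recs in g.objects.items():
            for entity in assemble_entities(recs, kind_of[oid]):
                comp = by_id.get(entity.ID)
                if comp is None:
                    comp = Component(
                        component_id=entity.ID,
                        time=g.t,
                        component_name=entity.label,
                        prev_ids=list(parents_of.get((g.index, entity.ID), [])),
                    )
                    by_id[entity.ID] = comp
                    components.append(comp)
                comp.measurements.append(Measurement(
                    object_ref=oid, kind=entity.kind,
                    vertices=entity.vertices, radius=entity.radius,
                ))
        for oid, frecs in g.features.items():
            for fr in frecs:
                comp = by_id.get(fr.ID)
                for m in comp.measurements:
                    if m.object_ref == oid:
                        m.features.append((fr.fID, fr.value))
                        break

    for comp in components:
        if len(comp.prev_ids) > 1:
            report.multi_parent_components += 1
            report.warnings.append(
                f"component {comp.component_id!r} carries {len(comp.prev_ids)} prevID children "
                f"(fusion); single-prevID BDML consumers cannot represent it")

    bdml = BDMLDocument(
        meta=meta or BDMLMeta(),
        scale_unit=doc.scale_unit,
        object_defs=list(doc.object_defs),
        feature_defs=list(doc.feature_defs),
        components=components,
    )
    return bdml, report


def write_bdml_meta(meta: BDMLMeta, bd5_path, out_path=None) -> bytes:
    """Emit a BDML v3.0 meta-information skeleton pointing at a BD5 file.

    The skeleton holds info (title/summary/methods/contacts/license) and an
    ``extFile/bd5File`` element naming the BD5 file; no inline payload.  A
    missing BD5 file is accepted with a warning.
    """
    if not os.path.exists(str(bd5_path)):
        warnings.warn(f"BD5 file {bd5_path!s} does not exist; writing pointer on trust")
    doc = BDMLDocument(meta=meta, ext_file=str(bd5_path))
    return write_bdml(doc, out_path)
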