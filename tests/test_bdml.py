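"""BDML parsing/emission and BDML <-> BD5 conversion."""

import numpy as np
import pytest

from bd5tools import (
    BDMLMeta,
    Contact,
    bd5_to_bdml,
    bdml_to_bd5,
    build_track_graph,
    find_divisions,
    parse_bdml,
    validate_document,
    write_bdml,
    write_bdml_meta,
)
from bd5tools.errors import BDMLParseError
from bd5tools.synthcell import random_document

MINIMAL = b"""<?xml version="1.0" encoding="UTF-8"?>
<bdml version="3.0">
  <info><title>t</title><summary>s</summary><methods>m</methods></info>
  <data>
    <scaleUnit>
      <dimension>2D+T</dimension>
      <xScale>1.0</xScale><yScale>1.0</yScale>
      <sUnit>micrometer</sUnit><tScale>1.0</tScale><tUnit>minute</tUnit>
    </scaleUnit>
    <object><oID>0</oID><name>cell</name><entity>point</entity></object>
    <component>
      <componentID>c1</componentID>
      <time>0.0</time>
      <measurement><objectRef>0</objectRef><point><x>1.5</x><y>2.5</y></point></measurement>
    </component>
  </data>
</bdml>
"""


class TestParse:
    def test_minimal_component(self):
        doc = parse_bdml(MINIMAL)
        assert len(doc.components) == 1
        (m,) = doc.components[0].measurements
        assert m.kind == "point" and m.vertices == [(1.5, 2.5)]

    def test_malformed_xml(self):
        with pytest.raises(BDMLParseError, match="malformed"):
            parse_bdml(b"<bdml><data></bdml>")

    def test_missing_payload_and_extfile(self):
        with pytest.raises(BDMLParseError, match="extFile"):
            parse_bdml(b"<bdml version='3.0'><info><title>x</title></info></bdml>")

    def test_unknown_elements_warned_and_skipped(self):
        xml = MINIMAL.replace(b"<data>", b"<data><mystery>1</mystery>")
        with pytest.warns(UserWarning, match="mystery"):
            doc = parse_bdml(xml)
        assert len(doc.components) == 1

    def test_multiple_contacts_with_orcid(self):
        meta = BDMLMeta(title="T", summary="S", methods="M", contacts=[
            Contact(name="A Researcher", orcid="0000-0002-1825-0097"),
            Contact(name="B Researcher"),
        ])
        with pytest.warns(UserWarning, match="does not exist"):
            payload = write_bdml_meta(meta, "a.bd5")
        back = parse_bdml(payload)
        assert back.meta.contacts == meta.contacts
        assert back.ext_file == "a.bd5"

    def test_emit_parse_round_trip_random(self, rng, tmp_path):
        for i in range(10):
            doc = random_document(rng, max_groups=4)
            bdml, _ = bd5_to_bdml(doc, meta=BDMLMeta(title=f"fixture {i}"))
            path = tmp_path / f"r{i}.bdml"
            write_bdml(bdml, path)
            back = parse_bdml(str(path))
            assert back == bdml


class TestBdmlToBd5:
    def test_prev_id_becomes_track_edge(self):
        xml = MINIMAL.replace(b"</data>", b"""
    <component>
      <componentID>c2</componentID>
      <time>1.0</time>
      <prevID>c1</prevID>
      <measurement><objectRef>0</objectRef><point><x>1.0</x><y>2.0</y></point></measurement>
    </component>
  </data>""")
        doc, report = bdml_to_bd5(parse_bdml(xml))
        assert len(doc.time_groups) == 2
        assert [(e.src, e.dst) for e in doc.track_info] == [("c1", "c2")]
        assert validate_document(doc) == []
        assert report.dropped_edges == []

    def test_no_prev_ids_empty_track_info(self):
        doc, _ = bdml_to_bd5(parse_bdml(MINIMAL))
        assert doc.track_info == []

    def test_unknown_prev_id_dropped_and_reported(self):
        xml = MINIMAL.replace(b"<time>0.0</time>", b"<time>0.0</time><prevID>ghost</prevID>")
        doc, report = bdml_to_bd5(parse_bdml(xml))
        assert doc.track_info == []
        assert [(e.src, e.dst) for e in report.dropped_edges] == [("ghost", "c1")]

    def test_planted_division_survives_conversion(self):
        """Two components sharing one prevID become one two-daughter division."""
        xml = MINIMAL.replace(b"</data>", b"""
    <component>
      <componentID>d1</componentID>
      <time>1.0</time>
      <prevID>c1</prevID>
      <measurement><objectRef>0</objectRef><point><x>1.0</x><y>2.0</y></point></measurement>
    </component>
    <component>
      <componentID>d2</componentID>
      <time>1.0</time>
      <prevID>c1</prevID>
      <measurement><objectRef>0</objectRef><point><x>2.0</x><y>2.0</y></point></measurement>
    </component>
  </data>""")
        doc, _ = bdml_to_bd5(parse_bdml(xml))
        divisions = find_divisions(build_track_graph(doc))
        assert len(divisions) == 1 and len(divisions[0][1]) == 2


class TestBd5ToBdml:
    def test_division_only_round_trip_exact(self, rng):
        for i in range(10):
            doc = random_document(rng, max_groups=5)
            bdml, report = bd5_to_bdml(doc)
            back, _ = bdml_to_bd5(bdml)
            assert back.scale_unit == doc.scale_unit
            assert back.object_defs == doc.object_defs
            assert back.feature_defs == doc.feature_defs
            assert back.time_groups == doc.time_groups
            assert sorted((e.src, e.dst) for e in back.track_info) == \
                   sorted((e.src, e.dst) for e in doc.track_info)

    def test_defs_only_document_has_no_components(self, scale_2d):
        from bd5tools import BD5Document, ObjectDef
        doc = BD5Document(scale_unit=scale_2d,
                          object_defs=[ObjectDef(oID=0, name="cell", entity="point")])
        bdml, _ = bd5_to_bdml(doc)
        assert bdml.components == [] and bdml.object_defs == doc.object_defs

    def test_fusion_flagged_as_multi_parent(self):
        from bd5tools import BD5Document, ObjectDef, ScaleUnit, SpatialRecord, TimeGroup, TrackEdge
        su = ScaleUnit(dimension="2D+T", x_scale=1, y_scale=1, t_scale=1, t_unit="minute")
        g0 = TimeGroup(index=0, t=0.0, objects={0: [
            SpatialRecord(ID="a", t=0.0, x=0.0, y=0.0),
            SpatialRecord(ID="b", t=0.0, x=1.0, y=0.0)]})
        g1 = TimeGroup(index=1, t=1.0, objects={0: [
            SpatialRecord(ID="c", t=1.0, x=0.5, y=0.0)]})
        doc = BD5Document(su, [ObjectDef(oID=0, name="cell", entity="point")], [],
                          [g0, g1], [TrackEdge("a", "c"), TrackEdge("b", "c")])
        bdml, report = bd5_to_bdml(doc)
        assert report.multi_parent_components == 1
        back, _ = bdml_to_bd5(bdml)  # multiple prevID children still round-trip
        assert sorted((e.src, e.dst) for e in back.track_info) == [("a", "c"), ("b", "c")]

    def test_numeric_fidelity(self, rng):
        """Coordinates survive BD5 -> BDML text -> BD5 with <= 1e-12 relative error."""
        doc = random_document(rng, max_groups=6)
        bdml, _ = bd5_to_bdml(doc)
        back, _ = bdml_to_bd5(parse_bdml(write_bdml(bdml)))
        worst = 0.0
        for g, g2 in zip(doc.time_groups, back.time_groups):
            for oid in g.objects:
                for r, r2 in zip(g.objects[oid], g2.objects[oid]):
                    for a, b in ((r.x, r2.x), (r.y, r2.y)):
                        if a != 0:
                            worst = max(worst, abs(a - b) / abs(a))
        assert worst <= 1e-12


class TestMetaSkeleton:
    def test_bd5_file_pointer(self, tmp_path):
        with pytest.warns(UserWarning, match="does not exist"):
            payload = write_bdml_meta(BDMLMeta(title="x"), "a.bd5")
        assert b"<bd5File>a.bd5</bd5File>" in payload

    def test_orcid_serialized_on_contact(self):
        with pytest.warns(UserWarning, match="does not exist"):
            payload = write_bdml_meta(
                BDMLMeta(contacts=[Contact(name="N", orcid="0000-0001-2345-6789")]), "d.bd5")
        assert b"<orcid>0000-0001-2345-6789</orcid>" in payload
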