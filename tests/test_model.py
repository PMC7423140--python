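"""Document model: time-group assignment, validation, physical units."""

import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from bd5tools import (
    BD5Document,
    FeatureDef,
    FeatureRecord,
    ObjectDef,
    ScaleUnit,
    SpatialRecord,
    TimeGroup,
    TrackEdge,
    assign_time_groups,
    resolve_physical,
    validate_document,
)
from bd5tools.errors import DimensionMismatchError


def _points(times):
    return [SpatialRecord(ID=f"p{i}", t=float(t), x=float(i), y=0.0)
            for i, t in enumerate(times)]


class TestAssignTimeGroups:
    def test_irregular_interval_example(self):
        """Times {0, 2, 7} land in groups 0, 1, 2 in time order."""
        groups = assign_time_groups(_points([0, 2, 7]))
        assert [(g.index, g.t) for g in groups] == [(0, 0.0), (1, 2.0), (2, 7.0)]

    def test_single_time_point(self):
        groups = assign_time_groups(_points([5]))
        assert len(groups) == 1 and groups[0].index == 0 and groups[0].t == 5.0

    def test_shuffled_times_share_groups(self):
        groups = assign_time_groups(_points([3, 1, 3, 2]))
        assert [g.t for g in groups] == [1.0, 2.0, 3.0]
        assert [r.ID for r in groups[2].objects[0]] == ["p0", "p2"]

    @settings(derandomize=True, max_examples=50)
    @given(st.permutations(list(range(8))))
    def test_permutation_invariance(self, order):
        records = _points([0, 0, 1, 3, 3, 3, 7, 9])
        base = assign_time_groups(records)
        shuffled = assign_time_groups([records[i] for i in order])
        for a, b in zip(base, shuffled):
            assert (a.index, a.t) == (b.index, b.t)
            assert sorted(r.ID for r in a.objects[0]) == sorted(r.ID for r in b.objects[0])

    def test_non_finite_time_rejected(self):
        with pytest.raises(ValueError, match="p1"):
            assign_time_groups(_points([0, float("nan")]))

    def test_per_record_oids(self):
        groups = assign_time_groups(_points([0, 0]), oids=[0, 1])
        assert set(groups[0].objects) == {0, 1}


class TestScaleUnit:
    def test_z_scale_tied_to_dimension(self):
        with pytest.raises(ValueError):
            ScaleUnit(dimension="2D+T", x_scale=1, y_scale=1, z_scale=1,
                      t_scale=1, t_unit="minute")

    def test_non_positive_scale_rejected(self):
        with pytest.raises(ValueError):
            ScaleUnit(dimension="2D", x_scale=0.0, y_scale=1.0)


class TestValidateDocument:
    def test_well_formed_document_is_clean(self, mixed_document):
        assert validate_document(mixed_document) == []

    @pytest.mark.parametrize("defect,rule", [
        ("unknown_oid", "unknown-oid"),
        ("unknown_fid", "unknown-fid"),
        ("gap_sid", "sid-run"),
        ("same_time_edge", "edge-order"),
        ("duplicate_point_id", "duplicate-id"),
    ])
    def test_single_defect_yields_single_matching_violation(self, mixed_document, defect, rule):
        doc = mixed_document
        if defect == "unknown_oid":
            doc.time_groups[1].objects[7] = [
                SpatialRecord(ID="x", t=1.0, x=0.0, y=0.0, z=0.0)]
        elif defect == "unknown_fid":
            doc.time_groups[0].features[0].append(FeatureRecord(ID="a0", fID=9, value=1.0))
        elif defect == "gap_sid":
            rows = doc.time_groups[0].objects[1]
            doc.time_groups[0].objects[1] = [
                dataclasses.replace(r, sID=r.sID if r.sID < 2 else 5) for r in rows]
        elif defect == "same_time_edge":
            doc.track_info.append(TrackEdge(src="a0", dst="f0"))
        elif defect == "duplicate_point_id":
            doc.time_groups[0].objects[0].append(
                dataclasses.replace(doc.time_groups[0].objects[0][0], x=9.0))
        violations = validate_document(doc)
        assert len(violations) == 1
        assert violations[0].rule == rule

    def test_dangling_edge_names_missing_id(self, mixed_document):
        mixed_document.track_info.append(TrackEdge(src="ghost", dst="a1"))
        violations = validate_document(mixed_document)
        assert [v.rule for v in violations] == ["dangling-edge"]
        assert violations[0].key == "ghost"


class TestResolvePhysical:
    def test_two_minute_interval(self):
        """Stored t=1 under tScale=2 is 2 physical minutes."""
        su = ScaleUnit(dimension="2D+T", x_scale=1, y_scale=1,
                       t_scale=2.0, t_unit="minute")
        p = resolve_physical(SpatialRecord(ID="a", t=1.0, x=0.0, y=0.0), su)
        assert p.t == 2.0 and p.t_unit == "minute"

    def test_identity_scaling(self):
        su = ScaleUnit(dimension="3D+T", x_scale=1, y_scale=1, z_scale=1,
                       t_scale=1, t_unit="s")
        r = SpatialRecord(ID="a", t=3.0, x=1.0, y=2.0, z=4.0)
        p = resolve_physical(r, su)
        assert (p.x, p.y, p.z, p.t) == (1.0, 2.0, 4.0, 3.0)

    def test_componentwise_multiplication(self):
        su = ScaleUnit(dimension="2D", x_scale=0.5, y_scale=2.0)
        p = resolve_physical(SpatialRecord(ID="a", t=0.0, x=3.0, y=3.0), su)
        assert (p.x, p.y) == (1.5, 6.0)

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_linearity_in_scale_factors(self, c):
        su1 = ScaleUnit(dimension="2D", x_scale=0.7, y_scale=1.3)
        su2 = ScaleUnit(dimension="2D", x_scale=0.7 * c, y_scale=1.3 * c)
        r = SpatialRecord(ID="a", t=0.0, x=3.0, y=5.0)
        p1, p2 = resolve_physical(r, su1), resolve_physical(r, su2)
        assert p2.x == pytest.approx(p1.x * c) and p2.y == pytest.approx(p1.y * c)

    def test_dimension_mismatch(self):
        su = ScaleUnit(dimension="2D", x_scale=1, y_scale=1)
        with pytest.raises(DimensionMismatchError):
            resolve_physical(SpatialRecord(ID="a", t=0.0, x=0.0, y=0.0, z=1.0), su)
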