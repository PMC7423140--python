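"""HDF5 persistence: layout, round trips, random access, numeric ordering."""

import h5py
import numpy as np
import pytest

from bd5tools import (
    BD5Document,
    BD5File,
    ObjectDef,
    ScaleUnit,
    SpatialRecord,
    TimeGroup,
    read_bd5,
    write_bd5,
)
from bd5tools.errors import StructureError, ValidationFailedError
from bd5tools.synthcell import random_document


def _sphere_doc(times, ids=None):
    su = ScaleUnit(dimension="3D+T", x_scale=1.0, y_scale=1.0, z_scale=1.0,
                   s_unit="micrometer", t_scale=1.0, t_unit="minute")
    groups = []
    for k, t in enumerate(times):
        g = TimeGroup(index=k, t=float(t))
        ID = (ids or [f"c{k}" for k in range(len(times))])[k]
        g.objects[0] = [SpatialRecord(ID=ID, t=float(t), x=1.0, y=2.0, z=3.0, radius=0.5)]
        groups.append(g)
    return BD5Document(
        scale_unit=su,
        object_defs=[ObjectDef(oID=0, name="nucleus", entity="sphere")],
        time_groups=groups,
    )


class TestLayout:
    def test_numbered_groups_and_required_datasets(self, tmp_path, mixed_document):
        path = tmp_path / "doc.bd5"
        write_bd5(mixed_document, path).close()
        with h5py.File(path) as f:
            assert {"scaleUnit", "objectDef", "featureDef", "trackInfo", "0", "1"} <= set(f["data"])
            # one numbered dataset per object class at each time point
            assert set(f["data/0/object"]) == {"0", "1"}
            assert f["data/0/object/0"].attrs["entity"] in (b"sphere", "sphere")

    def test_empty_track_info_is_omitted(self, tmp_path):
        path = tmp_path / "doc.bd5"
        write_bd5(_sphere_doc([0, 1]), path).close()
        with h5py.File(path) as f:
            assert "trackInfo" not in f["data"]
        from bd5tools.lint import lint
        assert lint(path).passed

    def test_invalid_document_refused(self, tmp_path, mixed_document):
        mixed_document.time_groups[0].objects[9] = mixed_document.time_groups[0].objects[0]
        with pytest.raises(ValidationFailedError):
            write_bd5(mixed_document, tmp_path / "bad.bd5")

    def test_writes_are_byte_reproducible(self, tmp_path, mixed_document):
        a, b = tmp_path / "a.bd5", tmp_path / "b.bd5"
        write_bd5(mixed_document, a).close()
        write_bd5(mixed_document, b).close()
        assert a.read_bytes() == b.read_bytes()


class TestRoundTrip:
    def test_mixed_document(self, tmp_path, mixed_document):
        path = tmp_path / "doc.bd5"
        write_bd5(mixed_document, path).close()
        assert read_bd5(path) == mixed_document

    def test_fuzzed_documents(self, tmp_path, rng):
        for i in range(25):
            doc = random_document(rng)
            path = tmp_path / f"r{i}.bd5"
            write_bd5(doc, path).close()
            assert read_bd5(path) == doc

    def test_missing_scale_unit_reported_by_path(self, tmp_path, mixed_document):
        path = tmp_path / "doc.bd5"
        write_bd5(mixed_document, path).close()
        with h5py.File(path, "r+") as f:
            del f["data/scaleUnit"]
        with pytest.raises(StructureError, match="data/scaleUnit"):
            read_bd5(path)

    def test_reads_file_from_independent_writer(self, tmp_path):
        """A file assembled with raw h5py calls (variable-length strings)
        reads back as the expected document."""
        path = tmp_path / "foreign.bd5"
        vs = h5py.string_dtype(encoding="utf-8")
        with h5py.File(path, "w") as f:
            data = f.create_group("data")
            su = np.zeros(1, dtype=[("dimension", vs), ("xScale", "f8"), ("yScale", "f8"),
                                    ("zScale", "f8"), ("sUnit", vs), ("tScale", "f8"),
                                    ("tUnit", vs)])
            su[0] = ("2D+T", 0.8, 0.8, np.nan, "micrometer", 5.0, "second")
            data.create_dataset("scaleUnit", data=su)
            od = np.zeros(1, dtype=[("oID", "i8"), ("name", vs), ("entity", vs)])
            od[0] = (0, "cell", "circle")
            data.create_dataset("objectDef", data=od)
            data.create_dataset("featureDef", data=np.zeros(0, dtype=[("fID", "i8"), ("name", vs)]))
            rows = np.zeros(1, dtype=[("ID", vs), ("t", "f8"), ("x", "f8"), ("y", "f8"),
                                      ("radius", "f8")])
            rows[0] = ("c1", 0.0, 4.0, 5.0, 1.25)
            ds = data.create_dataset("0/object/0", data=rows)
            ds.attrs["entity"] = "circle"
        doc = read_bd5(path)
        assert doc.scale_unit == ScaleUnit(dimension="2D+T", x_scale=0.8, y_scale=0.8,
                                           s_unit="micrometer", t_scale=5.0, t_unit="second")
        assert doc.object_defs == [ObjectDef(oID=0, name="cell", entity="circle")]
        (rec,) = doc.time_groups[0].objects[0]
        assert rec == SpatialRecord(ID="c1", t=0.0, x=4.0, y=5.0, radius=1.25)


class TestRandomAccess:
    def test_list_times_irregular(self, tmp_path):
        path = tmp_path / "irr.bd5"
        write_bd5(_sphere_doc([0, 2, 7]), path).close()
        with BD5File(path) as h:
            assert h.list_times() == [(0, 0.0), (1, 2.0), (2, 7.0)]

    def test_numeric_not_lexicographic_ordering(self, tmp_path):
        times = list(range(11))  # group "10" must follow "9", not "1"
        path = tmp_path / "eleven.bd5"
        write_bd5(_sphere_doc(times), path).close()
        with BD5File(path) as h:
            assert [k for k, _ in h.list_times()] == times
            assert [t for _, t in h.list_times()] == [float(t) for t in times]

    def test_read_time_group_matches_full_read(self, tmp_path, rng):
        doc = random_document(rng, max_groups=10)
        path = tmp_path / "ra.bd5"
        write_bd5(doc, path).close()
        full = read_bd5(path)
        with BD5File(path) as h:
            for k in range(h.n_groups):
                assert h.read_time_group(k) == full.time_groups[k]

    def test_out_of_range_index(self, tmp_path):
        path = tmp_path / "ten.bd5"
        write_bd5(_sphere_doc(list(range(10))), path).close()
        with BD5File(path) as h, pytest.raises(IndexError, match="0..9"):
            h.read_time_group(10)

    def test_single_group_file(self, tmp_path):
        doc = _sphere_doc([4])
        path = tmp_path / "one.bd5"
        write_bd5(doc, path).close()
        with BD5File(path) as h:
            assert h.read_time_group(0) == doc.time_groups[0]
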