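"""Single-defect mutations of valid BD5 files, for linter completeness tests.

Each injector takes the path of a freshly written valid file and corrupts
exactly one thing; DEFECT_CATALOGUE maps injector name -> (mutation
function, expected lint check class).  Mutations operate through raw h5py
calls, independent of the writer under test.
"""

import h5py
import numpy as np


def _replace_dataset(f, path, arr, attrs=None):
    old_attrs = dict(f[path].attrs)
    del f[path]
    ds = f.create_dataset(path, data=arr)
    for k, v in (attrs if attrs is not None else old_attrs).items():
        ds.attrs[k] = v


def _retype_column(f, path, column, new_dtype):
    ds = f[path]
    arr = ds[()]
    fields = [(n, new_dtype if n == column else arr.dtype[n]) for n in arr.dtype.names]
    out = np.zeros(arr.shape, dtype=fields)
    for n in arr.dtype.names:
        out[n] = arr[n].astype(fields[[x[0] for x in fields].index(n)][1])
    _replace_dataset(f, path, out)


def drop_scale_unit(path):
    with h5py.File(path, "r+") as f:
        del f["data/scaleUnit"]


def drop_object_def(path):
    with h5py.File(path, "r+") as f:
        del f["data/objectDef"]


def drop_feature_def(path):
    with h5py.File(path, "r+") as f:
        del f["data/featureDef"]


def unregistered_oid_dataset(path):
    with h5py.File(path, "r+") as f:
        obj = f["data/0/object"]
        src = obj["0"]
        ds = obj.create_dataset("9", data=src[()])
        for k, v in src.attrs.items():
            ds.attrs[k] = v


def unregistered_fid(path):
    with h5py.File(path, "r+") as f:
        ds = f["data/0/feature/0"]
        arr = ds[()]
        arr["fID"][0] = 99
        _replace_dataset(f, "data/0/feature/0", arr)


def z_in_2d_file(path):
    # declare the file 2D while its records keep finite z values
    with h5py.File(path, "r+") as f:
        su = f["data/scaleUnit"][()]
        su["dimension"][0] = b"2D+T"
        su["zScale"][0] = np.nan
        _replace_dataset(f, "data/scaleUnit", su)


def nan_z_in_3d_file(path):
    with h5py.File(path, "r+") as f:
        arr = f["data/0/object/0"][()]
        arr["z"][0] = np.nan
        _replace_dataset(f, "data/0/object/0", arr)


def integer_x_column(path):
    with h5py.File(path, "r+") as f:
        _retype_column(f, "data/0/object/0", "x", np.dtype("<i8"))


def bad_entity_attribute(path):
    with h5py.File(path, "r+") as f:
        f["data/0/object/0"].attrs["entity"] = "blob"


def broken_sid_run(path):
    with h5py.File(path, "r+") as f:
        arr = f["data/0/object/1"][()]  # the face dataset
        arr["sID"][-1] = arr["sID"][-1] + 5
        _replace_dataset(f, "data/0/object/1", arr)


def missing_object_subgroup(path):
    with h5py.File(path, "r+") as f:
        del f["data/1/object"]


DEFECT_CATALOGUE = {
    "drop_scale_unit": (drop_scale_unit, "structure"),
    "drop_object_def": (drop_object_def, "structure"),
    "drop_feature_def": (drop_feature_def, "structure"),
    "unregistered_oid_dataset": (unregistered_oid_dataset, "reference"),
    "unregistered_fid": (unregistered_fid, "reference"),
    "z_in_2d_file": (z_in_2d_file, "dimension"),
    "nan_z_in_3d_file": (nan_z_in_3d_file, "dimension"),
    "integer_x_column": (integer_x_column, "type"),
    "bad_entity_attribute": (bad_entity_attribute, "type"),
    "broken_sid_run": (broken_sid_run, "type"),
}
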