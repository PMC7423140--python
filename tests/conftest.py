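import numpy as np
import pytest

from bd5tools import (
    BD5Document,
    FeatureDef,
    FeatureRecord,
    ObjectDef,
    ScaleUnit,
    TimeGroup,
    TrackEdge,
    make_entity,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240812)


@pytest.fixture
def scale_3d():
    return ScaleUnit(dimension="3D+T", x_scale=0.5, y_scale=0.5, z_scale=2.0,
                     s_unit="micrometer", t_scale=2.0, t_unit="minute")


@pytest.fixture
def scale_2d():
    return ScaleUnit(dimension="2D+T", x_scale=1.0, y_scale=1.0,
                     s_unit="micrometer", t_scale=1.0, t_unit="minute")


def build_mixed_document() -> BD5Document:
    """Deterministic two-time-point document with a sphere and a face class,
    sparse features and one continuation edge; passes validation."""
    su = ScaleUnit(dimension="3D+T", x_scale=1.0, y_scale=1.0, z_scale=1.0,
                   s_unit="micrometer", t_scale=2.0, t_unit="minute")
    g0 = TimeGroup(index=0, t=0.0)
    g0.objects[0] = make_entity("sphere", "a0", 0.0, [(1.0, 2.0, 3.0)], radius=1.5)
    g0.objects[1] = make_entity("face", "f0", 0.0,
                                [(0.0, 0.0, 0.0), (1.0, 0.0, 0.0), (0.0, 1.0, 0.0)])
    g0.features[0] = [FeatureRecord(ID="a0", fID=0, value=10.0)]
    g1 = TimeGroup(index=1, t=1.0)
    g1.objects[0] = make_entity("sphere", "a1", 1.0, [(1.5, 2.5, 3.5)], radius=1.5,
                                label="nucleus one")
    g1.objects[1] = make_entity("face", "f1", 1.0,
                                [(0.0, 0.0, 1.0), (1.0, 0.0, 1.0), (1.0, 1.0, 1.0),
                                 (0.0, 1.0, 1.0)])
    return BD5Document(
        scale_unit=su,
        object_defs=[ObjectDef(oID=0, name="nucleus", entity="sphere"),
                     ObjectDef(oID=1, name="membrane patch", entity="face")],
        feature_defs=[FeatureDef(fID=0, name="total GFP signal"),
                      FeatureDef(fID=1, name="average GFP signal")],
        time_groups=[g0, g1],
        track_info=[TrackEdge(src="a0", dst="a1")],
    )


@pytest.fixture
def mixed_document():
    return build_mixed_document()
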