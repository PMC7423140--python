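"""Synthetic tracked-cell data and the BD5-vs-BDML benchmark harness.

:func:`simulate` runs a minimal branching/coalescing random walk: spheres
("cells") diffuse in a box, divide with a per-object per-step probability
and fuse with a per-pair per-step probability.  Every object instance gets
a fresh ID at every time step and trackInfo edges carry identity, so the
emitted document exercises continuation, division and fusion links exactly
as the format stores them, with a ground-truth event log to check trackers
against.  The dynamics make no claim of biophysical realism — they exist
to exercise the format, the track graph, the converter and the benchmarks.

:func:`random_document` is a structural fuzzer producing documents over
all five entity kinds for round-trip and linter testing.

:func:`benchmark` compares the serialized size and access cost of the same
documents in BD5 and BDML form.  Access time means: one time group read
through an open BD5 handle versus a whole-file BDML parse — the usage
pattern each format affords.  Absolute times are hardware-dependent; only
ratios are meaningful.
"""

from __future__ import annotations

import math
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .bdml import bd5_to_bdml, parse_bdml, write_bdml
from .geometry import make_entity
from .model import (
    BD5Document,
    FeatureDef,
    FeatureRecord,
    ObjectDef,
    ScaleUnit,
    SpatialRecord,
    TimeGroup,
    TrackEdge,
)
from .store import BD5File, write_bd5

__all__ = ["SimConfig", "Event", "GroundTruth", "simulate", "random_document", "benchmark"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the branching/coalescing random walk.

    Lengths are in coordinate units (micrometers at unit scale), time in
    steps (one stored t unit per step).  ``rng`` names the generator
    algorithm so that emitted fixtures stay stable across releases.
    """

    n0: int = 10                #: initial object count
    T: int = 20                 #: number of time points
    p_div: float = 0.02         #: per-object per-step division probability
    p_fuse: float = 0.005       #: per-pair per-step fusion probability
    motion_sigma: float = 0.5   #: per-step coordinate jitter (micrometer)
    radius0: float = 5.0        #: initial sphere radius (micrometer)
    box: float = 100.0          #: side of the cubic arena (micrometer)
    with_features: bool = True  #: record volume (fID 0) per object per step
    seed: int = 0               #: RNG seed
    rng: str = "numpy-PCG64"    #: RNG algorithm, fixed and versioned

    def __post_init__(self):
        if self.n0 < 1 or self.T < 1:
            raise ValueError("n0 and T must be at least 1")
        for p in ("p_div", "p_fuse"):
            if not 0.0 <= getattr(self, p) <= 1.0:
                raise ValueError(f"{p} must lie in [0, 1]")
        if self.rng != "numpy-PCG64":
            raise ValueError(f"unsupported rng {self.rng!r}")


@dataclass(frozen=True)
class Event:
    """One division or fusion, logged at the step the children appear."""

    step: int
    kind: str  # "division" | "fusion"
    parents: tuple[str, ...]
    children: tuple[str, ...]


@dataclass
class GroundTruth:
    """Event log and full trajectory table of one simulation."""

    events: list[Event] = field(default_factory=list)
    trajectory: pd.DataFrame | None = None

    def by_kind(self, kind: str) -> list[Event]:
        return [e for e in self.events if e.kind == kind]


_VOLUME = lambda r: 4.0 / 3.0 * math.pi * r ** 3


def simulate(config: SimConfig) -> tuple[BD5Document, GroundTruth]:
    """Run the simulation and emit a 3D+T sphere document plus ground truth.

    Deterministic given the config (including seed): identical configs give
    identical documents, and writing them yields byte-identical BD5 files.
    Population bookkeeping per step: each division nets +1 object, each
    fusion nets -1.
    """
    rng = np.random.default_rng(config.seed)
    serial = 0

    def fresh() -> str:
        nonlocal serial
        serial += 1
        return str(serial - 1)

    # state: per live object (ID, position (3,), radius)
    positions = rng.uniform(0.0, config.box, size=(config.n0, 3))
    radii = np.full(config.n0, config.radius0)
    ids = [fresh() for _ in range(config.n0)]

    groups: list[TimeGroup] = []
    edges: list[TrackEdge] = []
    truth = GroundTruth()
    traj_rows = []

    for step in range(config.T):
        g = TimeGroup(index=step, t=float(step))
        recs = [
            SpatialRecord(ID=ids[i], t=float(step),
                          x=float(positions[i, 0]), y=float(positions[i, 1]),
                          z=float(positions[i, 2]), radius=float(radii[i]))
            for i in range(len(ids))
        ]
        g.objects[0] = recs
        if config.with_features:
            g.features[0] = [
                FeatureRecord(ID=ids[i], fID=0, value=_VOLUME(float(radii[i])))
                for i in range(len(ids))
            ]
        groups.append(g)
        for i in range(len(ids)):
            traj_rows.append((ids[i], step, *positions[i], radii[i]))

        if step == config.T - 1:
            break

        n = len(ids)
        divides = rng.random(n) < config.p_div
        n_pairs = math.comb(n, 2)
        n_fusions = int(rng.binomial(n_pairs, config.p_fuse)) if n_pairs else 0
        survivors = [i for i in range(n) if not divides[i]]
        n_fusions = min(n_fusions, len(survivors) // 2)
        fuse_idx = rng.permutation(len(survivors))[: 2 * n_fusions]
        fuse_pairs = [(survivors[fuse_idx[2 * j]], survivors[fuse_idx[2 * j + 1]])
                      for j in range(n_fusions)]
        fused = {i for pair in fuse_pairs for i in pair}

        new_ids, new_pos, new_rad = [], [], []

        def advance(pos):
            out = pos + rng.normal(0.0, config.motion_sigma, size=3) if config.motion_sigma else pos.copy()
            return np.clip(out, 0.0, config.box)

        for i in range(n):
            if divides[i]:
                offset = rng.normal(0.0, max(config.motion_sigma, 1e-3), size=3)
                r_child = radii[i] / 2.0 ** (1.0 / 3.0)  # conserve total volume
                children = []
                for sign in (+1.0, -1.0):
                    cid = fresh()
                    children.append(cid)
                    new_ids.append(cid)
                    new_pos.append(np.clip(positions[i] + sign * offset, 0.0, config.box))
                    new_rad.append(r_child)
                    edges.append(TrackEdge(src=ids[i], dst=cid))
                truth.events.append(Event(step=step + 1, kind="division",
                                          parents=(ids[i],), children=tuple(children)))
            elif i not in fused:
                cid = fresh()
                new_ids.append(cid)
                new_pos.append(advance(positions[i]))
                new_rad.append(float(radii[i]))
                edges.append(TrackEdge(src=ids[i], dst=cid))
        for a, b in fuse_pairs:
            cid = fresh()
            new_ids.append(cid)
            new_pos.append(advance((positions[a] + positions[b]) / 2.0))
            new_rad.append((radii[a] ** 3 + radii[b] ** 3) ** (1.0 / 3.0))
            edges.append(TrackEdge(src=ids[a], dst=cid))
            edges.append(TrackEdge(src=ids[b], dst=cid))
            truth.events.append(Event(step=step + 1, kind="fusion",
                                      parents=(ids[a], ids[b]), children=(cid,)))

        ids = new_ids
        positions = np.asarray(new_pos).reshape(len(new_ids), 3)
        radii = np.asarray(new_rad)

    doc = BD5Document(
        scale_unit=ScaleUnit(dimension="3D+T", x_scale=1.0, y_scale=1.0, z_scale=1.0,
                             s_unit="micrometer", t_scale=1.0, t_unit="minute"),
        object_defs=[ObjectDef(oID=0, name="cell", entity="sphere")],
        feature_defs=[FeatureDef(fID=0, name="volume")] if config.with_features else [],
        time_groups=groups,
        track_info=edges,
    )
    truth.trajectory = pd.DataFrame(traj_rows, columns=["ID", "step", "x", "y", "z", "radius"])
    return doc, truth


def random_document(
    rng: np.random.Generator,
    max_groups: int = 8,
    kinds: tuple[str, ...] | None = None,
    with_features: bool = True,
    with_tracks: bool = True,
) -> BD5Document:
    """Structural fuzzer: a valid document with random entity content.

    Covers all five entity kinds (one object class per kind), 2D or 3D,
    regular or irregular time spacing, sparse features and continuation
    track edges.  Every document it returns passes validation.
    """
    all_kinds = ("point", "circle", "line", "sphere", "face")
    if kinds is None:
        count = int(rng.integers(1, len(all_kinds) + 1))
        kinds = tuple(str(k) for k in rng.choice(all_kinds, size=count, replace=False))
    three_d = bool(rng.random() < 0.5)
    n_groups = int(rng.integers(1, max_groups + 1))
    times = np.cumsum(rng.uniform(0.5, 3.0, size=n_groups))

    su = ScaleUnit(
        dimension="3D+T" if three_d else "2D+T",
        x_scale=float(rng.uniform(0.1, 2.0)),
        y_scale=float(rng.uniform(0.1, 2.0)),
        z_scale=float(rng.uniform(0.1, 2.0)) if three_d else None,
        s_unit="micrometer", t_scale=float(rng.uniform(0.5, 5.0)), t_unit="minute",
    )
    object_defs = [ObjectDef(oID=i, name=f"{k}-class", entity=k) for i, k in enumerate(kinds)]
    feature_defs = [FeatureDef(fID=0, name="total GFP signal"),
                    FeatureDef(fID=1, name="average GFP signal")] if with_features else []

    def vertex():
        v = rng.uniform(0.0, 50.0, size=3 if three_d else 2)
        return tuple(float(c) for c in v)

    groups = []
    edges = []
    prev_ids: list[str] = []
    for g_idx in range(n_groups):
        g = TimeGroup(index=g_idx, t=float(times[g_idx]))
        group_ids = []
        for oid, kind in enumerate(kinds):
            n_entities = int(rng.integers(1, 5))
            recs = []
            frecs = []
            for j in range(n_entities):
                ID = f"g{g_idx}k{oid}e{j}"
                group_ids.append(ID)
                n_vertices = {"line": int(rng.integers(2, 7)),
                              "face": int(rng.integers(3, 7))}.get(kind, 1)
                radius = float(rng.uniform(0.5, 5.0)) if kind in ("circle", "sphere") else None
                label = f"obj{j}" if rng.random() < 0.3 else None
                recs += make_entity(kind, ID, float(times[g_idx]),
                                    [vertex() for _ in range(n_vertices)],
                                    radius=radius, label=label)
                if with_features and rng.random() < 0.5:  # features are sparse
                    frecs.append(FeatureRecord(ID=ID, fID=int(rng.integers(0, 2)),
                                               value=float(rng.uniform(0.0, 1000.0))))
            g.objects[oid] = recs
            if frecs:
                g.features[oid] = frecs
        groups.append(g)
        if with_tracks and prev_ids:
            for dst in group_ids:
                if rng.random() < 0.5:
                    src = prev_ids[int(rng.integers(0, len(prev_ids)))]
                    edges.append(TrackEdge(src=src, dst=dst))
        prev_ids = group_ids

    return BD5Document(scale_unit=su, object_defs=object_defs,
                       feature_defs=feature_defs, time_groups=groups, track_info=edges)


def _time_group_access(path, indices, repeats: int) -> float:
    """Median wall time of one time-group read through an open handle."""
    samples = []
    with BD5File(path) as h:
        h.read_time_group(indices[0])  # warm up file cache / metadata
        for k in indices[:repeats]:
            t0 = time.perf_counter()
            h.read_time_group(k)
            samples.append(time.perf_counter() - t0)
    return float(np.median(samples))


def _full_parse_time(path, repeats: int) -> float:
    samples = []
    for _ in range(repeats):
        t0 = time.perf_counter()
        parse_bdml(str(path))
        samples.append(time.perf_counter() - t0)
    return float(np.median(samples))


def benchmark(
    configs: list[SimConfig],
    workdir,
    access_repeats: int = 15,
    parse_repeats: int = 3,
) -> pd.DataFrame:
    """Serialize each config's document both ways and measure size and access.

    Returns one row per config: record count, serialized bytes of each
    format, percent size reduction 100*(1 - BD5/BDML), the median
    single-time-group BD5 access time, and the median whole-file BDML parse
    time.  Time columns are hardware-dependent; compare them across rows,
    not across machines.
    """
    os.makedirs(workdir, exist_ok=True)
    rows = []
    for i, cfg in enumerate(configs):
        doc, _ = simulate(cfg)
        n_records = sum(len(r) for g in doc.time_groups for r in g.objects.values())
        bd5_path = os.path.join(workdir, f"bench{i}.bd5")
        bdml_path = os.path.join(workdir, f"bench{i}.bdml")
        write_bd5(doc, bd5_path).close()
        bdml, _ = bd5_to_bdml(doc)
        write_bdml(bdml, bdml_path)

        rng = np.random.default_rng(cfg.seed + 1)
        indices = rng.integers(0, len(doc.time_groups), size=max(access_repeats, 1)).tolist()
        rows.append({
            "n0": cfg.n0, "T": cfg.T, "records": n_records,
            "bdml_bytes": os.path.getsize(bdml_path),
            "bd5_bytes": os.path.getsize(bd5_path),
            "reduction_pct": 100.0 * (1.0 - os.path.getsize(bd5_path) / os.path.getsize(bdml_path)),
            "bd5_access_s": _time_group_access(bd5_path, indices, access_repeats),
            "bdml_parse_s": _full_parse_time(bdml_path, parse_repeats),
        })
    return pd.DataFrame(rows)


def config_dict(config: SimConfig) -> dict:
    """Config as a flat key-value mapping (for provenance output)."""
    return asdict(config)
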