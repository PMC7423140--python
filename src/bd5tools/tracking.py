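"""trackInfo semantics: links, divisions, fusions and lineage traversal.

trackInfo rows carry only two object IDs (from, to) and no time column, so
an endpoint must be resolved to a time group.  An edge's source is resolved
to the *latest* group containing that ID and its target to the *earliest*
(division: one source at t feeds two targets at t+1; fusion: the mirror
image).  When an ID occurs in several groups the resolution is flagged as
ambiguous on the graph — unambiguous data gives every object instance a
fresh ID per time point and expresses persistence through edges.

Nodes of the graph are (time-group index, ID) pairs.  Edges may span
non-adjacent groups (gap tracking); only strict forward time ordering is
enforced.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

from .errors import DanglingEdgeError, TrackError
from .model import BD5Document, TrackEdge

__all__ = ["Node", "TrackGraph", "build_track_graph", "find_divisions", "find_fusions", "lineage"]

#: A graph node: (time-group index, object ID).
Node = tuple[int, str]


@dataclass
class TrackGraph:
    """Directed graph over (time group, ID) nodes built from trackInfo."""

    edges: list[tuple[Node, Node]] = field(default_factory=list)
    out_edges: dict[Node, list[Node]] = field(default_factory=dict)
    in_edges: dict[Node, list[Node]] = field(default_factory=dict)
    ambiguous: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> list[Node]:
        seen = dict.fromkeys(self.out_edges)
        seen.update(dict.fromkeys(self.in_edges))
        return list(seen)

    def add(self, src: Node, dst: Node) -> None:
        self.edges.append((src, dst))
        self.out_edges.setdefault(src, []).append(dst)
        self.in_edges.setdefault(dst, []).append(src)
        self.out_edges.setdefault(dst, self.out_edges.get(dst, []))
        self.in_edges.setdefault(src, self.in_edges.get(src, []))


def build_track_graph(doc: BD5Document) -> TrackGraph:
    """Resolve every trackInfo edge against the document's time groups.

    Raises :class:`DanglingEdgeError` for an edge naming an ID with no
    spatial record, and :class:`TrackError` if a resolved edge does not move
    forward in time.  IDs occurring at several time points are resolved by
    the latest-source / earliest-target rule and noted in ``ambiguous``.
    """
    occurrences: dict[str, list[int]] = {}
    for g in doc.time_groups:
        for recs in g.objects.values():
            for r in recs:
                at = occurrences.setdefault(r.ID, [])
                if not at or at[-1] != g.index:
                    at.append(g.index)
    t_of = {g.index: g.t for g in doc.time_groups}

    graph = TrackGraph()
    flagged = set()
    for e in doc.track_info:
        for ID in (e.src, e.dst):
            if ID not in occurrences:
                raise DanglingEdgeError(
                    f"trackInfo edge {e.src!r}->{e.dst!r} names ID {ID!r} "
                    f"with no spatial record in any time group")
            if len(occurrences[ID]) > 1 and ID not in flagged:
                flagged.add(ID)
                graph.ambiguous.append(ID)
        src: Node = (occurrences[e.src][-1], e.src)
        dst: Node = (occurrences[e.dst][0], e.dst)
        if src == dst:
            raise TrackError(f"trackInfo edge {e.src!r}->{e.dst!r} resolves to a self-loop")
        if not (t_of[src[0]] < t_of[dst[0]]):
            raise TrackError(
                f"trackInfo edge {e.src!r}->{e.dst!r} does not move forward in time "
                f"(t_from={t_of[src[0]]}, t_to={t_of[dst[0]]})")
        graph.add(src, dst)
    return graph


def find_divisions(graph: TrackGraph) -> list[tuple[Node, list[Node]]]:
    """Nodes with out-degree >= 2, children in stored edge order."""
    return [
        (node, children)
        for node, children in graph.out_edges.items()
        if len(children) >= 2
    ]


def find_fusions(graph: TrackGraph) -> list[tuple[Node, list[Node]]]:
    """Nodes with in-degree >= 2 (the child first, then its parents)."""
    return [
        (node, parents)
        for node, parents in graph.in_edges.items()
        if len(parents) >= 2
    ]


def lineage(graph: TrackGraph, node: Node, direction: str = "forward") -> dict[Node, Node | None]:
    """Breadth-first reachable set from ``node`` with parent pointers.

    Returns a mapping from each reachable node to its BFS predecessor (the
    start node maps to None).  ``direction`` is "forward" (descendants) or
    "backward" (ancestors).  A cycle — impossible under correct time
    ordering, hence a sign of corrupt input — raises :class:`TrackError`.
    """
    if direction not in ("forward", "backward"):
        raise ValueError(f"direction must be 'forward' or 'backward', got {direction!r}")
    if node not in graph.out_edges and node not in graph.in_edges:
        raise KeyError(f"node {node!r} not in track graph")
    step = graph.out_edges if direction == "forward" else graph.in_edges

    # Cycle check: iterative DFS with colors over the reachable subgraph.
    WHITE, GRAY, BLACK = 0, 1, 2
    color: dict[Node, int] = {}
    stack = [(node, iter(step.get(node, [])))]
    color[node] = GRAY
    while stack:
        current, it = stack[-1]
        advanced = False
        for nxt in it:
            c = color.get(nxt, WHITE)
            if c == GRAY:
                raise TrackError(f"cycle detected through {nxt!r}; trackInfo is corrupt")
            if c == WHITE:
                color[nxt] = GRAY
                stack.append((nxt, iter(step.get(nxt, []))))
                advanced = True
                break
        if not advanced:
            color[current] = BLACK
            stack.pop()

    parents: dict[Node, Node | None] = {node: None}
    queue = deque([node])
    while queue:
        current = queue.popleft()
        for nxt in step.get(current, []):
            if nxt not in parents:
                parents[nxt] = current
                queue.append(nxt)
    return parents
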