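"""Vessel-network data model and CAM morphometrics.

The quantities measured on the chorioallantoic membrane (CAM) are computed on a
planar *vessel graph*: nodes are 2-D points (µm), edges are vessel centreline
polylines with a Euclidean length.  After canonicalization (degree-2 nodes
merged away) each edge is a *segment* — a maximal vessel stretch between
branch points and/or free ends — and the morphometric parameters are

* junction count: nodes of graph degree >= 3,
* total / mean vessel length (µm),
* vessel density: total vessel length per ROI area (µm/mm²),
* branch hierarchy: generation order 1–4 from designated feeder (root)
  segments, and the ratio (3rd + 4th) / (1st + 2nd) degree counts.

Vessel density has no universal definition in the CAM literature; length per
unit area is the morphometric convention adopted here and is recorded in the
output metadata of the scoring pipeline.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter, deque
from dataclasses import dataclass, field, replace
from typing import Any, Hashable, Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    DisconnectedNetworkWarning,
    GraphValidationError,
    InvalidROIError,
)

__all__ = [
    "RingROI",
    "Segment",
    "VesselGraph",
    "VesselMetrics",
    "polyline_length",
    "canonicalize",
    "count_junctions",
    "length_metrics",
    "vessel_density",
    "assign_branch_degrees",
    "hierarchy_ratio",
    "compute_metrics",
]

UM2_PER_MM2 = 1.0e6

#: degrees of branching scored on the CAM; finer generations are pooled here
MAX_BRANCH_DEGREE = 4

_LENGTH_RTOL = 1e-6


def polyline_length(points: Sequence[Sequence[float]]) -> float:
    """Euclidean length (µm) of a polyline given as an (k, 2) point sequence."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise GraphValidationError(
            f"polyline must be an (k>=2, 2) point sequence, got shape {pts.shape}"
        )
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


@dataclass(frozen=True)
class RingROI:
    """Annular region of interest delimited on the CAM by a plastic ring.

    Coordinates and radii are µm; ``inner_radius`` may be 0 (a disc).  The
    area is reported in mm² (1 mm² = 10⁶ µm²).
    """

    center: tuple[float, float] = (0.0, 0.0)
    inner_radius: float = 0.0
    outer_radius: float = 3000.0

    def __post_init__(self) -> None:
        if not (self.outer_radius > self.inner_radius >= 0.0):
            raise InvalidROIError(
                f"require outer_radius > inner_radius >= 0, got "
                f"outer={self.outer_radius}, inner={self.inner_radius}"
            )

    @property
    def area_mm2(self) -> float:
        return math.pi * (self.outer_radius**2 - self.inner_radius**2) / UM2_PER_MM2

    def to_dict(self) -> dict[str, Any]:
        return {
            "center": [float(self.center[0]), float(self.center[1])],
            "inner_radius_um": float(self.inner_radius),
            "outer_radius_um": float(self.outer_radius),
            "area_mm2": self.area_mm2,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RingROI":
        return cls(
            center=(float(d["center"][0]), float(d["center"][1])),
            inner_radius=float(d["inner_radius_um"]),
            outer_radius=float(d["outer_radius_um"]),
        )


@dataclass(frozen=True)
class Segment:
    """A vessel edge: polyline from node ``u`` to node ``v`` with length in µm.

    ``points[0]`` is the coordinate of ``u`` and ``points[-1]`` that of ``v``.
    """

    id: int
    u: Hashable
    v: Hashable
    points: tuple[tuple[float, float], ...]
    length: float

    @classmethod
    def make(
        cls,
        id: int,
        u: Hashable,
        v: Hashable,
        points: Sequence[Sequence[float]],
        length: float | None = None,
    ) -> "Segment":
        pts = tuple((float(x), float(y)) for x, y in points)
        true_len = polyline_length(pts)
        if length is None:
            length = true_len
        elif not math.isclose(length, true_len, rel_tol=_LENGTH_RTOL, abs_tol=1e-9):
            raise GraphValidationError(
                f"edge {id}: stored length {length} differs from polyline "
                f"length {true_len} beyond tolerance"
            )
        if length <= 0.0:
            raise GraphValidationError(f"edge {id}: length must be > 0, got {length}")
        return cls(id=int(id), u=u, v=v, points=pts, length=float(length))


@dataclass
class VesselGraph:
    """Planar vessel network: node coordinates (µm), polyline edges, roots.

    ``roots`` designates edge ids of 1st-degree feeder vessels entering the
    region of interest; it may be empty (a fallback applies when branch
    degrees are assigned).  Self-loop edges are not representable; isolated
    vessel loops are outside the data model.
    """

    nodes: dict[Hashable, tuple[float, float]]
    edges: list[Segment] = field(default_factory=list)
    roots: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.nodes = {k: (float(v[0]), float(v[1])) for k, v in self.nodes.items()}
        self.edges = list(self.edges)
        self.roots = tuple(self.roots)

    # -- structure helpers -------------------------------------------------

    def edge_map(self) -> dict[int, Segment]:
        return {e.id: e for e in self.edges}

    def adjacency(self) -> dict[Hashable, list[Segment]]:
        adj: dict[Hashable, list[Segment]] = {n: [] for n in self.nodes}
        for e in self.edges:
            adj[e.u].append(e)
            adj[e.v].append(e)
        return adj

    def degrees(self) -> dict[Hashable, int]:
        deg = {n: 0 for n in self.nodes}
        for e in self.edges:
            deg[e.u] += 1
            deg[e.v] += 1
        return deg

    @property
    def total_length(self) -> float:
        return float(sum(e.length for e in self.edges))

    def validate(self) -> None:
        ids = [e.id for e in self.edges]
        if len(set(ids)) != len(ids):
            raise GraphValidationError("duplicate edge ids")
        id_set = set(ids)
        for r in self.roots:
            if r not in id_set:
                raise GraphValidationError(f"root edge id {r} not present")
        for e in self.edges:
            if e.u not in self.nodes or e.v not in self.nodes:
                raise GraphValidationError(
                    f"edge {e.id}: endpoint missing from node table"
                )
            if e.u == e.v:
                raise GraphValidationError(f"edge {e.id}: self-loops not supported")
            if e.length <= 0:
                raise GraphValidationError(f"edge {e.id}: nonpositive length")
            true_len = polyline_length(e.points)
            if not math.isclose(e.length, true_len, rel_tol=_LENGTH_RTOL, abs_tol=1e-9):
                raise GraphValidationError(
                    f"edge {e.id}: length {e.length} != polyline length {true_len}"
                )
            for node, pt in ((e.u, e.points[0]), (e.v, e.points[-1])):
                nx_, ny_ = self.nodes[node]
                if math.hypot(pt[0] - nx_, pt[1] - ny_) > 1e-6 * max(
                    1.0, abs(nx_), abs(ny_)
                ):
                    raise GraphValidationError(
                        f"edge {e.id}: polyline end does not coincide with node {node}"
                    )


def _merge_polylines(
    p1: tuple[tuple[float, float], ...], p2: tuple[tuple[float, float], ...]
) -> tuple[tuple[float, float], ...]:
    # p1 ends where p2 starts; drop the duplicated shared point
    return p1 + p2[1:]


def _oriented(seg: Segment, start: Hashable) -> tuple[tuple[float, float], ...]:
    return seg.points if seg.u == start else seg.points[::-1]


def canonicalize(graph: VesselGraph) -> VesselGraph:
    """Merge chains through degree-2 nodes so every edge is a maximal segment.

    Conserves total length and junction structure; idempotent.  A degree-2
    node whose two incident edges share both endpoints (a two-edge cycle) is
    left in place, since merging would create a self-loop.
    """
    graph.validate()
    edges = graph.edge_map()
    adj: dict[Hashable, set[int]] = {n: set() for n in graph.nodes}
    for e in graph.edges:
        adj[e.u].add(e.id)
        adj[e.v].add(e.id)

    root_ids = set(graph.roots)
    # nodes of degree exactly two are merge candidates; process deterministically
    work = deque(sorted((n for n in adj if len(adj[n]) == 2), key=repr))
    removed_nodes: set[Hashable] = set()
    while work:
        n = work.popleft()
        if n in removed_nodes or len(adj[n]) != 2:
            continue
        e1_id, e2_id = sorted(adj[n])
        e1, e2 = edges[e1_id], edges[e2_id]
        a = e1.v if e1.u == n else e1.u
        c = e2.v if e2.u == n else e2.u
        if a == c or a == n or c == n:
            continue  # merging would create a self-loop; keep the node
        pts = _merge_polylines(_oriented(e1, a), _oriented(e2, n))
        new_id = min(e1_id, e2_id)
        merged = Segment(
            id=new_id, u=a, v=c, points=pts, length=e1.length + e2.length
        )
        for old in (e1_id, e2_id):
            adj[a].discard(old)
            adj[c].discard(old)
            if old in root_ids:
                root_ids.discard(old)
                root_ids.add(new_id)
        del edges[e1_id], edges[e2_id]
        edges[new_id] = merged
        adj[a].add(new_id)
        adj[c].add(new_id)
        removed_nodes.add(n)
        for m in (a, c):
            if len(adj[m]) == 2:
                work.append(m)

    nodes = {k: v for k, v in graph.nodes.items() if k not in removed_nodes}
    out = VesselGraph(
        nodes=nodes,
        edges=sorted(edges.values(), key=lambda e: e.id),
        roots=tuple(sorted(root_ids)),
    )
    return out


def count_junctions(graph: VesselGraph) -> int:
    """Number of branching points: nodes of graph degree >= 3."""
    return sum(1 for d in graph.degrees().values() if d >= 3)


def length_metrics(graph: VesselGraph) -> tuple[float, int, float]:
    """(total length µm, segment count, mean length µm; mean is NaN if empty)."""
    n = len(graph.edges)
    total = graph.total_length
    mean = total / n if n else float("nan")
    return total, n, mean


def vessel_density(graph: VesselGraph, roi: RingROI) -> float:
    """Total vessel length per ROI area, in µm/mm²."""
    area = roi.area_mm2
    if area <= 0.0:
        raise InvalidROIError("ROI area must be positive")
    return graph.total_length / area


def _fallback_roots(graph: VesselGraph, roi: RingROI | None) -> list[int]:
    """Roots when none are designated: segments touching the ROI outer boundary,
    else the single longest segment."""
    if not graph.edges:
        return []
    if roi is not None:
        cx, cy = roi.center
        hits = []
        for e in graph.edges:
            pts = np.asarray(e.points)
            d = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
            if float(d.max()) >= roi.outer_radius - 1e-6:
                hits.append(e.id)
        if hits:
            return sorted(hits)
    longest = max(graph.edges, key=lambda e: (e.length, -e.id))
    return [longest.id]


def assign_branch_degrees(
    graph: VesselGraph, roi: RingROI | None = None
) -> dict[int, int]:
    """Generation order 1–4 of each segment by breadth-first traversal from roots.

    Root segments are degree 1; each segment takes its predecessor's degree
    plus one, capped at :data:`MAX_BRANCH_DEGREE`.  Ties are broken by
    ascending edge id.  Segments unreachable from every root are flagged with
    :class:`DisconnectedNetworkWarning` and assigned degree 4 (the
    finest-vessel class) so that degree counts still sum to the segment count.
    """
    if not graph.edges:
        return {}
    roots = list(graph.roots) or _fallback_roots(graph, roi)
    edge_map = graph.edge_map()
    adj = graph.adjacency()

    degree: dict[int, int] = {}
    q: deque[int] = deque()
    for r in sorted(set(roots)):
        degree[r] = 1
        q.append(r)
    while q:
        eid = q.popleft()
        seg = edge_map[eid]
        d = degree[eid]
        neighbours: list[int] = []
        for node in (seg.u, seg.v):
            neighbours.extend(e.id for e in adj[node] if e.id != eid)
        for nid in sorted(set(neighbours)):
            if nid not in degree:
                degree[nid] = min(d + 1, MAX_BRANCH_DEGREE)
                q.append(nid)

    missing = [e.id for e in graph.edges if e.id not in degree]
    if missing:
        warnings.warn(
            f"{len(missing)} segment(s) unreachable from roots; assigned degree "
            f"{MAX_BRANCH_DEGREE}",
            DisconnectedNetworkWarning,
            stacklevel=2,
        )
        for eid in missing:
            degree[eid] = MAX_BRANCH_DEGREE
    return degree


def hierarchy_ratio(branch_counts: Sequence[int]) -> float:
    """(n3 + n4) / (n1 + n2); NaN when no 1st/2nd-degree segments exist."""
    n1, n2, n3, n4 = (int(c) for c in branch_counts)
    if min(n1, n2, n3, n4) < 0:
        raise ValueError("branch counts must be nonnegative")
    low = n1 + n2
    if low == 0:
        return float("nan")
    return (n3 + n4) / low


@dataclass(frozen=True)
class VesselMetrics:
    """Per-embryo, per-day measured vessel parameters.

    Undefined quantities (mean length of an empty network, hierarchy ratio
    with no low-degree segments) are NaN.
    """

    junction_count: int
    segment_count: int
    total_length: float
    mean_length: float
    density: float
    branch_counts: tuple[int, int, int, int]
    hierarchy_ratio: float

    def as_row(self) -> dict[str, Any]:
        n1, n2, n3, n4 = self.branch_counts
        return {
            "junctions": self.junction_count,
            "segments": self.segment_count,
            "total_length_um": self.total_length,
            "mean_length_um": self.mean_length,
            "density_um_per_mm2": self.density,
            "n1": n1,
            "n2": n2,
            "n3": n3,
            "n4": n4,
            "hierarchy_ratio": self.hierarchy_ratio,
        }


def compute_metrics(graph: VesselGraph, roi: RingROI) -> VesselMetrics:
    """All CAM morphometric parameters of one vessel network in one ROI."""
    g = canonicalize(graph)
    total, n_seg, mean = length_metrics(g)
    density = vessel_density(g, roi)
    if g.edges:
        deg = assign_branch_degrees(g, roi)
        counts = Counter(deg.values())
        branch_counts = tuple(counts.get(k, 0) for k in (1, 2, 3, 4))
    else:
        branch_counts = (0, 0, 0, 0)
    return VesselMetrics(
        junction_count=count_junctions(g),
        segment_count=n_seg,
        total_length=total,
        mean_length=mean,
        density=density,
        branch_counts=branch_counts,  # type: ignore[arg-type]
        hierarchy_ratio=hierarchy_ratio(branch_counts) if n_seg else float("nan"),
    )
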