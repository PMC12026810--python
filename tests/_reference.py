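"""Independent brute-force oracles used only by the tests.

These deliberately re-derive every quantity by a different route than the
package (chain walking instead of node merging, recursive traversal instead
of the package BFS, explicit O-E sums for the log-rank statistic) so that
agreement is evidence, not tautology.
"""

from __future__ import annotations

import math
from collections import defaultdict, deque

import numpy as np

from angiocam.vesselnet import RingROI, Segment, VesselGraph


# ---------------------------------------------------------------------------
# brute-force morphometrics
# ---------------------------------------------------------------------------


def _adjacency(graph):
    adj = defaultdict(list)
    for e in graph.edges:
        adj[e.u].append(e)
        adj[e.v].append(e)
    return adj


def brute_segments(graph: VesselGraph):
    """Maximal chains between non-degree-2 nodes, found by walking edges.

    Returns a list of dicts with edge-id sets, total length, and the two
    terminal nodes of each chain.
    """
    adj = _adjacency(graph)
    deg = {n: len(adj[n]) for n in graph.nodes}

    def walk(edge, node):
        """Follow the chain from ``edge`` through ``node`` while degree == 2."""
        chain = []
        cur_e, cur_n = edge, node
        while deg[cur_n] == 2:
            nxt = [e for e in adj[cur_n] if e.id != cur_e.id][0]
            chain.append(nxt)
            cur_n = nxt.v if nxt.u == cur_n else nxt.u
            cur_e = nxt
        return chain, cur_n

    visited = set()
    segments = []
    for e in sorted(graph.edges, key=lambda s: s.id):
        if e.id in visited:
            continue
        back, n_back = walk(e, e.u)
        fwd, n_fwd = walk(e, e.v)
        edge_ids = {e.id} | {x.id for x in back} | {x.id for x in fwd}
        visited |= edge_ids
        length = sum(graph.edge_map()[i].length for i in edge_ids)
        segments.append({"edges": edge_ids, "length": length,
                         "ends": (n_back, n_fwd)})
    return segments


def brute_branch_degrees(graph: VesselGraph, segments, roots):
    """Generation order by an explicit frontier expansion over brute segments."""
    seg_of_edge = {}
    for i, s in enumerate(segments):
        for eid in s["edges"]:
            seg_of_edge[eid] = i
    node_segs = defaultdict(set)
    for i, s in enumerate(segments):
        for n in s["ends"]:
            node_segs[n].add(i)
    degree = {}
    frontier = sorted({seg_of_edge[r] for r in roots})
    for i in frontier:
        degree[i] = 1
    gen = 1
    while frontier:
        gen += 1
        nxt = set()
        for i in frontier:
            for n in segments[i]["ends"]:
                for j in node_segs[n]:
                    if j not in degree:
                        degree[j] = min(gen, 4)
                        nxt.add(j)
        frontier = sorted(nxt)
    for i in range(len(segments)):
        if i not in degree:
            degree[i] = 4
    return degree


def brute_metrics(graph: VesselGraph, roi: RingROI):
    """All morphometrics by naive iteration; same output keys as VesselMetrics."""
    deg = {n: 0 for n in graph.nodes}
    for e in graph.edges:
        deg[e.u] += 1
        deg[e.v] += 1
    junctions = sum(1 for d in deg.values() if d >= 3)
    segments = brute_segments(graph)
    total = sum(s["length"] for s in segments)
    n_seg = len(segments)
    mean = total / n_seg if n_seg else float("nan")
    density = total / roi.area_mm2
    if n_seg and graph.roots:
        degs = brute_branch_degrees(graph, segments, graph.roots)
        counts = [0, 0, 0, 0]
        for d in degs.values():
            counts[d - 1] += 1
    else:
        counts = [0, 0, 0, 0]
    low = counts[0] + counts[1]
    ratio = (counts[2] + counts[3]) / low if low else float("nan")
    return {
        "junction_count": junctions,
        "segment_count": n_seg,
        "total_length": total,
        "mean_length": mean,
        "density": density,
        "branch_counts": tuple(counts),
        "hierarchy_ratio": ratio,
    }


# ---------------------------------------------------------------------------
# random test graphs (built differently from the package generator)
# ---------------------------------------------------------------------------


def random_vessel_tree(
    rng: np.random.Generator,
    n_branch_events: int = 8,
    n_roots: int = 2,
    bounding: float = 5000.0,
) -> VesselGraph:
    """Random rooted tree with 3-point polyline edges and random tip selection."""
    nodes = {}
    edges = []
    next_node = [0]
    next_edge = [0]

    def add_node(x, y):
        nid = next_node[0]
        nodes[nid] = (float(x), float(y))
        next_node[0] += 1
        return nid

    def add_edge(u, v):
        (x0, y0), (x1, y1) = nodes[u], nodes[v]
        mx = 0.5 * (x0 + x1) + rng.normal(0, 5.0)
        my = 0.5 * (y0 + y1) + rng.normal(0, 5.0)
        pts = ((x0, y0), (mx, my), (x1, y1))
        eid = next_edge[0]
        edges.append(Segment.make(id=eid, u=u, v=v, points=pts))
        next_edge[0] += 1
        return eid

    tips = []  # (node, direction)
    roots = []
    for i in range(n_roots):
        theta = 2 * math.pi * i / n_roots + rng.uniform(0, 0.3)
        a = add_node(bounding * math.cos(theta), bounding * math.sin(theta))
        length = rng.uniform(100, 400)
        d = theta + math.pi
        b = add_node(nodes[a][0] + length * math.cos(d),
                     nodes[a][1] + length * math.sin(d))
        roots.append(add_edge(a, b))
        tips.append((b, d))
    for _ in range(n_branch_events):
        node, d = tips.pop(int(rng.integers(len(tips))))
        for sign in (+1, -1):
            dd = d + sign * rng.uniform(0.2, 0.9)
            length = rng.uniform(50, 300)
            end = add_node(nodes[node][0] + length * math.cos(dd),
                           nodes[node][1] + length * math.sin(dd))
            add_edge(node, end)
            tips.append((end, dd))
    g = VesselGraph(nodes=nodes, edges=edges, roots=tuple(roots))
    g.validate()
    return g


def insert_degree2_nodes(graph: VesselGraph, rng: np.random.Generator,
                         k: int) -> VesselGraph:
    """Split k random non-root edges at an interior polyline vertex.

    Leaves every morphometric quantity unchanged (only the representation
    gains degree-2 nodes).
    """
    nodes = dict(graph.nodes)
    edges = {e.id: e for e in graph.edges}
    next_node = max(nodes) + 1
    next_edge = max(edges) + 1
    candidates = [e.id for e in graph.edges
                  if e.id not in graph.roots and len(e.points) >= 3]
    rng.shuffle(candidates)
    for eid in candidates[:k]:
        e = edges.pop(eid)
        split = len(e.points) // 2
        mid = e.points[split]
        nid = next_node
        nodes[nid] = mid
        next_node += 1
        edges[eid] = Segment.make(id=eid, u=e.u, v=nid,
                                  points=e.points[: split + 1])
        edges[next_edge] = Segment.make(id=next_edge, u=nid, v=e.v,
                                        points=e.points[split:])
        next_edge += 1
    g = VesselGraph(nodes=nodes, edges=sorted(edges.values(), key=lambda s: s.id),
                    roots=graph.roots)
    g.validate()
    return g


# ---------------------------------------------------------------------------
# survival oracles
# ---------------------------------------------------------------------------


def hand_km(times, events):
    """Product-limit table computed directly from its definition."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out = {}
    s = 1.0
    for t in sorted(set(times[events == 1])):
        at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d / at_risk
        out[float(t)] = s
    return out


def hand_km_at(times, events, day):
    s = 1.0
    for t, v in sorted(hand_km(times, events).items()):
        if t <= day:
            s = v
    return s


def hand_logrank(times_a, events_a, times_b, events_b):
    """Mantel-Cox chi-square by the explicit O-E / hypergeometric-variance sum."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    death_times = sorted(set(ta[ea == 1]) | set(tb[eb == 1]))
    o_minus_e = 0.0
    var = 0.0
    for t in death_times:
        n1 = int(np.sum(ta >= t))
        n2 = int(np.sum(tb >= t))
        d1 = int(np.sum((ta == t) & (ea == 1)))
        d2 = int(np.sum((tb == t) & (eb == 1)))
        n = n1 + n2
        d = d1 + d2
        if n < 2:
            continue
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1) if n > 1 else 0.0
    if var == 0.0:
        return 0.0
    return o_minus_e**2 / var
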