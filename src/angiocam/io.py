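"""Readers and writers for the pipeline's file formats.

Formats
-------
* Vessel graphs: a documented JSON schema (``angiocam-graph/1``) and GraphML
  (via networkx).  Both round-trip losslessly: node coordinates, polyline
  edges with µm lengths, designated root edges, and the ring ROI.
* Cohort tables: RFC-4180 CSV with a header row, UTF-8.
  - metrics: embryo_id, group, day, junctions, segments, total_length_um,
    mean_length_um, density_um_per_mm2, n1..n4, hierarchy_ratio
  - survival: embryo_id, group, last_day_alive, status (1 = died, 0 = alive)
  - thickness: embryo_id, group, thickness_um
* Results: profile CSV (group, parameter, day, ar, sd, n, aai) and a
  versioned JSON report holding the AAI profile, exclusions and the design
  metadata.  Floating-point output is serialized at 6 significant digits;
  internal computation keeps full precision.
"""

from __future__ import annotations

import json
import math
import warnings
from pathlib import Path
from typing import Any, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .errors import SchemaError
from .scoring import AAIProfile, CohortDataset
from .vesselnet import RingROI, Segment, VesselGraph

__all__ = [
    "GRAPH_SCHEMA",
    "REPORT_SCHEMA",
    "graph_to_dict",
    "graph_from_dict",
    "write_graph_json",
    "read_graph_json",
    "write_graph_graphml",
    "read_graph_graphml",
    "write_metrics_csv",
    "read_metrics_csv",
    "write_survival_csv",
    "read_survival_csv",
    "write_thickness_csv",
    "read_thickness_csv",
    "read_cohort",
    "write_cohort",
    "write_profile_csv",
    "profile_report_dict",
    "write_profile_report",
    "round_sig",
]

GRAPH_SCHEMA = "angiocam-graph/1"
REPORT_SCHEMA = "angiocam-report/1"

METRICS_COLUMNS = [
    "embryo_id",
    "group",
    "day",
    "junctions",
    "segments",
    "total_length_um",
    "mean_length_um",
    "density_um_per_mm2",
    "n1",
    "n2",
    "n3",
    "n4",
    "hierarchy_ratio",
]
SURVIVAL_COLUMNS = ["embryo_id", "group", "last_day_alive", "status"]
THICKNESS_COLUMNS = ["embryo_id", "group", "thickness_um"]


def round_sig(x: float, digits: int = 6) -> float:
    """Round to ``digits`` significant digits (NaN/inf pass through)."""
    if not math.isfinite(x) or x == 0.0:
        return float(x)
    return float(f"{x:.{digits}g}")


# ---------------------------------------------------------------------------
# vessel graphs
# ---------------------------------------------------------------------------


def graph_to_dict(graph: VesselGraph, roi: RingROI | None = None) -> dict[str, Any]:
    d: dict[str, Any] = {
        "schema": GRAPH_SCHEMA,
        "nodes": {str(k): [v[0], v[1]] for k, v in graph.nodes.items()},
        "edges": [
            {
                "id": e.id,
                "source": str(e.u),
                "target": str(e.v),
                "points": [[p[0], p[1]] for p in e.points],
                "length_um": e.length,
            }
            for e in graph.edges
        ],
        "roots": list(graph.roots),
    }
    if roi is not None:
        d["roi"] = roi.to_dict()
    return d


def graph_from_dict(d: Mapping[str, Any]) -> tuple[VesselGraph, RingROI | None]:
    if d.get("schema") != GRAPH_SCHEMA:
        raise SchemaError(
            f"unexpected graph schema {d.get('schema')!r}; expected {GRAPH_SCHEMA!r}"
        )
    nodes = {k: (float(v[0]), float(v[1])) for k, v in d["nodes"].items()}
    edges = [
        Segment.make(
            id=int(e["id"]),
            u=str(e["source"]),
            v=str(e["target"]),
            points=e["points"],
            length=float(e["length_um"]) if "length_um" in e else None,
        )
        for e in d["edges"]
    ]
    roi = RingROI.from_dict(d["roi"]) if "roi" in d else None
    graph = VesselGraph(nodes=nodes, edges=edges, roots=tuple(d.get("roots", ())))
    graph.validate()
    return graph, roi


def write_graph_json(path: str | Path, graph: VesselGraph,
                     roi: RingROI | None = None) -> None:
    Path(path).write_text(json.dumps(graph_to_dict(graph, roi)), encoding="utf-8")


def read_graph_json(path: str | Path) -> tuple[VesselGraph, RingROI | None]:
    text = Path(path).read_text(encoding="utf-8")
    if not text.strip():
        raise SchemaError(f"{path}: empty input file")
    return graph_from_dict(json.loads(text))


def _points_to_str(points: tuple[tuple[float, float], ...]) -> str:
    return ";".join(f"{x!r},{y!r}" for x, y in points)


def _points_from_str(s: str) -> list[tuple[float, float]]:
    pts = []
    for chunk in s.split(";"):
        x, y = chunk.split(",")
        pts.append((float(x), float(y)))
    return pts


def write_graph_graphml(path: str | Path, graph: VesselGraph,
                        roi: RingROI | None = None) -> None:
    g = nx.MultiGraph()
    g.graph["schema"] = GRAPH_SCHEMA
    g.graph["roots"] = ",".join(str(r) for r in graph.roots)
    if roi is not None:
        g.graph["roi_center_x"] = repr(roi.center[0])
        g.graph["roi_center_y"] = repr(roi.center[1])
        g.graph["roi_inner_um"] = repr(roi.inner_radius)
        g.graph["roi_outer_um"] = repr(roi.outer_radius)
    for node, (x, y) in graph.nodes.items():
        g.add_node(str(node), x=repr(x), y=repr(y))
    for e in graph.edges:
        g.add_edge(
            str(e.u),
            str(e.v),
            key=e.id,
            eid=e.id,
            length_um=repr(e.length),
            points=_points_to_str(e.points),
        )
    nx.write_graphml(g, str(path))


def read_graph_graphml(path: str | Path) -> tuple[VesselGraph, RingROI | None]:
    g = nx.read_graphml(str(path), force_multigraph=True)
    nodes = {n: (float(d["x"]), float(d["y"])) for n, d in g.nodes(data=True)}
    edges = []
    for u, v, data in g.edges(data=True):
        pts = _points_from_str(data["points"])
        eid = int(data["eid"])
        # orient the polyline from u to v
        if pts[0] != nodes[u]:
            pts = pts[::-1]
        edges.append(
            Segment.make(id=eid, u=u, v=v, points=pts,
                         length=float(data["length_um"]))
        )
    edges.sort(key=lambda e: e.id)
    roots_attr = g.graph.get("roots", "")
    roots = tuple(int(r) for r in roots_attr.split(",") if r != "")
    roi = None
    if "roi_outer_um" in g.graph:
        roi = RingROI(
            center=(float(g.graph["roi_center_x"]), float(g.graph["roi_center_y"])),
            inner_radius=float(g.graph["roi_inner_um"]),
            outer_radius=float(g.graph["roi_outer_um"]),
        )
    graph = VesselGraph(nodes=nodes, edges=edges, roots=roots)
    graph.validate()
    return graph, roi


# ---------------------------------------------------------------------------
# cohort CSV tables
# ---------------------------------------------------------------------------


def _read_csv_checked(path: str | Path, required: list[str]) -> pd.DataFrame:
    p = Path(path)
    if not p.exists() or p.stat().st_size == 0:
        raise SchemaError(f"{path}: empty or missing input file")
    df = pd.read_csv(p)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{path}: ignoring unknown columns {extra}", stacklevel=2)
    return df[required]


def write_metrics_csv(path: str | Path, metrics: pd.DataFrame) -> None:
    out = metrics[METRICS_COLUMNS].copy()
    for c in ("total_length_um", "mean_length_um", "density_um_per_mm2",
              "hierarchy_ratio"):
        out[c] = out[c].map(round_sig)
    out.to_csv(path, index=False)


def read_metrics_csv(path: str | Path) -> pd.DataFrame:
    df = _read_csv_checked(path, METRICS_COLUMNS)
    df["day"] = df["day"].astype(int)
    # fail early, naming the embryo, when the day-0 baseline is absent
    for eid, sub in df.groupby("embryo_id"):
        if 0 not in set(sub["day"]):
            raise SchemaError(f"{path}: embryo {eid!r} has no day-0 row")
    return df


def write_survival_csv(path: str | Path, survival: pd.DataFrame) -> None:
    out = survival.copy()
    died = out["event"].astype(int) == 1
    out["last_day_alive"] = np.where(died, out["time"] - 1, out["time"])
    out["status"] = out["event"].astype(int)
    out[SURVIVAL_COLUMNS].to_csv(path, index=False)


def read_survival_csv(path: str | Path) -> pd.DataFrame:
    df = _read_csv_checked(path, SURVIVAL_COLUMNS)
    died = df["status"].astype(int) == 1
    df["time"] = np.where(died, df["last_day_alive"] + 1, df["last_day_alive"])
    df["event"] = df["status"].astype(int)
    return df[["embryo_id", "group", "time", "event"]]


def write_thickness_csv(path: str | Path, thickness: pd.DataFrame) -> None:
    out = thickness[THICKNESS_COLUMNS].copy()
    out["thickness_um"] = out["thickness_um"].map(round_sig)
    out.to_csv(path, index=False)


def read_thickness_csv(path: str | Path) -> pd.DataFrame:
    return _read_csv_checked(path, THICKNESS_COLUMNS)


def write_cohort(
    out_dir: str | Path, cohort: CohortDataset, prefix: str = "cohort"
) -> dict[str, Path]:
    """Write the three cohort tables; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "metrics": out / f"{prefix}_metrics.csv",
        "survival": out / f"{prefix}_survival.csv",
        "thickness": out / f"{prefix}_thickness.csv",
    }
    write_metrics_csv(paths["metrics"], cohort.metrics)
    write_survival_csv(paths["survival"], cohort.survival)
    write_thickness_csv(paths["thickness"], cohort.thickness)
    return paths


def read_cohort(
    metrics_path: str | Path,
    survival_path: str | Path,
    thickness_path: str | Path,
    control_group: str = "control",
) -> CohortDataset:
    cohort = CohortDataset(
        metrics=read_metrics_csv(metrics_path),
        survival=read_survival_csv(survival_path),
        thickness=read_thickness_csv(thickness_path),
        control_group=control_group,
    )
    cohort.validate()
    return cohort


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


def write_profile_csv(path: str | Path, profile: AAIProfile) -> None:
    table = profile.table.copy() if profile.table is not None else pd.DataFrame()
    for c in ("ar", "sd", "aai"):
        if c in table.columns:
            table[c] = table[c].map(round_sig)
    table.to_csv(path, index=False)


def _jsonify(x: Any) -> Any:
    if isinstance(x, float):
        return None if not math.isfinite(x) else round_sig(x)
    if isinstance(x, (np.floating,)):
        return _jsonify(float(x))
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, dict):
        return {str(k): _jsonify(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonify(v) for v in x]
    return x


def profile_report_dict(profile: AAIProfile) -> dict[str, Any]:
    return _jsonify(
        {
            "schema": REPORT_SCHEMA,
            "treatment_group": profile.treatment_group,
            "headline_day": profile.day,
            "per_parameter_aai": profile.indices,
            "n_parameters": profile.n,
            "final_aai": profile.final_aai,
            "excluded": [
                {"parameter": p, "reason": r} for p, r in profile.excluded
            ],
            "metadata": profile.metadata,
        }
    )


def write_profile_report(path: str | Path, profile: AAIProfile) -> None:
    Path(path).write_text(
        json.dumps(profile_report_dict(profile), indent=2), encoding="utf-8"
    )
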