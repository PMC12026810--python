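"""End-to-end orchestration: ingest a cohort, score it, write the report bundle.

Two ingestion modes exist because CAM measurements are often tabulated by
hand: ``graphs`` starts from per-embryo vessel-network files (JSON or
GraphML, located through an index CSV) and measures them; ``metrics`` starts
from an already-tabulated per-embryo metrics CSV.  Both converge on the same
:class:`~angiocam.scoring.CohortDataset` and produce identical scores for
equivalent inputs.

Outputs per run: the metrics table, one profile CSV and one JSON report per
treatment group, a survival summary (Kaplan–Meier values and pairwise
Mantel–Cox log-rank tests), and a plain-text log of every measurement
convention applied.  Logging goes to standard error; results go to files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd

from . import io as aio
from .errors import SchemaError
from .scoring import (
    AAI_PARAMETERS,
    AAIProfile,
    CohortDataset,
    build_angiogenic_profile,
    km_estimator,
    logrank_test,
)
from .vesselnet import RingROI, compute_metrics

__all__ = ["RunConfig", "RunResult", "load_cohort", "run"]

logger = logging.getLogger("angiocam")


@dataclass(frozen=True)
class RunConfig:
    """One scoring run.

    ``mode`` is ``"metrics"`` (pre-tabulated metrics CSV) or ``"graphs"``
    (index CSV with columns embryo_id, group, day, path pointing at graph
    files).  ``survival`` and ``thickness`` CSVs are required in both modes.
    """

    mode: str
    metrics_or_index: str | Path
    survival: str | Path
    thickness: str | Path
    out_dir: str | Path
    control_group: str = "control"
    day: int = 7
    parameters: tuple[str, ...] = AAI_PARAMETERS
    roi: RingROI | None = None
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("metrics", "graphs"):
            raise ValueError(f"mode must be 'metrics' or 'graphs', got {self.mode!r}")
        if not self.parameters:
            raise ValueError("the AAI parameter set must be non-empty")


@dataclass
class RunResult:
    cohort: CohortDataset
    profiles: dict[str, AAIProfile]
    outputs: dict[str, Path] = field(default_factory=dict)


def _read_graph_any(path: Path):
    if path.suffix.lower() == ".graphml":
        return aio.read_graph_graphml(path)
    return aio.read_graph_json(path)


def _cohort_from_graphs(config: RunConfig) -> CohortDataset:
    index = aio._read_csv_checked(
        config.metrics_or_index, ["embryo_id", "group", "day", "path"]
    )
    base = Path(config.metrics_or_index).parent
    rows: list[dict[str, Any]] = []
    for _, r in index.iterrows():
        gpath = Path(r["path"])
        if not gpath.is_absolute():
            gpath = base / gpath
        graph, roi = _read_graph_any(gpath)
        roi = roi or config.roi
        if roi is None:
            raise SchemaError(
                f"{gpath}: no ROI stored in the graph file and none configured"
            )
        metrics = compute_metrics(graph, roi)
        row = {
            "embryo_id": r["embryo_id"],
            "group": r["group"],
            "day": int(r["day"]),
        }
        row.update(metrics.as_row())
        rows.append(row)
    return CohortDataset(
        metrics=pd.DataFrame(rows),
        survival=aio.read_survival_csv(config.survival),
        thickness=aio.read_thickness_csv(config.thickness),
        control_group=config.control_group,
    )


def load_cohort(config: RunConfig) -> CohortDataset:
    if config.mode == "graphs":
        cohort = _cohort_from_graphs(config)
    else:
        cohort = aio.read_cohort(
            config.metrics_or_index,
            config.survival,
            config.thickness,
            control_group=config.control_group,
        )
    cohort.validate()
    return cohort


def _survival_summary(cohort: CohortDataset) -> pd.DataFrame:
    rows = []
    curves = {}
    for group in cohort.groups:
        sub = cohort.survival[cohort.survival["group"] == group]
        curves[group] = km_estimator(sub["time"].to_numpy(), sub["event"].to_numpy())
        for t, r, s in zip(*[getattr(curves[group], f) for f in
                             ("times", "at_risk", "survival")]):
            rows.append(
                {"kind": "km", "group": group, "vs": "", "time": t,
                 "at_risk": r, "value": s}
            )
    groups = cohort.groups
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            sa = cohort.survival[cohort.survival["group"] == a]
            sb = cohort.survival[cohort.survival["group"] == b]
            stat, p = logrank_test(
                sa["time"].to_numpy(), sa["event"].to_numpy(),
                sb["time"].to_numpy(), sb["event"].to_numpy(),
            )
            rows.append(
                {"kind": "logrank", "group": a, "vs": b, "time": float("nan"),
                 "at_risk": 0, "value": stat, "p_value": p}
            )
    return pd.DataFrame(rows)


def run(config: RunConfig) -> RunResult:
    """Execute one scoring run and write the report bundle to ``out_dir``."""
    if config.verbose:
        logging.basicConfig(level=logging.INFO)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = load_cohort(config)
    logger.info(
        "cohort loaded: %d metric rows, groups %s", len(cohort.metrics), cohort.groups
    )

    outputs: dict[str, Path] = {}
    outputs["metrics"] = out / "metrics.csv"
    aio.write_metrics_csv(outputs["metrics"], cohort.metrics)

    profiles: dict[str, AAIProfile] = {}
    decision_lines: list[str] = []
    for group in cohort.treatment_groups:
        profile = build_angiogenic_profile(
            cohort, group, day=config.day, parameters=config.parameters
        )
        profiles[group] = profile
        slug = group.replace("/", "_")
        p_csv = out / f"profile_{slug}.csv"
        p_json = out / f"aai_{slug}.json"
        aio.write_profile_csv(p_csv, profile)
        aio.write_profile_report(p_json, profile)
        outputs[f"profile_{group}"] = p_csv
        outputs[f"aai_{group}"] = p_json
        for param, reason in profile.excluded:
            logger.warning("group %s: parameter %s excluded (%s)", group, param, reason)
            decision_lines.append(f"excluded: group={group} parameter={param}: {reason}")
        logger.info("group %s: final AAI %.4f", group, profile.final_aai)

    outputs["survival_summary"] = out / "survival_summary.csv"
    _survival_summary(cohort).to_csv(outputs["survival_summary"], index=False)

    meta = next(iter(profiles.values())).metadata if profiles else {}
    lines = ["# measurement conventions applied by this run"]
    lines += [f"{k}: {v}" for k, v in meta.items()]
    lines += decision_lines
    outputs["decisions_log"] = out / "decisions.log"
    outputs["decisions_log"].write_text("\n".join(lines) + "\n", encoding="utf-8")

    return RunResult(cohort=cohort, profiles=profiles, outputs=outputs)
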