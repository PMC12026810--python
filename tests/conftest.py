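import math

import numpy as np
import pandas as pd
import pytest

from angiocam import (
    RingROI,
    Segment,
    VesselGraph,
    CohortDataset,
    default_config,
    simulate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_roi():
    """Disc ROI with area exactly 1 mm² (radius sqrt(1e6/pi) µm)."""
    return RingROI(center=(0.0, 0.0), inner_radius=0.0,
                   outer_radius=math.sqrt(1.0e6 / math.pi))


def straight(eid, u, v, nodes):
    return Segment.make(id=eid, u=u, v=v, points=(nodes[u], nodes[v]))


@pytest.fixture
def y_graph():
    """Root segment of 100 µm splitting into two 50 µm children."""
    nodes = {
        "a": (0.0, 0.0),
        "b": (100.0, 0.0),
        "c": (100.0 + 50.0 / math.sqrt(2), 50.0 / math.sqrt(2)),
        "d": (100.0 + 50.0 / math.sqrt(2), -50.0 / math.sqrt(2)),
    }
    edges = [
        straight(0, "a", "b", nodes),
        straight(1, "b", "c", nodes),
        straight(2, "b", "d", nodes),
    ]
    return VesselGraph(nodes=nodes, edges=edges, roots=(0,))


@pytest.fixture(scope="session")
def default_cohort():
    """One simulated cohort at the default study design, shared across tests."""
    return simulate_cohort(default_config(seed=0))


def make_cohort(fold_changes_by_group, thickness_by_group=None,
                deaths_by_group=None, final_day=7):
    """Tiny hand-built cohort: per-group dict {embryo: {day: junctions}}.

    All metric columns carry the same per-day value so any fold-change
    parameter can be inspected; branch counts are fixed.
    """
    rows, surv, thick = [], [], []
    deaths_by_group = deaths_by_group or {}
    thickness_by_group = thickness_by_group or {}
    for group, embryos in fold_changes_by_group.items():
        death_map = deaths_by_group.get(group, {})
        for embryo, by_day in embryos.items():
            eid = f"{group}-{embryo}"
            for day, value in by_day.items():
                rows.append(
                    {
                        "embryo_id": eid, "group": group, "day": day,
                        "junctions": value, "segments": 2 * value + 1,
                        "total_length_um": 100.0 * value,
                        "mean_length_um": 100.0 * value / (2 * value + 1),
                        "density_um_per_mm2": 50.0 * value,
                        "n1": 1, "n2": 1, "n3": value, "n4": value,
                        "hierarchy_ratio": value,
                    }
                )
            death = death_map.get(embryo)
            surv.append(
                {"embryo_id": eid, "group": group,
                 "time": death if death is not None else final_day,
                 "event": 1 if death is not None else 0}
            )
            t = thickness_by_group.get(group, {}).get(embryo)
            if t is not None:
                thick.append({"embryo_id": eid, "group": group, "thickness_um": t})
    return CohortDataset(
        metrics=pd.DataFrame(rows),
        survival=pd.DataFrame(surv),
        thickness=pd.DataFrame(thick, columns=["embryo_id", "group", "thickness_um"]),
        control_group="control",
    )
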