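"""Synthetic CAM cohorts, assay tables, and their analytic expectations.

The generator emulates the study design the scoring pipeline assumes: three
groups (one control, two secretome-like treatments), 17 embryos per group,
vessel networks observed on treatment days 0, 2, 4 and 7, embryo dropout,
and a final-day CAM thickness measurement.

Growth model
------------
Each embryo starts from ``n_roots`` feeder vessels entering the ring ROI.
The day-0 network applies a fixed number of *branching events*; every event
takes the oldest active tip (uniform-front growth) and appends two daughter
segments at it, creating one junction.  Between observation days, the number
of new branching events is Poisson with mean ``base_sprout_rate × group
sprout multiplier × elapsed days``; daughter lengths are log-normal, scaled
by ``sprout_length_scale`` and the group's elongation multiplier.  Networks
are nested over time (no pruning).  Day-0 segment lengths are rescaled so
every embryo starts from the same total length, which makes the per-embryo
fold-change expectations exact functions of the rates.

Deaths occur at whole days with a constant daily hazard; thickness is normal
around a group-shifted mean, measured on final-day survivors only.

Default rates are calibrated so the expected day-7 fold changes equal the
study conditions (junctions 1.19 / 2.07 / 2.54; total vessel length
1.09 / 1.36 / 1.42 for control and the two treatments).

Because density divides total length by a fixed ROI area, its fold change
coincides with the total-length fold change; and because uniform-front
growth makes the pooled branch-hierarchy ratio an affine function of the
junction count, the hierarchy index coincides with the junction index.
These are properties of this generator, not claims about real CAMs.

:func:`expected_outcome` returns two flavours of expectation per parameter:
the *plug-in* AAI (the index applied to expected angiogenic responses) and
the *estimator mean* (the expected value of the cohort-level ratio estimator,
via exact Poisson/binomial inverse-moment sums and second-order corrections
for compound sums), which is what repeated simulated cohorts average to.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateControlError
from .scoring import AAI_PARAMETERS, CohortDataset, aai_parameter, thickness_index
from .vesselnet import RingROI, Segment, VesselGraph, compute_metrics

__all__ = [
    "GroupSpec",
    "SimulationConfig",
    "ExpectedOutcome",
    "default_config",
    "simulate_vessel_timecourse",
    "simulate_cohort",
    "clone_control_as_treatment",
    "expected_outcome",
    "branch_degree_counts",
    "ScratchCondition",
    "ScratchSimConfig",
    "simulate_scratch_series",
    "CtSimConfig",
    "simulate_ct_table",
    "config_to_dict",
    "config_from_dict",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """One cohort arm: name, growth multipliers, thickness shift, death hazard."""

    name: str
    sprout_multiplier: float = 1.0
    elongation_multiplier: float = 1.0
    thickness_shift_um: float = 0.0
    daily_death_hazard: float = 0.03

    def __post_init__(self) -> None:
        if self.sprout_multiplier < 0 or self.elongation_multiplier < 0:
            raise ValueError("growth multipliers must be nonnegative")
        if not (0.0 <= self.daily_death_hazard < 1.0):
            raise ValueError("daily death hazard must lie in [0, 1)")


# Calibration of the default arms (day-7 expectations; day 0 -> 7 window):
#   junction fold change  = 1 + rate*7*mult / initial_branch_events
#   length fold change    = 1 + 2*rate*7*mult*elong*scale*mean_len / L0
_D7 = 7.0
_J0 = 12  # day-0 branching events = day-0 junctions
_ROOTS = 3
_LEN_MEAN = 200.0
_L0 = (_ROOTS + 2 * _J0) * _LEN_MEAN  # 27 segments x 200 um = 5400 um
_RATE = 0.19 * _J0 / _D7  # control junction fold change 1.19 at day 7
_SCALE = 0.09 * _L0 / (2.0 * _RATE * _D7 * _LEN_MEAN)  # control length FC 1.09


def _mult_for_junction_fc(fc: float) -> float:
    return (fc - 1.0) / (_RATE * _D7 / _J0)


def _elong_for_length_fc(fc: float, sprout_mult: float) -> float:
    return (fc - 1.0) * _L0 / (2.0 * _RATE * _D7 * sprout_mult * _SCALE * _LEN_MEAN)


_DEFAULT_GROUPS = (
    GroupSpec("control"),
    GroupSpec(
        "adsc-secretome",
        sprout_multiplier=_mult_for_junction_fc(2.07),
        elongation_multiplier=_elong_for_length_fc(1.36, _mult_for_junction_fc(2.07)),
        thickness_shift_um=76.2 - 59.0,
    ),
    GroupSpec(
        "mixed-secretome",
        sprout_multiplier=_mult_for_junction_fc(2.54),
        elongation_multiplier=_elong_for_length_fc(1.42, _mult_for_junction_fc(2.54)),
        thickness_shift_um=80.5 - 59.0,
    ),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic cohort.

    The first group is the control and must have unit multipliers and no
    thickness shift.
    """

    groups: tuple[GroupSpec, ...] = _DEFAULT_GROUPS
    n_embryos: int = 17
    days: tuple[int, ...] = (0, 2, 4, 7)
    n_roots: int = _ROOTS
    initial_branch_events: int = _J0
    base_sprout_rate: float = _RATE  # branching events / embryo / day (control)
    segment_length_mean_um: float = _LEN_MEAN
    segment_length_sd_um: float = 100.0
    initial_total_length_um: float = _L0
    sprout_length_scale: float = _SCALE  # new sprouts are shorter than day-0 vessels
    thickness_mean_um: float = 59.0
    thickness_sd_um: float = 12.0
    roi: RingROI = field(default_factory=RingROI)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group (the control) is required")
        ctrl = self.groups[0]
        if (
            ctrl.sprout_multiplier != 1.0
            or ctrl.elongation_multiplier != 1.0
            or ctrl.thickness_shift_um != 0.0
        ):
            raise ValueError(
                "the first group is the control and must have unit multipliers "
                "and zero thickness shift"
            )
        if len({g.name for g in self.groups}) != len(self.groups):
            raise ValueError("group names must be unique")
        if self.n_embryos < 1:
            raise ValueError("n_embryos must be >= 1")
        if self.days[0] != 0 or list(self.days) != sorted(set(self.days)):
            raise ValueError("observation days must be strictly increasing from 0")
        if self.n_roots < 1 or self.initial_branch_events < 1:
            raise ValueError("need at least one root and one initial branch event")
        if self.base_sprout_rate < 0:
            raise ValueError("base sprout rate must be nonnegative")
        if self.segment_length_mean_um <= 0 or self.segment_length_sd_um < 0:
            raise ValueError("segment length mean must be > 0, sd >= 0")
        if self.initial_total_length_um <= 0 or self.sprout_length_scale <= 0:
            raise ValueError("initial length and sprout scale must be positive")

    @property
    def control_group(self) -> str:
        return self.groups[0].name

    @property
    def final_day(self) -> int:
        return int(self.days[-1])


def default_config(seed: int = 0) -> SimulationConfig:
    """The default 3-arm, 17-embryos-per-group study configuration."""
    return SimulationConfig(seed=seed)


# ---------------------------------------------------------------------------
# configuration (de)serialization — the CLI config-file schema
# ---------------------------------------------------------------------------


def config_to_dict(config: SimulationConfig) -> dict[str, Any]:
    return {
        "schema": "angiocam-simconfig/1",
        "groups": [
            {
                "name": g.name,
                "sprout_multiplier": g.sprout_multiplier,
                "elongation_multiplier": g.elongation_multiplier,
                "thickness_shift_um": g.thickness_shift_um,
                "daily_death_hazard": g.daily_death_hazard,
            }
            for g in config.groups
        ],
        "n_embryos": config.n_embryos,
        "days": list(config.days),
        "n_roots": config.n_roots,
        "initial_branch_events": config.initial_branch_events,
        "base_sprout_rate": config.base_sprout_rate,
        "segment_length_mean_um": config.segment_length_mean_um,
        "segment_length_sd_um": config.segment_length_sd_um,
        "initial_total_length_um": config.initial_total_length_um,
        "sprout_length_scale": config.sprout_length_scale,
        "thickness_mean_um": config.thickness_mean_um,
        "thickness_sd_um": config.thickness_sd_um,
        "roi": config.roi.to_dict(),
        "seed": config.seed,
    }


def config_from_dict(d: Mapping[str, Any]) -> SimulationConfig:
    groups = tuple(
        GroupSpec(
            name=g["name"],
            sprout_multiplier=float(g.get("sprout_multiplier", 1.0)),
            elongation_multiplier=float(g.get("elongation_multiplier", 1.0)),
            thickness_shift_um=float(g.get("thickness_shift_um", 0.0)),
            daily_death_hazard=float(g.get("daily_death_hazard", 0.03)),
        )
        for g in d["groups"]
    )
    kwargs: dict[str, Any] = {"groups": groups}
    for key in (
        "n_embryos",
        "n_roots",
        "initial_branch_events",
        "seed",
    ):
        if key in d:
            kwargs[key] = int(d[key])
    for key in (
        "base_sprout_rate",
        "segment_length_mean_um",
        "segment_length_sd_um",
        "initial_total_length_um",
        "sprout_length_scale",
        "thickness_mean_um",
        "thickness_sd_um",
    ):
        if key in d:
            kwargs[key] = float(d[key])
    if "days" in d:
        kwargs["days"] = tuple(int(x) for x in d["days"])
    if "roi" in d:
        kwargs["roi"] = RingROI.from_dict(d["roi"])
    return SimulationConfig(**kwargs)


# ---------------------------------------------------------------------------
# random streams: one stream per embryo and purpose, so adding embryos or
# purposes never perturbs existing draws
# ---------------------------------------------------------------------------

_PURPOSE_GROWTH, _PURPOSE_DEATH, _PURPOSE_THICKNESS = 0, 1, 2


def _rng(config: SimulationConfig, group_index: int, embryo_index: int,
         purpose: int) -> np.random.Generator:
    return np.random.default_rng(
        [int(config.seed), int(group_index), int(embryo_index), int(purpose)]
    )


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    if sd == 0.0:
        return math.log(mean), 0.0
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - 0.5 * sigma2, math.sqrt(sigma2)


# ---------------------------------------------------------------------------
# vessel-network growth
# ---------------------------------------------------------------------------


class _GrowthState:
    """Mutable tree under construction; tips are a FIFO of (node, direction)."""

    __slots__ = ("nodes", "edges", "tips", "next_node", "next_edge", "roots")

    def __init__(self) -> None:
        self.nodes: dict[int, tuple[float, float]] = {}
        self.edges: list[Segment] = []
        self.tips: deque[tuple[int, float]] = deque()  # (node id, direction rad)
        self.next_node = 0
        self.next_edge = 0
        self.roots: list[int] = []

    def add_node(self, x: float, y: float) -> int:
        nid = self.next_node
        self.nodes[nid] = (float(x), float(y))
        self.next_node += 1
        return nid

    def add_segment(self, u: int, v: int, length: float) -> int:
        eid = self.next_edge
        pu, pv = self.nodes[u], self.nodes[v]
        self.edges.append(
            Segment(id=eid, u=u, v=v, points=(pu, pv), length=float(length))
        )
        self.next_edge += 1
        return eid

    def snapshot(self) -> VesselGraph:
        return VesselGraph(
            nodes=dict(self.nodes), edges=list(self.edges), roots=tuple(self.roots)
        )


def _branch(state: _GrowthState, lengths: tuple[float, float],
            deltas: tuple[float, float]) -> None:
    """One branching event: two daughters at the oldest active tip."""
    node, direction = state.tips.popleft()
    x, y = state.nodes[node]
    for length, delta in zip(lengths, deltas):
        d = direction + delta
        end = state.add_node(x + length * math.cos(d), y + length * math.sin(d))
        state.add_segment(node, end, length)
        state.tips.append((end, d))


_BRANCH_HALF_ANGLE = (0.25, 0.80)  # radians; daughters deviate +/- within this


def simulate_vessel_timecourse(
    config: SimulationConfig, group_index: int, embryo_index: int
) -> dict[int, VesselGraph]:
    """Nested per-day vessel networks of one embryo (observation days -> graph).

    Deterministic for a fixed (config.seed, group, embryo) triple.
    """
    group = config.groups[group_index]
    rng = _rng(config, group_index, embryo_index, _PURPOSE_GROWTH)
    mu, sigma = _lognormal_params(
        config.segment_length_mean_um, config.segment_length_sd_um
    )

    def draw_lengths(k: int) -> np.ndarray:
        return rng.lognormal(mu, sigma, size=k)

    def draw_delta() -> float:
        lo, hi = _BRANCH_HALF_ANGLE
        return float(rng.uniform(lo, hi))

    b0 = config.initial_branch_events
    n_init_segments = config.n_roots + 2 * b0
    raw = draw_lengths(n_init_segments)
    scale0 = config.initial_total_length_um / float(raw.sum())
    init_lengths = deque(raw * scale0)

    state = _GrowthState()
    r_start = 0.95 * config.roi.outer_radius
    cx, cy = config.roi.center
    for i in range(config.n_roots):
        theta = 2.0 * math.pi * i / config.n_roots
        start = state.add_node(cx + r_start * math.cos(theta),
                               cy + r_start * math.sin(theta))
        length = init_lengths.popleft()
        direction = theta + math.pi  # inward
        end = state.add_node(
            cx + (r_start - 0.0) * math.cos(theta) + length * math.cos(direction),
            cy + r_start * math.sin(theta) + length * math.sin(direction),
        )
        state.roots.append(state.add_segment(start, end, length))
        state.tips.append((end, direction))
    for _ in range(b0):
        lengths = (init_lengths.popleft(), init_lengths.popleft())
        d = draw_delta()
        _branch(state, lengths, (+d, -draw_delta()))

    sprout_mean_factor = config.sprout_length_scale * group.elongation_multiplier
    graphs: dict[int, VesselGraph] = {}
    prev_day = 0
    for day in config.days:
        if day > 0:
            elapsed = day - prev_day
            mean_events = config.base_sprout_rate * group.sprout_multiplier * elapsed
            n_events = int(rng.poisson(mean_events)) if mean_events > 0 else 0
            for _ in range(n_events):
                lengths = tuple(draw_lengths(2) * sprout_mean_factor)
                _branch(state, lengths, (+draw_delta(), -draw_delta()))
            prev_day = day
        graphs[int(day)] = state.snapshot()
    return graphs


def _death_day(rng: np.random.Generator, hazard: float, final_day: int) -> int | None:
    """First whole day (1..final_day) the embryo dies, or None if it survives."""
    if hazard <= 0.0:
        return None
    for t in range(1, final_day + 1):
        if rng.random() < hazard:
            return t
    return None


def simulate_cohort(
    config: SimulationConfig, with_graphs: bool = False
) -> CohortDataset | tuple[CohortDataset, dict[tuple[str, int], VesselGraph]]:
    """Full synthetic cohort: metric records, survival events, thickness.

    Metric rows are produced by running :func:`angiocam.vesselnet.compute_metrics`
    on each simulated network, i.e. through the same measurement code the
    pipeline applies to real data.  With ``with_graphs=True`` the per-embryo
    per-day graphs are returned as well, keyed by (embryo_id, day).
    """
    metric_rows: list[dict[str, Any]] = []
    survival_rows: list[dict[str, Any]] = []
    thickness_rows: list[dict[str, Any]] = []
    graphs: dict[tuple[str, int], VesselGraph] = {}
    final = config.final_day

    for gi, group in enumerate(config.groups):
        for ei in range(config.n_embryos):
            embryo_id = f"{group.name}-e{ei:02d}"
            death = _death_day(
                _rng(config, gi, ei, _PURPOSE_DEATH), group.daily_death_hazard, final
            )
            timecourse = simulate_vessel_timecourse(config, gi, ei)
            for day, graph in timecourse.items():
                if death is not None and day >= death:
                    continue
                metrics = compute_metrics(graph, config.roi)
                row = {"embryo_id": embryo_id, "group": group.name, "day": int(day)}
                row.update(metrics.as_row())
                metric_rows.append(row)
                if with_graphs:
                    graphs[(embryo_id, int(day))] = graph
            survival_rows.append(
                {
                    "embryo_id": embryo_id,
                    "group": group.name,
                    "time": int(death) if death is not None else final,
                    "event": 1 if death is not None else 0,
                }
            )
            if death is None:
                t_rng = _rng(config, gi, ei, _PURPOSE_THICKNESS)
                thickness = max(
                    1.0,
                    float(
                        t_rng.normal(
                            config.thickness_mean_um + group.thickness_shift_um,
                            config.thickness_sd_um,
                        )
                    ),
                )
                thickness_rows.append(
                    {
                        "embryo_id": embryo_id,
                        "group": group.name,
                        "thickness_um": thickness,
                    }
                )

    cohort = CohortDataset(
        metrics=pd.DataFrame(metric_rows),
        survival=pd.DataFrame(survival_rows),
        thickness=pd.DataFrame(
            thickness_rows, columns=["embryo_id", "group", "thickness_um"]
        ),
        control_group=config.control_group,
    )
    if with_graphs:
        return cohort, graphs
    return cohort


def clone_control_as_treatment(
    cohort: CohortDataset, name: str = "cloned-control"
) -> CohortDataset:
    """Cohort with the control group duplicated verbatim under a treatment label.

    Scoring the clone against the control exercises the reference identity of
    the index (every parameter's AAI is 0).
    """

    def retag(df: pd.DataFrame) -> pd.DataFrame:
        sub = df[df["group"] == cohort.control_group].copy()
        sub["group"] = name
        sub["embryo_id"] = sub["embryo_id"].astype(str) + "-clone"
        return sub

    return CohortDataset(
        metrics=pd.concat([cohort.metrics, retag(cohort.metrics)], ignore_index=True),
        survival=pd.concat(
            [cohort.survival, retag(cohort.survival)], ignore_index=True
        ),
        thickness=pd.concat(
            [cohort.thickness, retag(cohort.thickness)], ignore_index=True
        ),
        control_group=cohort.control_group,
    )


# ---------------------------------------------------------------------------
# analytic expectations
# ---------------------------------------------------------------------------


def branch_degree_counts(n_roots: int, n_events: int) -> np.ndarray:
    """Branch-degree counts (n1..n4) after each oldest-tip-first branching event.

    Returns an array of shape (n_events + 1, 4); row j is the degree census
    after j events, starting from ``n_roots`` first-degree feeder segments.
    """
    counts = np.zeros((n_events + 1, 4), dtype=np.int64)
    counts[0, 0] = n_roots
    tips = deque([1] * n_roots)
    for j in range(1, n_events + 1):
        parent = tips.popleft()
        child = min(parent + 1, 4)
        counts[j] = counts[j - 1]
        counts[j, child - 1] += 2
        tips.append(child)
        tips.append(child)
    return counts


@dataclass(frozen=True)
class ExpectedOutcome:
    """Closed-form expectations of the cohort generator at the headline day.

    ``ar`` holds expected angiogenic responses per group and parameter;
    ``aai_plugin`` applies the index to those expectations; ``aai_mean`` is
    the expected value of the cohort-level estimator (what repeated simulated
    cohorts average to), conditional on the parameter not being excluded.
    """

    day: int
    ar: dict[str, dict[str, float]]
    aai_plugin: dict[str, dict[str, float]]
    aai_mean: dict[str, dict[str, float]]
    final_aai_plugin: dict[str, float]
    final_aai_mean: dict[str, float]
    excluded: dict[str, list[str]]


def _poisson_cap(lam: float) -> int:
    return max(10, int(lam + 12.0 * math.sqrt(max(lam, 1.0)) + 30))


def _binom_pmf(n: int, p: float) -> np.ndarray:
    return stats.binom.pmf(np.arange(n + 1), n, p)


def _e_inv_poisson_sum(k_pmf: np.ndarray, lam_per: float) -> tuple[float, float]:
    """(E[K / T ; T>=1], P[T>=1]) with T | K ~ Poisson(K * lam_per), K ~ k_pmf.

    The expectation is taken jointly with the inclusion event T >= 1; divide
    by the returned probability for the conditional mean.
    """
    e_joint = 0.0
    p_incl = 0.0
    for k in range(1, k_pmf.size):
        pk = float(k_pmf[k])
        if pk <= 0.0:
            continue
        lam = k * lam_per
        cap = _poisson_cap(lam)
        t = np.arange(1, cap + 1)
        pois = stats.poisson.pmf(t, lam)
        e_joint += pk * k * float(np.sum(pois / t))
        p_incl += pk * (1.0 - math.exp(-lam))
    return e_joint, p_incl


def _e_inv_compound_sum(
    k_pmf: np.ndarray, lam_per: float, jump_mean: float, jump_cv2: float
) -> tuple[float, float]:
    """(E[K / W ; M>=1], P[M>=1]) for W = sum of 2M i.i.d. jumps, M | K Poisson.

    Uses the second-order small-CV expansion E[1/S_n] ~ (1/(n mu))(1 + cv2/n)
    for the sum of n = 2M jumps with mean ``jump_mean`` and squared CV
    ``jump_cv2``.
    """
    e_joint = 0.0
    p_incl = 0.0
    for k in range(1, k_pmf.size):
        pk = float(k_pmf[k])
        if pk <= 0.0:
            continue
        lam = k * lam_per
        cap = _poisson_cap(lam)
        m = np.arange(1, cap + 1)
        pois = stats.poisson.pmf(m, lam)
        inv = (1.0 / (2.0 * m * jump_mean)) * (1.0 + jump_cv2 / (2.0 * m))
        e_joint += pk * k * float(np.sum(pois * inv))
        p_incl += pk * (1.0 - math.exp(-lam))
    return e_joint, p_incl


def _poisson_mix_moments(
    seq_vals: np.ndarray, b0: int, lam: float
) -> tuple[float, float]:
    """Mean and variance of seq_vals[b0 + N] with N ~ Poisson(lam)."""
    cap = _poisson_cap(lam)
    n = np.arange(0, cap + 1)
    pmf = stats.poisson.pmf(n, lam)
    pmf = pmf / pmf.sum()
    idx = np.minimum(b0 + n, seq_vals.size - 1)
    vals = seq_vals[idx].astype(float)
    mean = float(np.sum(pmf * vals))
    var = float(np.sum(pmf * (vals - mean) ** 2))
    return mean, var


def _hierarchy_moments(
    config: SimulationConfig, lam: float, k_pmf: np.ndarray
) -> tuple[float, float]:
    """Approximate mean and variance of the pooled hierarchy AR of one group."""
    b0 = config.initial_branch_events
    cap = b0 + _poisson_cap(lam)
    seq = branch_degree_counts(config.n_roots, cap)
    low = (seq[:, 0] + seq[:, 1]).astype(float)
    high = (seq[:, 2] + seq[:, 3]).astype(float)
    hr0 = high[b0] / low[b0]
    n_grid = np.arange(0, cap - b0 + 1)
    pmf = stats.poisson.pmf(n_grid, lam)
    pmf = pmf / pmf.sum()
    hv = high[b0 + n_grid]
    lv = low[b0 + n_grid]
    m_h = float(np.sum(pmf * hv))
    m_l = float(np.sum(pmf * lv))
    v_h = float(np.sum(pmf * (hv - m_h) ** 2))
    v_l = float(np.sum(pmf * (lv - m_l) ** 2))
    c_hl = float(np.sum(pmf * (hv - m_h) * (lv - m_l)))
    ks = np.arange(k_pmf.size)
    # renormalize over K >= 1 (inclusion)
    kp = k_pmf.copy()
    kp[0] = 0.0
    kp = kp / kp.sum()
    e_k = float(np.sum(kp * ks))
    v_k = float(np.sum(kp * (ks - e_k) ** 2))
    ex = e_k * m_h
    ez = e_k * m_l
    var_x = e_k * v_h + v_k * m_h**2
    var_z = e_k * v_l + v_k * m_l**2
    cov = e_k * c_hl + v_k * m_h * m_l
    ratio = ex / ez
    mean_r = ratio * (1.0 + var_z / ez**2 - cov / (ex * ez)) / hr0
    var_r = ratio**2 * (
        var_x / ex**2 + var_z / ez**2 - 2.0 * cov / (ex * ez)
    ) / hr0**2
    return mean_r, var_r


def _hierarchy_is_junction_affine(config: SimulationConfig, lam_max: float) -> bool:
    """True when, over the relevant event range, every event adds exactly two
    high-degree segments and no low-degree ones — then the pooled hierarchy AR
    is an affine function of the junction count and the two estimators agree."""
    b0 = config.initial_branch_events
    cap = b0 + _poisson_cap(lam_max)
    seq = branch_degree_counts(config.n_roots, cap)
    low = seq[b0:, 0] + seq[b0:, 1]
    high = seq[b0:, 2] + seq[b0:, 3]
    return bool(np.all(low == low[0]) and np.all(np.diff(high) == 2))


def expected_outcome(config: SimulationConfig) -> ExpectedOutcome:
    """Analytic expectations of the generator at the final observation day."""
    day = config.final_day
    n = config.n_embryos
    b0 = config.initial_branch_events
    l0 = config.initial_total_length_um
    lbar = config.segment_length_mean_um
    cv2 = (config.segment_length_sd_um / lbar) ** 2
    s = config.sprout_length_scale
    s0 = config.n_roots + 2 * b0

    ctrl = config.groups[0]
    lam_c = config.base_sprout_rate * ctrl.sprout_multiplier * day
    q = {g.name: (1.0 - g.daily_death_hazard) ** day for g in config.groups}
    lam = {
        g.name: config.base_sprout_rate * g.sprout_multiplier * day
        for g in config.groups
    }
    elong = {g.name: g.elongation_multiplier for g in config.groups}
    mu_thick = {
        g.name: config.thickness_mean_um + g.thickness_shift_um for g in config.groups
    }

    cap_seq = b0 + _poisson_cap(max(lam.values()))
    seq = branch_degree_counts(config.n_roots, cap_seq)
    low = (seq[:, 0] + seq[:, 1]).astype(float)
    high = (seq[:, 2] + seq[:, 3]).astype(float)
    hr0 = high[b0] / low[b0]

    # ---- expected angiogenic responses (plug-in means) --------------------
    ar: dict[str, dict[str, float]] = {}
    for g in config.groups:
        lg, eg = lam[g.name], elong[g.name]
        len_ar = 1.0 + 2.0 * lg * eg * s * lbar / l0
        m_h, _ = _poisson_mix_moments(high, b0, lg)
        m_l, _ = _poisson_mix_moments(low, b0, lg)
        ar[g.name] = {
            "survival": q[g.name],
            "junctions": 1.0 + lg / b0,
            "hierarchy": (m_h / m_l) / hr0,
            "total_length": len_ar,
            "density": len_ar,
            "mean_length": len_ar * s0 / (s0 + 2.0 * lg),
            "thickness": mu_thick[g.name],
        }

    # ---- control-side inverse moments (shared across treatments) ----------
    k_pmf_c = _binom_pmf(n, q[ctrl.name])
    p_c_death = 1.0 - q[ctrl.name]

    junction_inv = _e_inv_poisson_sum(k_pmf_c, lam_c) if lam_c > 0 else (0.0, 0.0)
    length_inv = (
        _e_inv_compound_sum(k_pmf_c, lam_c, s * lbar, cv2) if lam_c > 0 else (0.0, 0.0)
    )
    if p_c_death > 0:
        d_grid = np.arange(1, n + 1)
        d_pmf = stats.binom.pmf(d_grid, n, p_c_death)
        p_incl_surv = float(d_pmf.sum())
        e_inv_d = float(np.sum(d_pmf / d_grid)) / p_incl_surv
    else:
        e_inv_d = float("nan")
    kp = k_pmf_c.copy()
    kp[0] = 0.0
    kp_norm = kp / kp.sum() if kp.sum() > 0 else kp
    var_med_c = float(
        np.sum(
            kp_norm[1:]
            * (math.pi * config.thickness_sd_um**2 / 2.0)
            / np.arange(1, n + 1)
        )
    )
    e_inv_med_c = (1.0 / mu_thick[ctrl.name]) * (
        1.0 + var_med_c / mu_thick[ctrl.name] ** 2
    )

    hier_affine = _hierarchy_is_junction_affine(config, max(lam.values()))
    hier_c = None if hier_affine else _hierarchy_moments(config, lam_c, k_pmf_c)

    # ---- per-treatment indices --------------------------------------------
    aai_plugin: dict[str, dict[str, float]] = {}
    aai_mean: dict[str, dict[str, float]] = {}
    final_plugin: dict[str, float] = {}
    final_mean: dict[str, float] = {}
    excluded: dict[str, list[str]] = {}

    for g in config.groups[1:]:
        name = g.name
        plug: dict[str, float] = {}
        mean: dict[str, float] = {}
        excl: list[str] = []
        for param in AAI_PARAMETERS:
            if param == "thickness":
                try:
                    plug[param] = thickness_index(
                        mu_thick[name], mu_thick[ctrl.name]
                    )
                except Exception:
                    excl.append(param)
                    continue
                mean[param] = mu_thick[name] * e_inv_med_c - 1.0
                continue
            try:
                plug[param] = aai_parameter(ar[name][param], 1.0, ar[ctrl.name][param], 1.0)
            except DegenerateControlError:
                excl.append(param)
                continue
            if param in ("junctions",) or (param == "hierarchy" and hier_affine):
                e_joint, p_incl = junction_inv
                mean[param] = lam[name] * (e_joint / p_incl) - 1.0
            elif param == "hierarchy":
                mean_rc, var_rc = hier_c  # type: ignore[misc]
                k_pmf_t = _binom_pmf(n, q[name])
                mean_rt, _ = _hierarchy_moments(config, lam[name], k_pmf_t)
                denom = mean_rc - 1.0
                mean[param] = (mean_rt - mean_rc) / denom + var_rc * (
                    mean_rt - 1.0
                ) / denom**3
            elif param in ("total_length", "density"):
                # E[1/dAR_c] = L0 * E[K/W | M >= 1]; the jump mean passed to the
                # compound sum already carries the sprout length scale.
                e_joint, p_incl = length_inv
                e_dt = 2.0 * lam[name] * elong[name] * s * lbar / l0
                mean[param] = e_dt * l0 * (e_joint / p_incl) - 1.0
            elif param == "survival":
                p_t_death = 1.0 - q[name]
                mean[param] = n * p_t_death * e_inv_d - 1.0
        aai_plugin[name] = plug
        aai_mean[name] = mean
        excluded[name] = excl
        final_plugin[name] = float(np.mean(list(plug.values())))
        final_mean[name] = float(np.mean(list(mean.values())))

    return ExpectedOutcome(
        day=day,
        ar=ar,
        aai_plugin=aai_plugin,
        aai_mean=aai_mean,
        final_aai_plugin=final_plugin,
        final_aai_mean=final_mean,
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# scratch-assay and qPCR table generators
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScratchCondition:
    """Configured true closure / remaining-width percentages of one condition."""

    name: str
    closure_pct: tuple[tuple[float, float], ...] = ((6.0, 30.0), (24.0, 73.7))
    width_remaining_pct: tuple[tuple[float, float], ...] = ((6.0, 60.0), (24.0, 17.1))


_DEFAULT_SCRATCH_CONDITIONS = (
    ScratchCondition("medium"),
    ScratchCondition(
        "adsc-secretome",
        closure_pct=((6.0, 41.8), (24.0, 90.0)),
        width_remaining_pct=((6.0, 55.0), (24.0, 29.0)),
    ),
    ScratchCondition(
        "mixed-secretome",
        closure_pct=((6.0, 25.6), (24.0, 78.4)),
        width_remaining_pct=((6.0, 70.0), (24.0, 46.7)),
    ),
)


@dataclass(frozen=True)
class ScratchSimConfig:
    conditions: tuple[ScratchCondition, ...] = _DEFAULT_SCRATCH_CONDITIONS
    n_samples: int = 8
    baseline_area_um2: float = 1.0e6
    baseline_width_um: float = 800.0
    baseline_noise_cv: float = 0.05
    closure_noise_sd_pct: float = 12.0
    width_noise_sd_pct: float = 12.0
    lps_flag: int = 0


def simulate_scratch_series(config: ScratchSimConfig, seed: int) -> pd.DataFrame:
    """Synthetic scratch measurements in the scratch CSV schema.

    Measured closure / remaining-width percentages are unbiased for the
    configured values; with all noise parameters 0 they are exact.
    """
    rng = np.random.default_rng([int(seed), 101])
    rows = []
    for cond in config.conditions:
        for si in range(config.n_samples):
            sample = f"{cond.name}-s{si:02d}"
            a0 = config.baseline_area_um2 * max(
                0.05, 1.0 + config.baseline_noise_cv * rng.standard_normal()
            )
            w0 = config.baseline_width_um * max(
                0.05, 1.0 + config.baseline_noise_cv * rng.standard_normal()
            )
            rows.append(
                {
                    "sample": sample, "condition": cond.name,
                    "lps_flag": config.lps_flag, "time_h": 0.0, "area": a0,
                    **{f"w{i}": w0 for i in range(1, 6)},
                }
            )
            widths = dict(cond.width_remaining_pct)
            for t, closure in cond.closure_pct:
                c = closure + config.closure_noise_sd_pct * rng.standard_normal()
                c = min(c, 100.0)
                r = widths[t] + config.width_noise_sd_pct * rng.standard_normal()
                r = max(r, 0.0)
                rows.append(
                    {
                        "sample": sample, "condition": cond.name,
                        "lps_flag": config.lps_flag, "time_h": t,
                        "area": a0 * (1.0 - c / 100.0),
                        **{f"w{i}": w0 * r / 100.0 for i in range(1, 6)},
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class CtSimConfig:
    """Configured expression effects: gene -> condition -> fold change vs control."""

    conditions: tuple[str, ...] = ("medium", "adsc-secretome", "mixed-secretome")
    control_condition: str = "medium"
    genes: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "MMP9": {"adsc-secretome": 13.4, "mixed-secretome": 3.8},
            "TIMP1": {"adsc-secretome": 2.5, "mixed-secretome": 4.4},
            "MMP2": {"adsc-secretome": 0.17, "mixed-secretome": 0.30},
            "IL6": {"adsc-secretome": 20.0, "mixed-secretome": 7.7},
        }
    )
    housekeeping_ct: float = 15.0
    base_dct: float = 5.0
    ct_noise_sd: float = 0.15
    n_samples: int = 4
    n_technical: int = 3


def simulate_ct_table(config: CtSimConfig, seed: int) -> pd.DataFrame:
    """Synthetic qPCR CT table whose expected fold changes equal the config."""
    rng = np.random.default_rng([int(seed), 202])
    rows = []
    for cond in config.conditions:
        for gene, effects in config.genes.items():
            fc = 1.0 if cond == config.control_condition else float(
                effects.get(cond, 1.0)
            )
            true_dct = config.base_dct - math.log2(fc)
            for si in range(config.n_samples):
                sample = f"{cond}-s{si:02d}"
                for _ in range(config.n_technical):
                    hk = config.housekeeping_ct + config.ct_noise_sd * rng.standard_normal()
                    ct = hk + true_dct + config.ct_noise_sd * rng.standard_normal()
                    rows.append(
                        {
                            "sample": sample, "condition": cond, "gene": gene,
                            "ct": ct, "housekeeping_ct": hk,
                        }
                    )
    return pd.DataFrame(rows)
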