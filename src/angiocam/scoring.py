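"""Cohort scoring: fold changes, survival, and the angiogenic activity index.

The CAM assay observes each embryo on treatment days 0, 2, 4 and 7.  To remove
the embryo-specific starting vascularization, every vascular parameter is
expressed as a fold change over its own day-0 value; the group-level
*angiogenic response* AR of a parameter on a day is the group mean of those
per-embryo fold changes (mean fold change ± SD).

The per-parameter angiogenic activity index compares baseline-corrected
responses of a treatment group against the control group::

    AAI_i = ((AR_t(d) - AR_t(0)) - (AR_c(d) - AR_c(0))) / (AR_c(d) - AR_c(0))

so the control scored against itself gives 0 and a treatment whose
baseline-corrected change is exactly twice the control's gives 1.  The final
AAI is the arithmetic mean of the per-parameter indices.

Six parameters enter the final AAI: probability of survival (Kaplan–Meier
S(d), with S(0) = 1 as the day-0 response), junctions, branch hierarchy ratio,
total vessel length, vessel density, and CAM thickness.  Thickness exists only
at the final day; its index is the relative difference of group medians.  Mean
vessel length is reported in the profile but does not enter the final index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .errors import (
    DegenerateControlError,
    EmptyGroupError,
    InvalidBaselineError,
    NoValidParametersError,
    SchemaError,
)

__all__ = [
    "CohortDataset",
    "GroupResponse",
    "SurvivalCurve",
    "AAIProfile",
    "AAI_PARAMETERS",
    "METRIC_COLUMNS",
    "fold_change",
    "group_response",
    "aai_parameter",
    "thickness_index",
    "km_estimator",
    "survival_response",
    "logrank_test",
    "final_aai",
    "build_angiogenic_profile",
]

#: tolerance below which |AR_c(d) - AR_c(0)| is treated as a vanishing denominator
DEGENERATE_CONTROL_EPS = 1e-9

#: parameters entering the final AAI (mean vessel length is reported only)
AAI_PARAMETERS = (
    "survival",
    "junctions",
    "hierarchy",
    "total_length",
    "density",
    "thickness",
)

#: fold-change parameters and the metrics-table column holding each
METRIC_COLUMNS = {
    "junctions": "junctions",
    "total_length": "total_length_um",
    "density": "density_um_per_mm2",
    "mean_length": "mean_length_um",
    "segments": "segments",
}

_METRIC_TABLE_COLUMNS = [
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


@dataclass
class CohortDataset:
    """Embryo × day × group cohort: metric records, survival, thickness.

    ``metrics`` has one row per embryo and observation day with the columns of
    the metrics CSV schema.  ``survival`` has one row per embryo with columns
    ``embryo_id, group, time, event`` (``event`` 1 = died at ``time`` days,
    0 = censored/alive at ``time``).  ``thickness`` has columns
    ``embryo_id, group, thickness_um`` (final-day CAM thickness; optional per
    embryo).  Exactly one group is the control.
    """

    metrics: pd.DataFrame
    survival: pd.DataFrame
    thickness: pd.DataFrame
    control_group: str = "control"

    def __post_init__(self) -> None:
        self.metrics = self.metrics.reset_index(drop=True)
        self.survival = self.survival.reset_index(drop=True)
        self.thickness = self.thickness.reset_index(drop=True)

    @property
    def groups(self) -> list[str]:
        order: list[str] = []
        for g in self.metrics["group"]:
            if g not in order:
                order.append(g)
        return order

    @property
    def treatment_groups(self) -> list[str]:
        return [g for g in self.groups if g != self.control_group]

    @property
    def days(self) -> list[int]:
        return sorted(int(d) for d in self.metrics["day"].unique())

    def validate(self) -> None:
        missing = [c for c in _METRIC_TABLE_COLUMNS if c not in self.metrics.columns]
        if missing:
            raise SchemaError(f"metrics table missing columns: {missing}")
        if self.control_group not in set(self.metrics["group"]):
            raise SchemaError(
                f"control group {self.control_group!r} absent from metrics table"
            )
        # every embryo needs a day-0 record
        for eid, sub in self.metrics.groupby("embryo_id"):
            if 0 not in set(sub["day"].astype(int)):
                raise SchemaError(f"embryo {eid!r} has no day-0 record")
        # no metric records after an embryo's death day
        if len(self.survival):
            death = self.survival.set_index("embryo_id")
            for eid, sub in self.metrics.groupby("embryo_id"):
                if eid in death.index and int(death.loc[eid, "event"]) == 1:
                    t = float(death.loc[eid, "time"])
                    last = float(sub["day"].max())
                    if last >= t:
                        raise SchemaError(
                            f"embryo {eid!r} has records on/after its death day {t}"
                        )


@dataclass(frozen=True)
class GroupResponse:
    """Group-level angiogenic response: mean fold change of one parameter/day."""

    group: str
    parameter: str
    day: int
    ar: float
    sd: float
    n_embryos: int


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit survival estimate on the observation window."""

    times: tuple[float, ...]
    at_risk: tuple[int, ...]
    survival: tuple[float, ...]

    def survival_at(self, day: float) -> float:
        s = 1.0
        for t, p in zip(self.times, self.survival):
            if t <= day:
                s = p
            else:
                break
        return s


@dataclass
class AAIProfile:
    """Per-parameter AAI values, the final AAI, and the profile table."""

    treatment_group: str
    day: int
    indices: dict[str, float]
    final_aai: float
    excluded: list[tuple[str, str]] = field(default_factory=list)
    table: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.indices)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def fold_change(value_day: float, value_day0: float) -> float:
    """Fold change of a measurement over its day-0 baseline."""
    if not value_day0 > 0.0:
        raise InvalidBaselineError(
            f"day-0 baseline must be positive, got {value_day0}"
        )
    return value_day / value_day0


def aai_parameter(
    ar_treat_day: float,
    ar_treat_day0: float,
    ar_ctrl_day: float,
    ar_ctrl_day0: float,
    eps: float = DEGENERATE_CONTROL_EPS,
) -> float:
    """Per-parameter AAI from the four angiogenic responses.

    Raises :class:`DegenerateControlError` when the control change
    ``AR_c(d) - AR_c(0)`` is smaller than ``eps`` in magnitude.
    """
    ctrl_change = ar_ctrl_day - ar_ctrl_day0
    if abs(ctrl_change) < eps:
        raise DegenerateControlError(
            f"control change {ctrl_change} is below tolerance {eps}"
        )
    treat_change = ar_treat_day - ar_treat_day0
    return (treat_change - ctrl_change) / ctrl_change


def thickness_index(thickness_treat: float, thickness_ctrl: float) -> float:
    """Relative difference of group-median CAM thickness at the final day."""
    if not thickness_ctrl > 0.0:
        raise InvalidBaselineError(
            f"control median thickness must be positive, got {thickness_ctrl}"
        )
    return (thickness_treat - thickness_ctrl) / thickness_ctrl


def final_aai(
    indices: Mapping[str, float] | Iterable[tuple[str, float]],
    excluded: Sequence[tuple[str, str]] = (),
) -> AAIProfile:
    """Final AAI: arithmetic mean of the included per-parameter indices."""
    items = dict(indices)
    if not items:
        raise NoValidParametersError("all parameters excluded; final AAI undefined")
    value = float(np.mean(list(items.values())))
    return AAIProfile(
        treatment_group="",
        day=-1,
        indices=items,
        final_aai=value,
        excluded=list(excluded),
    )


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


def km_estimator(
    times: Sequence[float], events: Sequence[int]
) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimate (censoring reduces the risk set only)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise EmptyGroupError("no embryos for survival estimation")
    if np.any(times < 0):
        raise ValueError("event times must be nonnegative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    ts, at_risk, s_vals = [], [], []
    for t in table.index:
        ts.append(float(t))
        at_risk.append(int(table.loc[t, "at_risk"]))
        s_vals.append(float(surv.loc[t]))
    return SurvivalCurve(times=tuple(ts), at_risk=tuple(at_risk), survival=tuple(s_vals))


def survival_response(curve: SurvivalCurve, day: float) -> float:
    """Survival probability S(day) used as the angiogenic response; S(0) = 1."""
    if day <= 0:
        return 1.0
    return curve.survival_at(day)


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[int],
    times_b: Sequence[float],
    events_b: Sequence[int],
) -> tuple[float, float]:
    """Mantel–Cox log-rank comparison of two survival curves.

    Returns (chi-square statistic with 1 df, p-value).  With no deaths in
    either group the statistic is 0 and p = 1.
    """
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    if ta.size == 0 or tb.size == 0:
        raise EmptyGroupError("both groups must be nonempty for the log-rank test")
    if ea.sum() + eb.sum() == 0:
        return 0.0, 1.0
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# group-level responses
# ---------------------------------------------------------------------------


def _pivot_parameter(
    cohort: CohortDataset, group: str, column: str
) -> pd.DataFrame:
    sub = cohort.metrics[cohort.metrics["group"] == group]
    if sub.empty:
        raise EmptyGroupError(f"group {group!r} has no metric records")
    return sub.pivot_table(index="embryo_id", columns="day", values=column)


def group_response(
    cohort: CohortDataset, group: str, parameter: str, day: int
) -> GroupResponse:
    """Mean ± SD of per-embryo fold changes of one parameter at one day.

    Embryos dead before ``day`` (no record) or with a nonpositive/undefined
    baseline are excluded; sample SD uses n-1 degrees of freedom.
    """
    column = METRIC_COLUMNS.get(parameter, parameter)
    wide = _pivot_parameter(cohort, group, column)
    if day == 0:
        eligible = wide[0].dropna()
        eligible = eligible[eligible > 0]
        if eligible.empty:
            raise EmptyGroupError(
                f"group {group!r}: no embryo with a positive day-0 {parameter}"
            )
        fc = pd.Series(1.0, index=eligible.index)
    else:
        if day not in wide.columns:
            raise EmptyGroupError(f"group {group!r}: no records at day {day}")
        both = wide[[0, day]].dropna()
        both = both[both[0] > 0]
        if both.empty:
            raise EmptyGroupError(
                f"group {group!r}: no embryo has day-0 and day-{day} {parameter}"
            )
        fc = both[day] / both[0]
    n = int(fc.size)
    sd = float(fc.std(ddof=1)) if n > 1 else float("nan")
    return GroupResponse(
        group=group, parameter=parameter, day=int(day), ar=float(fc.mean()), sd=sd,
        n_embryos=n,
    )


def _pooled_hierarchy_ar(
    cohort: CohortDataset, group: str, day: int
) -> tuple[float, int]:
    """Group hierarchy AR: pooled (n3+n4)/(n1+n2) at ``day`` over embryos
    recorded at both day 0 and ``day``, divided by the same embryos' pooled
    day-0 ratio.  Robust to per-embryo undefined ratios."""
    sub = cohort.metrics[cohort.metrics["group"] == group]
    have_day = set(sub.loc[sub["day"] == day, "embryo_id"])
    have_0 = set(sub.loc[sub["day"] == 0, "embryo_id"])
    embryos = sorted(have_day & have_0)
    if not embryos:
        raise EmptyGroupError(
            f"group {group!r}: no embryo has day-0 and day-{day} branch counts"
        )
    pool = sub[sub["embryo_id"].isin(embryos)]

    def ratio(d: int) -> float:
        rows = pool[pool["day"] == d]
        low = float(rows["n1"].sum() + rows["n2"].sum())
        high = float(rows["n3"].sum() + rows["n4"].sum())
        return high / low if low > 0 else float("nan")

    hr0 = ratio(0)
    hrd = ratio(day) if day != 0 else hr0
    if not math.isfinite(hr0) or hr0 <= 0:
        raise EmptyGroupError(
            f"group {group!r}: pooled day-0 hierarchy ratio undefined or zero"
        )
    ar = hrd / hr0 if math.isfinite(hrd) else float("nan")
    return ar, len(embryos)


def _group_survival(cohort: CohortDataset, group: str) -> SurvivalCurve:
    sub = cohort.survival[cohort.survival["group"] == group]
    if sub.empty:
        raise EmptyGroupError(f"group {group!r} has no survival records")
    return km_estimator(sub["time"].to_numpy(), sub["event"].to_numpy())


def _group_thickness_median(cohort: CohortDataset, group: str) -> tuple[float, int]:
    sub = cohort.thickness[cohort.thickness["group"] == group]["thickness_um"].dropna()
    if sub.empty:
        raise EmptyGroupError(f"group {group!r} has no thickness measurements")
    return float(sub.median()), int(sub.size)


# ---------------------------------------------------------------------------
# full angiogenic profile
# ---------------------------------------------------------------------------

_DESIGN_METADATA = {
    "density_definition": "total vessel length per ROI area (um per mm^2)",
    "hierarchy_definition": "(3rd+4th degree)/(1st+2nd degree) segment counts, "
    "pooled over embryos within group before the ratio",
    "thickness_rule": "final-day only; index = relative difference of group medians",
    "survival_rule": "AR(d) = Kaplan-Meier S(d); S(0) = 1 is the day-0 response",
    "aggregation": "fold changes averaged within group before applying the index",
    "degenerate_control_eps": DEGENERATE_CONTROL_EPS,
    "final_aai_parameters": list(AAI_PARAMETERS),
    "reported_only_parameters": ["mean_length", "segments"],
}


def build_angiogenic_profile(
    cohort: CohortDataset,
    treatment_group: str,
    day: int = 7,
    parameters: Sequence[str] = AAI_PARAMETERS,
) -> AAIProfile:
    """Score one treatment group against the cohort's control group.

    Computes the angiogenic response of every parameter on every observation
    day (the *angiogenic profile*), applies the per-parameter index at the
    headline ``day``, and averages the included parameters into the final AAI.
    Parameters with a degenerate control change or no eligible embryos are
    excluded with a recorded reason.
    """
    if treatment_group not in cohort.groups:
        raise EmptyGroupError(f"treatment group {treatment_group!r} not in cohort")
    ctrl = cohort.control_group
    if ctrl not in cohort.groups:
        raise EmptyGroupError(f"control group {ctrl!r} not in cohort")
    days = [d for d in cohort.days if d != 0]

    rows: list[dict] = []
    indices: dict[str, float] = {}
    excluded: list[tuple[str, str]] = []

    def record(group: str, parameter: str, d: int, ar: float, sd: float, n: int,
               aai: float = float("nan")) -> None:
        rows.append(
            {"group": group, "parameter": parameter, "day": d, "ar": ar, "sd": sd,
             "n": n, "aai": aai}
        )

    def day_index(param: str, ar_t: float, ar_c: float, d: int) -> float:
        try:
            return aai_parameter(ar_t, 1.0, ar_c, 1.0)
        except DegenerateControlError:
            if d == day and param in parameters:
                excluded.append((param, f"degenerate control change at day {d}"))
            return float("nan")

    # --- fold-change parameters (mean_length reported but not indexed) ----
    fold_params = ["junctions", "total_length", "density", "mean_length"]
    for param in fold_params:
        for d in [0] + days:
            try:
                gr_c = group_response(cohort, ctrl, param, d)
                gr_t = group_response(cohort, treatment_group, param, d)
            except EmptyGroupError as exc:
                if d == day and param in parameters:
                    excluded.append((param, str(exc)))
                continue
            record(ctrl, param, d, gr_c.ar, gr_c.sd, gr_c.n_embryos)
            aai_d = day_index(param, gr_t.ar, gr_c.ar, d) if d else float("nan")
            record(treatment_group, param, d, gr_t.ar, gr_t.sd, gr_t.n_embryos, aai_d)
            if d == day and param in parameters and math.isfinite(aai_d):
                indices[param] = aai_d

    # --- branch hierarchy (pooled counts) ---------------------------------
    for d in [0] + days:
        try:
            ar_c, n_c = _pooled_hierarchy_ar(cohort, ctrl, d)
            ar_t, n_t = _pooled_hierarchy_ar(cohort, treatment_group, d)
        except EmptyGroupError as exc:
            if d == day and "hierarchy" in parameters:
                excluded.append(("hierarchy", str(exc)))
            continue
        record(ctrl, "hierarchy", d, ar_c, float("nan"), n_c)
        aai_d = day_index("hierarchy", ar_t, ar_c, d) if d else float("nan")
        record(treatment_group, "hierarchy", d, ar_t, float("nan"), n_t, aai_d)
        if d == day and "hierarchy" in parameters and math.isfinite(aai_d):
            indices["hierarchy"] = aai_d

    # --- survival ----------------------------------------------------------
    try:
        curve_c = _group_survival(cohort, ctrl)
        curve_t = _group_survival(cohort, treatment_group)
        for d in [0] + days:
            s_c = survival_response(curve_c, d)
            s_t = survival_response(curve_t, d)
            record(ctrl, "survival", d, s_c, float("nan"), curve_c.at_risk[0])
            aai_d = day_index("survival", s_t, s_c, d) if d else float("nan")
            record(treatment_group, "survival", d, s_t, float("nan"),
                   curve_t.at_risk[0], aai_d)
            if d == day and "survival" in parameters and math.isfinite(aai_d):
                indices["survival"] = aai_d
    except EmptyGroupError as exc:
        if "survival" in parameters:
            excluded.append(("survival", str(exc)))

    # --- CAM thickness (final day only) ------------------------------------
    if "thickness" in parameters:
        try:
            med_c, n_c = _group_thickness_median(cohort, ctrl)
            med_t, n_t = _group_thickness_median(cohort, treatment_group)
            record(ctrl, "thickness", day, med_c, float("nan"), n_c)
            idx = thickness_index(med_t, med_c)
            record(treatment_group, "thickness", day, med_t, float("nan"), n_t, idx)
            indices["thickness"] = idx
        except (EmptyGroupError, InvalidBaselineError) as exc:
            excluded.append(("thickness", str(exc)))

    if not indices:
        raise NoValidParametersError(
            f"every parameter excluded for {treatment_group!r}: {excluded}"
        )
    value = float(np.mean([indices[p] for p in indices]))
    table = pd.DataFrame(rows).sort_values(["parameter", "day", "group"]).reset_index(
        drop=True
    )
    return AAIProfile(
        treatment_group=treatment_group,
        day=day,
        indices=indices,
        final_aai=value,
        excluded=excluded,
        table=table,
        metadata=dict(_DESIGN_METADATA, headline_day=day, control_group=ctrl),
    )
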