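"""In vitro assay arithmetic: scratch wound closure and qPCR relative expression.

Scratch (wound-healing) assay: a cell-free gap is imaged at 0, 6 and 24 h.
Two readouts are computed: percent wound closure from the gap *area*
(reduction relative to the 0 h area), and the gap *width* measured at five
positions across the image.  Width is reported both as remaining width
(% of baseline) and as reduction (%); the two always sum to 100.

qPCR: relative expression is 2^(-dCT) against a housekeeping gene; fold
change between conditions is 2^(-(dCT_treated - dCT_control)).  Technical
replicates are averaged on the CT scale before dCT is formed.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidBaselineError, SchemaError

__all__ = [
    "wound_closure_percent",
    "width_percent_of_baseline",
    "width_reduction_percent",
    "rel_expression_neg_dct",
    "fold_change_vs_control",
    "scratch_closure_table",
    "ct_expression_table",
]

N_WIDTH_POSITIONS = 5


def wound_closure_percent(area_t0: float, area_t: float) -> float:
    """Percent wound closure from scratch areas; negative if the wound widened."""
    if not area_t0 > 0.0:
        raise InvalidBaselineError(f"baseline area must be positive, got {area_t0}")
    # complement form so closure + remaining-area percentage is exactly 100
    return 100.0 - (area_t / area_t0) * 100.0


def _mean_width(widths: Sequence[float], label: str) -> float:
    w = np.asarray(widths, dtype=float)
    if w.size != N_WIDTH_POSITIONS:
        raise SchemaError(
            f"{label}: expected {N_WIDTH_POSITIONS} width positions, got {w.size}"
        )
    if np.any(w < 0):
        raise SchemaError(f"{label}: widths must be nonnegative")
    return float(w.mean())


def width_percent_of_baseline(
    widths_t0: Sequence[float], widths_t: Sequence[float]
) -> float:
    """Remaining scratch width as percent of the 0 h width (means of 5 positions)."""
    w0 = _mean_width(widths_t0, "baseline widths")
    wt = _mean_width(widths_t, "widths")
    if not w0 > 0.0:
        raise InvalidBaselineError(f"mean baseline width must be positive, got {w0}")
    return wt / w0 * 100.0


def width_reduction_percent(
    widths_t0: Sequence[float], widths_t: Sequence[float]
) -> float:
    """Reduction in scratch width over time, in percent of baseline."""
    return 100.0 - width_percent_of_baseline(widths_t0, widths_t)


def rel_expression_neg_dct(ct_target: float, ct_housekeeping: float) -> float:
    """Relative expression by the -dCT method: 2^(-(CT_target - CT_housekeeping))."""
    return float(2.0 ** (-(ct_target - ct_housekeeping)))


def fold_change_vs_control(dct_treated: float, dct_control: float) -> float:
    """Expression fold change of a treated sample against the control (ddCT)."""
    return float(2.0 ** (-(dct_treated - dct_control)))


# ---------------------------------------------------------------------------
# tidy-table helpers (CSV schemas of the pipeline)
# ---------------------------------------------------------------------------

_SCRATCH_COLUMNS = ["sample", "condition", "lps_flag", "time_h", "area"] + [
    f"w{i}" for i in range(1, N_WIDTH_POSITIONS + 1)
]


def scratch_closure_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-sample closure and width percentages for every post-baseline timepoint.

    Input columns: ``sample, condition, lps_flag, time_h, area, w1..w5``; each
    sample needs a ``time_h == 0`` baseline row.
    """
    missing = [c for c in _SCRATCH_COLUMNS if c not in measurements.columns]
    if missing:
        raise SchemaError(f"scratch table missing columns: {missing}")
    wcols = [f"w{i}" for i in range(1, N_WIDTH_POSITIONS + 1)]
    out_rows = []
    for (sample, cond, lps), sub in measurements.groupby(
        ["sample", "condition", "lps_flag"], sort=False
    ):
        base = sub[sub["time_h"] == 0]
        if base.empty:
            raise SchemaError(f"sample {sample!r} has no 0 h baseline row")
        b = base.iloc[0]
        for _, row in sub[sub["time_h"] != 0].iterrows():
            out_rows.append(
                {
                    "sample": sample,
                    "condition": cond,
                    "lps_flag": lps,
                    "time_h": row["time_h"],
                    "closure_pct": wound_closure_percent(b["area"], row["area"]),
                    "width_remaining_pct": width_percent_of_baseline(
                        b[wcols].to_numpy(float), row[wcols].to_numpy(float)
                    ),
                }
            )
    out = pd.DataFrame(out_rows)
    if len(out):
        out["width_reduction_pct"] = 100.0 - out["width_remaining_pct"]
    return out


def ct_expression_table(
    ct_records: pd.DataFrame, control_condition: str = "medium"
) -> pd.DataFrame:
    """Relative expression and fold change vs control from a CT table.

    Input columns: ``sample, condition, gene, ct, housekeeping_ct``.  Technical
    replicates (duplicate rows per sample/condition/gene) are averaged on the
    CT scale.  Output: one row per condition × gene with mean dCT, relative
    expression 2^(-dCT) and fold change vs the control condition.
    """
    required = ["sample", "condition", "gene", "ct", "housekeeping_ct"]
    missing = [c for c in required if c not in ct_records.columns]
    if missing:
        raise SchemaError(f"CT table missing columns: {missing}")
    if control_condition not in set(ct_records["condition"]):
        raise SchemaError(f"control condition {control_condition!r} absent")
    # technical replicates -> one CT pair per sample/condition/gene
    per_sample = (
        ct_records.groupby(["condition", "gene", "sample"], sort=False)[
            ["ct", "housekeeping_ct"]
        ]
        .mean()
        .reset_index()
    )
    per_sample["dct"] = per_sample["ct"] - per_sample["housekeeping_ct"]
    agg = (
        per_sample.groupby(["condition", "gene"], sort=False)["dct"]
        .mean()
        .reset_index()
    )
    ctrl = agg[agg["condition"] == control_condition].set_index("gene")["dct"]
    rows = []
    for _, row in agg.iterrows():
        gene = row["gene"]
        if gene not in ctrl.index:
            raise SchemaError(f"gene {gene!r} missing from control condition")
        rows.append(
            {
                "condition": row["condition"],
                "gene": gene,
                "mean_dct": row["dct"],
                "rel_expression": 2.0 ** (-row["dct"]),
                "fold_change_vs_control": fold_change_vs_control(
                    row["dct"], float(ctrl.loc[gene])
                ),
            }
        )
    return pd.DataFrame(rows)
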