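"""Scratch wound closure and qPCR relative-expression arithmetic.

Generates small synthetic assay tables, then computes percent wound closure
(from areas), remaining scratch width (from five width positions), and
expression fold changes vs the medium control by the dCT method.
"""

from angiocam import (
    CtSimConfig,
    ScratchSimConfig,
    ct_expression_table,
    scratch_closure_table,
    simulate_ct_table,
    simulate_scratch_series,
)

scratch = simulate_scratch_series(ScratchSimConfig(), seed=11)
closure = scratch_closure_table(scratch)
summary = closure.groupby(["condition", "time_h"])[
    ["closure_pct", "width_remaining_pct"]
].mean().round(1)
print("scratch assay (means over 8 samples):")
print(summary)
print()

ct = simulate_ct_table(CtSimConfig(), seed=11)
expression = ct_expression_table(ct, control_condition="medium")
print("qPCR fold change vs medium control:")
pivot = expression.pivot(index="gene", columns="condition",
                         values="fold_change_vs_control").round(2)
print(pivot)
print()
print("Closure of 100% is a fully healed scratch; a fold change of 1 means")
print("expression at the level of the medium control.")
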