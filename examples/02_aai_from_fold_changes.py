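"""Score a treatment from tabulated day-7 fold changes.

The per-parameter angiogenic activity index compares baseline-corrected
group responses (fold changes over day 0) of a treatment against the
control; the final AAI is the mean across parameters.  Inputs here are
typical day-7 mean fold changes of a secretome-treated CAM cohort.
"""

from angiocam import aai_parameter, final_aai, thickness_index

# (control AR, treatment AR) at day 7; AR at day 0 is 1 by construction
day7_fold_changes = {
    "junctions": (1.19, 2.07),
    "total_length": (1.09, 1.36),
    "density": (1.15, 1.45),
}
indices = {
    param: aai_parameter(ar_treat, 1.0, ar_ctrl, 1.0)
    for param, (ar_ctrl, ar_treat) in day7_fold_changes.items()
}
# CAM thickness exists only at the final day: relative difference of medians
indices["thickness"] = thickness_index(76.2, 59.0)

profile = final_aai(indices)
for param, value in profile.indices.items():
    print(f"AAI[{param:13s}] = {value:+.3f}")
print(f"final AAI           = {profile.final_aai:+.3f}")
print()
print("0 means control-level angiogenesis; 1 means the baseline-corrected")
print("response doubled relative to the control group.")
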