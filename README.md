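# angiocam

Quantification of angiogenesis in the chicken chorioallantoic-membrane (CAM)
assay, for researchers who score vascular response to a treatment — a
secretome, a growth factor, a biomaterial eluate — applied onto the CAM over
a one-week window.

The CAM is observed on treatment days 0, 2, 4 and 7.  Starting from
vectorized vessel networks (node coordinates in µm, polyline edges) or from
pre-tabulated per-embryo measurements, the package computes the standard
vessel-network morphometrics, normalizes each embryo to its own day-0
vascularization, estimates embryo survival, and condenses everything into a
single **angiogenic activity index (AAI)** per treatment group.

## The model

For each vascular parameter, the *angiogenic response* AR of a group on day
*d* is the group-mean fold change over day 0.  The per-parameter index
compares baseline-corrected responses of treatment and control:

```
AAI_i = [ (AR_t(d) − AR_t(0)) − (AR_c(d) − AR_c(0)) ] / (AR_c(d) − AR_c(0))
```

and the final index is the arithmetic mean over the *n* scored parameters:

```
final AAI = (1/n) Σ_i AAI_i
```

By construction the control scored against itself gives 0, and a treatment
whose baseline-corrected response is exactly twice the control's gives 1.
Six parameters enter the final AAI: probability of survival (Kaplan–Meier
S(d), with S(0) = 1), number of junctions, branch-hierarchy ratio
((3rd+4th)-degree / (1st+2nd)-degree sprout counts), total vessel length,
vessel density (length per ROI area), and CAM thickness (final day,
relative difference of group medians).  Mean vessel length is reported in
the profile but not indexed.

The morphometrics are defined on a canonicalized vessel graph (degree-2
nodes merged away, so a *segment* is a maximal vessel stretch between branch
points): junctions are nodes of degree ≥ 3, and branch degree is generation
order 1–4 by breadth-first traversal from designated feeder (root) vessels.

A synthetic cohort generator (`angiocam.synthetic`) reproduces the study
design — 3 groups × 17 embryos, group-specific sprouting intensity, embryo
dropout, final-day thickness — together with closed-form expected outcomes
used by the validation suite.  Scratch-assay and qPCR (ΔCT) arithmetic for
the accompanying in vitro readouts lives in `angiocam.assays`.
See `docs/methods.md` for the full model description and design choices.

## Worked example

Score a treatment from tabulated day-7 mean fold changes
(`examples/02_aai_from_fold_changes.py`):

```python
from angiocam import aai_parameter, final_aai, thickness_index

day7 = {"junctions": (1.19, 2.07), "total_length": (1.09, 1.36),
        "density": (1.15, 1.45)}                   # (control, treatment)
indices = {p: aai_parameter(t, 1.0, c, 1.0) for p, (c, t) in day7.items()}
indices["thickness"] = thickness_index(76.2, 59.0)  # group medians, µm
print(final_aai(indices).final_aai)
```

which prints:

```
AAI[junctions    ] = +4.632
AAI[total_length ] = +3.000
AAI[density      ] = +2.000
AAI[thickness    ] = +0.292
final AAI           = +2.481
```

Junction formation responded most strongly (a 4.6-fold excess of
baseline-corrected change over the control); thickness increased 29% over
the control median; the final AAI of +2.5 summarizes a clearly
pro-angiogenic treatment.  The other examples cover raw-network
morphometrics (`examples/01`), full synthetic-cohort scoring with analytic
expectations (`examples/03`), and the in vitro assays (`examples/04`).

A thin CLI mirrors the pipeline:

```bash
angiocam simulate --seed 7 --out sim/           # synthetic cohort bundle
angiocam aai --metrics sim/cohort_metrics.csv \
    --survival sim/cohort_survival.csv \
    --thickness sim/cohort_thickness.csv --out run/
```

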