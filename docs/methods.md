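# Methods

This note documents the quantitative conventions of the package: what is
computed, which definitions were genuinely open and how they were fixed, what
the synthetic-data generator does and does not emulate, and the numerical
choices that matter when reproducing results.

## Vessel-network morphometrics

A vessel network is a planar graph with node coordinates in µm and polyline
edges carrying their Euclidean length.  Measurements are defined on the
**canonicalized** graph, in which every node of degree exactly 2 has been
merged away (polylines concatenated, lengths added), so that an edge is a
*segment*: a maximal vessel stretch between branch points and/or free ends.
Canonicalization is idempotent and conserves total length and junction
structure exactly.  Two degenerate inputs are treated explicitly: self-loop
edges are rejected at validation (isolated vessel loops are outside the data
model), and a degree-2 node whose removal would create a self-loop (a pure
two-edge cycle) is left in place.

* **Junctions** — nodes of graph degree ≥ 3.  Manual counts on micrographs
  carry no formal definition; this is the standard skeleton-graph surrogate.
* **Total / mean vessel length** — sum of segment lengths; mean is
  total / segment count, undefined (NaN) for an empty network.
* **Vessel density** — total vessel length per ROI area, in µm/mm².  No
  universal definition exists for CAM work; length per unit area is the
  common morphometric convention and is recorded in the output metadata.
  The ROI is an annulus (a ring placed on the CAM); 1 mm² = 10⁶ µm².
* **Branch hierarchy** — generation order by breadth-first traversal from
  designated *root* segments (1st-degree feeder vessels), each step one
  degree deeper, capped at degree 4 because only four degrees are scored.
  Generation order was chosen over Strahler order or caliber classes as a
  reproducible surrogate for visual scoring of sprout generations; the
  choice is a convention, not a claim about what human raters do.  When no
  roots are designated, segments touching the ROI outer boundary are taken
  as roots, and failing that the longest segment.  Segments unreachable from
  every root are flagged with a warning and assigned degree 4 (the
  finest-vessel class) so the degree census still sums to the segment count.
  BFS ties are broken by ascending edge id for determinism.
* **Hierarchy ratio** — (3rd+4th) / (1st+2nd) degree segment counts; NaN
  when no low-degree segments exist (a value, not an exception).

## Cohort scoring and the angiogenic activity index

Observation days are 0, 2, 4, 7.  Every fold-change parameter is normalized
per embryo to its day-0 value; the group-level angiogenic response AR is the
**mean of per-embryo fold changes** (±SD, n−1 denominator), i.e. aggregation
is group-mean-first, matching how such data are reported.  Embryos dead
before a day, or with a nonpositive baseline, are excluded from that day's
response.  The per-parameter index is

AAI_i = [(AR_t(d) − AR_t(0)) − (AR_c(d) − AR_c(0))] / (AR_c(d) − AR_c(0)),

which depends only on the ratio of baseline-corrected changes and is
therefore invariant under a common affine rescaling of the responses.  The
final AAI is the unweighted mean of the included parameters.  Indices are
computed for every post-baseline day; day 7 is the headline.

Parameter-specific conventions:

* **Survival** enters as the Kaplan–Meier estimate S(d) with S(0) = 1 as the
  day-0 response (product-limit estimation and the Mantel–Cox log-rank test
  are delegated to `lifelines`; both are verified against hand-computed
  tables in the test suite).  If both groups' survival changes coincide the
  control change is 0 and the parameter is excluded with a logged reason
  rather than producing 0/0.
* **Hierarchy** uses the group-level ratio of branch counts *pooled across
  embryos* before the ratio is formed (robust to per-embryo undefined
  ratios); per-embryo ratios are still reported in the metrics table.  The
  pooled day-0 ratio of the same embryo subset is the baseline.
* **CAM thickness** exists only at the final day, so no day-0 normalization
  is possible; its index is the relative difference of group medians,
  (median_t − median_c)/median_c (medians, because thickness distributions
  are summarized by median and interquartile range).
* **Degenerate control** tolerance: |AR_c(d) − AR_c(0)| < 1e-9 excludes the
  parameter with a recorded reason.
* Mean vessel length and segment counts are reported in the profile but do
  not enter the final AAI, which uses the six parameters listed in the
  README.

One caveat is worth stating: with the definition above, an index of −1
corresponds to *zero* baseline-corrected change in the treatment group (and
−0.5 to a halving), not to "half the control's angiogenesis"; descriptions of
−1 as a halving are inconsistent with the formula and are not adopted here.

## Synthetic cohort generator

The generator emulates the study design the pipeline assumes — one control
and two treatment arms, n = 17 embryos per group, observation days
0/2/4/7 — with a deliberately simple growth process chosen so that every
expected outcome has a closed form:

* **Day-0 network.** Three feeder (root) vessels enter the ROI; 12
  *branching events* are applied, each appending two daughter segments at
  the oldest active tip (uniform-front, first-in-first-out growth).  Day-0
  topology is therefore deterministic (12 junctions, 27 segments); segment
  lengths are log-normal draws (mean 200 µm, SD 100 µm) rescaled so every
  embryo starts at exactly 5 400 µm total length.  The rescaling makes
  per-embryo fold-change expectations exact functions of the rates.
* **Growth.** Between observation days, the number of new branching events
  is Poisson with mean `base_sprout_rate × sprout multiplier × elapsed
  days`; daughters are log-normal with the same shape, scaled by a global
  sprout-length factor (~0.53 — new sprouts are shorter than established
  vessels) and the group's elongation multiplier.  Networks are nested over
  time; there is no pruning, anastomosis or regression.
* **Dropout and thickness.** Deaths occur at whole days with constant daily
  hazard 0.03 (≈ 81% seven-day survival, identical across arms); thickness
  is normal (SD 12 µm) around a group-shifted mean, measured on final-day
  survivors.
* **Randomness.** One independent stream per (seed, group, embryo, purpose),
  so adding embryos or purposes never perturbs existing draws; everything is
  reproducible from a single integer seed.

Default multipliers are calibrated so the *expected* day-7 fold changes are
exactly the study conditions: junctions 1.19 / 2.07 / 2.54 and total vessel
length 1.09 / 1.36 / 1.42 for control and the two treatment arms; thickness
medians 59.0 / 76.2 / 80.5 µm.  (The rbADSC-arm scratch-closure default of
90% at 24 h in the assay simulator is an emulation choice; only the control
and mixed-arm values were fixed by the study conditions.)

Two structural consequences of this generator should be kept in mind when
interpreting green tests: the ROI is fixed, so the **density** fold change
coincides with the total-length fold change; and uniform-front growth makes
the pooled hierarchy ratio an affine function of the junction count, so the
**hierarchy** index coincides with the junction index.  Real CAMs need not
behave this way — passing tests validate the measurement and scoring code,
not biological realism.  The generator also does not emulate measurement
error of manual tracing, vessel regression, spatial heterogeneity inside
the ROI, or inter-day correlation beyond nesting.

## Analytic expectations (`expected_outcome`)

Two flavours are computed per parameter and treatment arm:

* **Plug-in AAI** — the index applied to the expected angiogenic responses.
  This is the design-level quantity: equal arms give exactly 0, a doubled
  baseline-corrected expected change gives exactly 1.
* **Estimator mean** — the expected value of the cohort-level estimator
  itself.  Because the index is a ratio with the (noisy) control change in
  the denominator, the estimator is biased upward by roughly CV² of the
  control change at n = 17; with ~1.3 expected control branching events per
  embryo the bias is several percent and cannot be ignored when averaging
  simulated cohorts.  The estimator mean is computed conditional on the
  parameter not being excluded, using exact inverse-moment sums for Poisson
  (junctions, hierarchy in the affine regime) and binomial (survival)
  denominators, a second-order small-CV expansion for compound-Poisson
  length sums and for the thickness median, and a delta-method fallback for
  non-affine hierarchy regimes.  Distribution sums are truncated at
  mean + 12·SD + 30 terms.

Parameter-recovery tests compare the mean of pipeline-computed indices over
200 simulated cohorts against the estimator mean at a 99% Monte-Carlo
interval; null-calibration tests (two identically parameterized arms) do the
same while also asserting the plug-in value is exactly 0.  Comparing the
simulation mean against the plug-in value instead would conflate estimator
bias with implementation error.

## In vitro assay arithmetic

Wound closure is 100 − (area_t/area_0)·100 (complement form, so closure and
remaining-area percentages sum to exactly 100); width is the arithmetic mean
of five positions and is reported both as remaining width (% of baseline)
and as reduction (the two sum to 100) — remaining width is the primary
readout because that is how such measurements are quoted.  qPCR relative
expression is 2^(−ΔCT) against the housekeeping gene; fold change between
conditions is 2^(−ΔΔCT); technical replicates are averaged on the CT scale
before ΔCT is formed (the averaging scale is a convention; CT-scale
averaging corresponds to geometric averaging of expression).

## Pipeline and I/O

Two ingestion modes exist because CAM measurements are often tabulated
manually: `graphs` (measure vectorized networks) and `metrics`
(pre-tabulated per-embryo table); both converge on the same dataset type and
give identical scores for equivalent inputs.  CSV/JSON outputs serialize
floats at 6 significant digits; internal computation is full precision.
Logs go to standard error, results to files, and each run writes a
plain-text log of every convention applied (density definition, thickness
rule, exclusions).  Problem sizes throughout the test suite (cohort counts,
replicate counts, graph sizes) are the package's own choices, kept small
enough that the full suite runs in a couple of minutes on one CPU.

## Known limitations

* 2-D networks only; no segmentation/skeletonization of raw micrographs.
* Generation-order branch degrees are one of several defensible hierarchy
  definitions; comparisons across scoring conventions need care.
* The AAI is reported without a confidence interval; the estimator-mean
  machinery quantifies its bias but not its sampling distribution.
* The growth model is a statistical stand-in, not a biophysical model of
  angiogenesis.
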