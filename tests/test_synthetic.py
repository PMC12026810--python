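import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from angiocam import (
    CtSimConfig,
    GroupSpec,
    ScratchCondition,
    ScratchSimConfig,
    SimulationConfig,
    branch_degree_counts,
    build_angiogenic_profile,
    compute_metrics,
    ct_expression_table,
    default_config,
    expected_outcome,
    scratch_closure_table,
    simulate_cohort,
    simulate_ct_table,
    simulate_scratch_series,
    simulate_vessel_timecourse,
)


class TestConfig:
    def test_default_calibration_targets(self):
        exp = expected_outcome(default_config())
        assert math.isclose(exp.ar["control"]["junctions"], 1.19, rel_tol=1e-12)
        assert math.isclose(exp.ar["adsc-secretome"]["junctions"], 2.07, rel_tol=1e-9)
        assert math.isclose(exp.ar["mixed-secretome"]["junctions"], 2.54, rel_tol=1e-9)
        assert math.isclose(exp.ar["control"]["total_length"], 1.09, rel_tol=1e-9)
        assert math.isclose(exp.ar["adsc-secretome"]["total_length"], 1.36, rel_tol=1e-9)
        assert math.isclose(exp.ar["mixed-secretome"]["total_length"], 1.42, rel_tol=1e-9)

    def test_control_must_be_neutral(self):
        with pytest.raises(ValueError):
            SimulationConfig(groups=(GroupSpec("control", sprout_multiplier=2.0),))

    def test_invalid_hazard_rejected(self):
        with pytest.raises(ValueError):
            GroupSpec("g", daily_death_hazard=1.0)


class TestTimecourse:
    def test_same_seed_reproduces_day7_metrics(self):
        cfg = default_config(seed=42)
        a = simulate_vessel_timecourse(cfg, 1, 3)
        b = simulate_vessel_timecourse(cfg, 1, 3)
        ma = compute_metrics(a[7], cfg.roi)
        mb = compute_metrics(b[7], cfg.roi)
        assert ma == mb

    def test_zero_multiplier_freezes_network(self):
        cfg = replace(
            default_config(seed=5),
            groups=(GroupSpec("control"),
                    GroupSpec("frozen", sprout_multiplier=0.0,
                              elongation_multiplier=0.0)),
        )
        graphs = simulate_vessel_timecourse(cfg, 1, 0)
        m0 = compute_metrics(graphs[0], cfg.roi)
        for day in (2, 4, 7):
            assert compute_metrics(graphs[day], cfg.roi) == m0

    def test_networks_are_nested_over_time(self):
        cfg = default_config(seed=9)
        graphs = simulate_vessel_timecourse(cfg, 2, 1)
        prev_ids: set[int] = set()
        for day in cfg.days:
            ids = {e.id for e in graphs[day].edges}
            assert prev_ids <= ids
            prev_ids = ids

    def test_day0_counts_follow_construction(self):
        cfg = default_config(seed=11)
        g0 = simulate_vessel_timecourse(cfg, 0, 0)[0]
        m = compute_metrics(g0, cfg.roi)
        assert m.junction_count == cfg.initial_branch_events
        assert m.segment_count == cfg.n_roots + 2 * cfg.initial_branch_events
        assert math.isclose(m.total_length, cfg.initial_total_length_um, rel_tol=1e-9)

    def test_branch_census_matches_degree_sequence(self):
        cfg = default_config(seed=13)
        graphs = simulate_vessel_timecourse(cfg, 1, 2)
        for day in cfg.days:
            m = compute_metrics(graphs[day], cfg.roi)
            events = m.junction_count  # one branching event per junction
            seq = branch_degree_counts(cfg.n_roots, events)
            assert m.branch_counts == tuple(seq[events])

    def test_mc_mean_junction_fold_change_matches_expectation(self):
        cfg = SimulationConfig(
            groups=(GroupSpec("control", daily_death_hazard=0.0),),
            n_embryos=200, seed=77,
        )
        cohort = simulate_cohort(cfg)
        wide = cohort.metrics.pivot_table(index="embryo_id", columns="day",
                                          values="junctions")
        fc = (wide[7] / wide[0]).to_numpy()
        se = fc.std(ddof=1) / math.sqrt(fc.size)
        assert abs(fc.mean() - 1.19) < 3.0 * se


class TestCohort:
    def test_zero_hazard_keeps_everyone_alive(self):
        cfg = replace(
            default_config(seed=2),
            groups=tuple(replace(g, daily_death_hazard=0.0)
                         for g in default_config().groups),
            n_embryos=5,
        )
        cohort = simulate_cohort(cfg)
        assert (cohort.survival["event"] == 0).all()
        assert len(cohort.thickness) == 3 * 5

    def test_cohort_satisfies_dataset_invariants(self, default_cohort):
        default_cohort.validate()

    def test_records_stop_at_death(self, default_cohort):
        died = default_cohort.survival.query("event == 1")
        for _, row in died.iterrows():
            sub = default_cohort.metrics[
                default_cohort.metrics["embryo_id"] == row["embryo_id"]
            ]
            assert (sub["day"] < row["time"]).all()

    def test_same_seed_same_cohort(self):
        cfg = default_config(seed=21)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a.metrics, b.metrics)
        pd.testing.assert_frame_equal(a.survival, b.survival)
        pd.testing.assert_frame_equal(a.thickness, b.thickness)


class TestExpectedOutcome:
    def test_all_equal_groups_plugin_zero(self):
        cfg = replace(
            default_config(),
            groups=(GroupSpec("control"), GroupSpec("twin")),
        )
        exp = expected_outcome(cfg)
        for param, value in exp.aai_plugin["twin"].items():
            assert math.isclose(value, 0.0, abs_tol=1e-12), param
        assert math.isclose(exp.final_aai_plugin["twin"], 0.0, abs_tol=1e-12)

    def test_exact_doubling_plugin_one(self):
        # every baseline-corrected expected change twice the control's:
        # sprouting x2 with unit elongation doubles junction/hierarchy/length
        # changes; survival deficit and thickness shift chosen likewise
        q_ctrl = (1 - 0.03) ** 7
        h_double = 1.0 - (1.0 - 2.0 * (1.0 - q_ctrl)) ** (1 / 7)
        cfg = replace(
            default_config(),
            groups=(
                GroupSpec("control"),
                GroupSpec("double", sprout_multiplier=2.0,
                          elongation_multiplier=1.0,
                          thickness_shift_um=59.0,
                          daily_death_hazard=h_double),
            ),
        )
        exp = expected_outcome(cfg)
        for param, value in exp.aai_plugin["double"].items():
            assert math.isclose(value, 1.0, rel_tol=1e-9), param
        assert math.isclose(exp.final_aai_plugin["double"], 1.0, rel_tol=1e-9)

    def test_tuned_junction_ars_reproduce_worked_index(self):
        exp = expected_outcome(default_config())
        assert math.isclose(exp.aai_plugin["adsc-secretome"]["junctions"],
                            88 / 19, rel_tol=1e-9)
        assert math.isclose(exp.aai_plugin["adsc-secretome"]["junctions"],
                            4.6316, abs_tol=5e-5)

    def test_degenerate_control_reported_excluded(self):
        cfg = replace(
            default_config(),
            base_sprout_rate=0.0,
            groups=(GroupSpec("control"), GroupSpec("t", sprout_multiplier=2.0)),
        )
        exp = expected_outcome(cfg)
        assert "junctions" in exp.excluded["t"]


class TestNullCalibration:
    def test_identical_groups_recover_the_null(self):
        """Two identically-parameterized arms: simulated per-parameter indices
        average to the estimator's expected value, and the expected response
        difference itself is zero."""
        base = default_config()
        cfg0 = replace(
            base, groups=(GroupSpec("control"), GroupSpec("twin"))
        )
        exp = expected_outcome(cfg0)
        assert math.isclose(exp.final_aai_plugin["twin"], 0.0, abs_tol=1e-12)
        vals: dict[str, list[float]] = {}
        R = 80
        for r in range(R):
            cohort = simulate_cohort(replace(cfg0, seed=50_000 + r))
            prof = build_angiogenic_profile(cohort, "twin", day=7)
            for p, v in prof.indices.items():
                vals.setdefault(p, []).append(v)
        for p, series in vals.items():
            v = np.asarray(series)
            se = v.std(ddof=1) / math.sqrt(v.size)
            assert abs(v.mean() - exp.aai_mean["twin"][p]) < 3.0 * se, p


class TestAssaySimulators:
    def test_zero_noise_scratch_is_exact(self):
        cfg = ScratchSimConfig(
            baseline_noise_cv=0.0, closure_noise_sd_pct=0.0,
            width_noise_sd_pct=0.0, n_samples=2,
        )
        out = scratch_closure_table(simulate_scratch_series(cfg, seed=1))
        for cond in cfg.conditions:
            configured = dict(cond.closure_pct)
            widths = dict(cond.width_remaining_pct)
            sub = out[out["condition"] == cond.name]
            for _, row in sub.iterrows():
                assert math.isclose(row["closure_pct"], configured[row["time_h"]],
                                    rel_tol=1e-9)
                assert math.isclose(row["width_remaining_pct"],
                                    widths[row["time_h"]], rel_tol=1e-9)

    def test_scratch_same_seed_reproducible(self):
        cfg = ScratchSimConfig()
        pd.testing.assert_frame_equal(
            simulate_scratch_series(cfg, seed=4), simulate_scratch_series(cfg, seed=4)
        )

    def test_configured_twofold_expression_recovered(self):
        cfg = CtSimConfig(
            conditions=("medium", "treat"),
            genes={"g": {"treat": 2.0}},
            n_samples=100, n_technical=1, ct_noise_sd=0.3,
        )
        table = simulate_ct_table(cfg, seed=8)
        # per-sample fold change estimates against the control-group mean dCT
        per_sample = table.copy()
        per_sample["dct"] = per_sample["ct"] - per_sample["housekeeping_ct"]
        ctrl_mean = per_sample.query("condition == 'medium'")["dct"].mean()
        fc = 2.0 ** (-(per_sample.query("condition == 'treat'")["dct"] - ctrl_mean))
        se = fc.std(ddof=1) / math.sqrt(fc.size)
        assert abs(fc.mean() - 2.0) < 3.0 * se

    def test_ct_same_seed_reproducible(self):
        cfg = CtSimConfig()
        pd.testing.assert_frame_equal(
            simulate_ct_table(cfg, seed=4), simulate_ct_table(cfg, seed=4)
        )
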