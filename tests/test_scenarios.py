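"""Base case, deterministic sensitivity analyses, and comparator projection."""

import numpy as np
import pytest

import survecon as se
from survecon.scenarios import (
    ScenarioSpec,
    bind_curves,
    project_comparator,
    run_base_case,
    run_dsa,
    run_projection_case,
    scale_projection_hrs,
)

PROJ_HRS = {"OS": 0.8975, "RFS": 0.9202, "DMFS": 0.8827}


class TestScenarioSpec:
    def test_unknown_key_rejected(self):
        with pytest.raises(KeyError, match="no_such_knob"):
            ScenarioSpec("bad", {"no_such_knob": 1})

    def test_known_keys_accepted(self):
        ScenarioSpec(
            "ok",
            {"discount_rate": 0.0, "horizon": 120.0, "lr_share": 0.2, "hr_shift": 1.1},
        )


class TestRunBaseCase:
    def test_comparator_vs_itself_undefined_icer(self, fitted_inputs):
        import dataclasses

        inputs = dataclasses.replace(fitted_inputs, treatment_arm="observation")
        inputs.econ = inputs.econ.with_overrides(treatment_cost_per_cycle={})
        ce_a, ce_b, icer = run_base_case(inputs)
        assert icer.delta_qaly == pytest.approx(0.0, abs=1e-12)
        assert icer.icer is None

    def test_synthetic_fixture_positive_gain(self, fitted_inputs):
        ce_t, ce_c, icer = run_base_case(fitted_inputs)
        assert ce_t.total_qaly > ce_c.total_qaly  # treatment arm was simulated superior
        assert ce_t.total_cost > ce_c.total_cost
        assert icer.icer is not None and icer.icer > 0

    def test_removing_drug_costs_lowers_incremental_cost(self, fitted_inputs):
        import dataclasses

        _, _, icer_base = run_base_case(fitted_inputs)
        inputs = dataclasses.replace(
            fitted_inputs,
            econ=fitted_inputs.econ.with_overrides(treatment_cost_per_cycle={}),
        )
        _, _, icer_nodrug = run_base_case(inputs)
        assert icer_nodrug.delta_cost < icer_base.delta_cost
        assert icer_nodrug.delta_qaly == pytest.approx(icer_base.delta_qaly)

    def test_determinism(self, fitted_inputs):
        a = run_base_case(fitted_inputs)
        b = run_base_case(fitted_inputs)
        assert a[0].total_cost == b[0].total_cost
        assert a[2].icer == b[2].icer


class TestExponentialFixtureClosedForm:
    def test_icer_matches_annuity_algebra(self, exp_curves, life_table):
        # flat costs/utilities on known exponential curves: the ICER reduces
        # to closed-form geometric sums over cycle boundaries
        cfg = se.ModelConfig(horizon=600.0)
        econ = se.EconomicsConfig(
            utility_rfs=1.0, utility_lr=1.0, utility_dm=1.0,
            cost_rfs_per_cycle=0.0, cost_lr_per_cycle=0.0,
            cost_dm1_per_cycle=0.0, cost_dm2_per_cycle=0.0,
            treatment_cost_per_cycle={"treatment": 10000.0},
            ae_cost=0.0, palliative_cost=0.0, discount_rate=0.03,
        )
        from survecon.cohort import run_cohort
        from survecon.economics import accumulate, compute_icer
        from conftest import ExpSurv

        better = dict(exp_curves)
        better["OS"] = ExpSurv(0.005)
        better["RFS"] = ExpSurv(0.01)
        tr_t = run_cohort(cfg, better)
        tr_c = run_cohort(cfg, exp_curves)
        icer = compute_icer(
            accumulate(tr_t, econ, "treatment"), accumulate(tr_c, econ, "observation")
        )

        def disc_ly(rate_os):
            k = np.arange(100)
            x = np.exp(-rate_os * 6.0) * 1.03 ** (-0.5)
            return 0.5 * (1 - x**100) / (1 - x)

        d_qaly = disc_ly(0.005) - disc_ly(0.01)
        # treatment cost: cycles at t=0 and t=6 weighted by S_RFS
        d_cost = 10000.0 * (1 + np.exp(-0.01 * 6) * 1.03 ** (-0.5))
        assert icer.delta_qaly == pytest.approx(d_qaly, rel=1e-12)
        assert icer.delta_cost == pytest.approx(d_cost, rel=1e-12)
        assert icer.icer == pytest.approx(d_cost / d_qaly, rel=1e-12)


class TestRunDSA:
    def test_empty_scenarios_gives_base_row(self, fitted_inputs):
        table = run_dsa(fitted_inputs, [])
        assert list(table["scenario"]) == ["base case"]

    def test_undiscounted_increases_qaly(self, fitted_inputs):
        table = run_dsa(fitted_inputs, [ScenarioSpec("undiscounted", {"discount_rate": 0.0})])
        base, undisc = table.iloc[0], table.iloc[1]
        assert undisc["qaly_treatment"] > base["qaly_treatment"]
        assert undisc["qaly_comparator"] > base["qaly_comparator"]

    def test_hr_shift_pair_brackets_survival(self, fitted_inputs):
        table = run_dsa(
            fitted_inputs,
            [
                ScenarioSpec("curves down", {"hr_shift": 1.1}),
                ScenarioSpec("curves up", {"hr_shift": 0.9}),
            ],
        )
        base, down, up = table.iloc[0], table.iloc[1], table.iloc[2]
        assert down["qaly_treatment"] < base["qaly_treatment"] < up["qaly_treatment"]
        # every row's ICER equals the ratio of its own columns
        for _, row in table.iterrows():
            assert row["icer"] == pytest.approx(
                (row["cost_treatment"] - row["cost_comparator"])
                / (row["qaly_treatment"] - row["qaly_comparator"]),
                rel=1e-9,
            )

    def test_shorter_cycles_change_icer_moderately(self, fitted_inputs):
        table = run_dsa(fitted_inputs, [ScenarioSpec("monthly", {"cycle_length": 1.0})])
        base, monthly = table.iloc[0]["icer"], table.iloc[1]["icer"]
        assert abs(monthly - base) / base < 0.10

    def test_deterministic_tables(self, fitted_inputs):
        scens = [ScenarioSpec("undiscounted", {"discount_rate": 0.0})]
        t1 = run_dsa(fitted_inputs, scens)
        t2 = run_dsa(fitted_inputs, scens)
        assert t1.equals(t2)


class TestProjection:
    def test_identity_hrs_reproduce_reference(self, fitted_inputs):
        curves_ref = bind_curves(fitted_inputs, fitted_inputs.config, fitted_inputs.treatment_arm)
        curves_proj = project_comparator(fitted_inputs, {"OS": 1.0, "RFS": 1.0, "DMFS": 1.0})
        t = np.linspace(0, 300, 31)
        for ep in ("OS", "RFS", "DMFS"):
            assert np.allclose(
                np.asarray(curves_ref[ep].survival(t)),
                np.asarray(curves_proj[ep].survival(t)),
                atol=1e-12,
            )

    def test_scaling_matches_reported_rounding(self):
        assert scale_projection_hrs(PROJ_HRS, 0.8) == {"OS": 0.72, "RFS": 0.74, "DMFS": 0.71}
        assert scale_projection_hrs(PROJ_HRS, 1.2) == {"OS": 1.08, "RFS": 1.10, "DMFS": 1.06}

    def test_ph_ordering(self, fitted_inputs):
        # HR(reference vs projected) < 1 means the reference is better:
        # projected survival never exceeds the reference
        curves_ref = bind_curves(fitted_inputs, fitted_inputs.config, fitted_inputs.treatment_arm)
        curves_proj = project_comparator(fitted_inputs, PROJ_HRS)
        t = np.linspace(0, 120, 25)
        assert np.all(
            np.asarray(curves_proj["OS"].survival(t))
            <= np.asarray(curves_ref["OS"].survival(t)) + 1e-12
        )

    def test_missing_endpoint_rejected(self, fitted_inputs):
        with pytest.raises(KeyError, match="DMFS"):
            project_comparator(fitted_inputs, {"OS": 0.9, "RFS": 0.9})

    def test_projection_case_between_arms(self, fitted_inputs):
        # a projected strategy with HR < 1 vs the reference lies between the
        # fitted arms in effectiveness
        ce_t, ce_c, _ = run_base_case(fitted_inputs)
        ce_p, ce_c2, icer = run_projection_case(fitted_inputs, projected_label="treatment")
        assert ce_c2.total_qaly == pytest.approx(ce_c.total_qaly)
        assert ce_c.total_qaly < ce_p.total_qaly < ce_t.total_qaly
        assert icer.icer is not None

    def test_hr_scale_moves_effectiveness(self, fitted_inputs):
        ce_low, _, _ = run_projection_case(fitted_inputs, "treatment", hr_scale=0.8)
        ce_mid, _, _ = run_projection_case(fitted_inputs, "treatment")
        ce_high, _, _ = run_projection_case(fitted_inputs, "treatment", hr_scale=1.2)
        # smaller HR(reference vs projected) pulls the projection down
        assert ce_low.total_qaly < ce_mid.total_qaly < ce_high.total_qaly


def test_dsa_bar_chart_writes_file(tmp_path, fitted_inputs):
    from survecon.scenarios import dsa_bar_chart

    table = run_dsa(fitted_inputs, [])
    out = tmp_path / "dsa.png"
    dsa_bar_chart(table, str(out))
    assert out.exists() and out.stat().st_size > 0
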