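"""Base-case and deterministic sensitivity-analysis orchestration.

Ties the pipeline together: reconstructed pseudo-IPD -> AIC-selected
parametric fits -> life-table-blended curves -> cohort traces for the
treated and comparator strategies -> discounted cost/QALY totals and
the ICER.  Scenario specifications override named configuration keys
(discount rate, horizon, state shares, hazard multipliers, convergence
window, uniform curve shifts, ...) and every result row re-validates
its own ICER from its cost/QALY columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import ModelConfig, REQUIRED_ENDPOINTS, run_cohort
from .curves import AtRiskTable, DigitizedCurve, reconstruct_pseudo_ipd
from .economics import CEResult, EconomicsConfig, ICERRecord, accumulate, compute_icer
from .indirect import HazardRatio
from .survival import (
    LifeTable,
    ParametricFit,
    apply_hazard_ratio,
    blend_with_life_table,
    fit_all_families,
    select_by_aic,
)

#: endpoints whose extrapolation converges to background mortality
TRIAL_ENDPOINTS = ("RFS", "OS", "DMFS")
#: progression curves driving the Markov sub-model (kept parametric)
SUBMODEL_ENDPOINTS = ("1LPFS", "2LOS")

_MODEL_KEYS = {
    "starting_age", "cycle_length", "horizon", "discount_rate", "lr_share",
    "lr_to_dm_hr", "lr_mortality_hr", "t_obs", "t_conv", "submodel_clock",
    "half_cycle_correction",
}
# discount_rate lives on both configs and is routed to both
_ECON_KEYS = {
    "discount_rate", "utility_rfs", "utility_lr", "utility_dm", "cost_rfs_per_cycle",
    "cost_lr_per_cycle", "cost_dm1_per_cycle", "cost_dm2_per_cycle",
    "treatment_duration", "ae_cost", "palliative_cost", "age_decrement",
    "age_decrement_enabled", "age_decrement_threshold", "ae_utility_decrement",
}
_SPECIAL_KEYS = {"hr_shift", "projection_hr_scale"}


@dataclass(frozen=True)
class ScenarioSpec:
    """A named set of flat overrides onto the model/economics configuration.

    Besides configuration fields, two special keys are understood:
    ``hr_shift`` applies a uniform hazard multiplier to the RFS/DMFS/OS
    curves of both arms (survival-shift scenarios) and
    ``projection_hr_scale`` rescales the projection hazard-ratio set.
    """

    name: str
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.overrides) - _MODEL_KEYS - _ECON_KEYS - _SPECIAL_KEYS
        if unknown:
            raise KeyError(f"unknown override key(s) in scenario {self.name!r}: {sorted(unknown)}")


@dataclass
class AnalysisInputs:
    """Fitted survival models plus configuration: everything a run needs."""

    config: ModelConfig
    econ: EconomicsConfig
    fits: dict[tuple[str, str], ParametricFit]  # (endpoint, arm) -> selected fit
    life_table: LifeTable
    treatment_arm: str = "treatment"
    comparator_arm: str = "observation"
    projection_hrs: dict[str, float] | None = None  # endpoint -> HR (reference vs projected)


def fits_from_curves(
    curves: dict[tuple[str, str], DigitizedCurve],
    at_risk: dict[tuple[str, str], AtRiskTable],
) -> dict[tuple[str, str], ParametricFit]:
    """Reconstruct pseudo-IPD for every bound curve and AIC-select a family."""
    fits = {}
    for key, curve in curves.items():
        ipd = reconstruct_pseudo_ipd(curve, at_risk[key])
        fits[key] = select_by_aic(fit_all_families(ipd))
    return fits


def bind_curves(
    inputs: AnalysisInputs,
    config: ModelConfig,
    arm: str,
    hr_shift: float = 1.0,
    projection_hr: dict[str, float] | None = None,
) -> dict[str, object]:
    """Build the five bound survival curves for one arm.

    Trial endpoints get the life-table-converging extrapolation; the
    sub-model progression curves stay parametric.  ``hr_shift``
    uniformly scales the trial-endpoint hazards (sensitivity scenarios);
    ``projection_hr`` maps endpoints to HR(reference vs this arm), used
    when this arm is a proportional-hazards projection of the reference
    arm's fits rather than fitted from its own curves.
    """
    bound: dict[str, object] = {}
    for ep in TRIAL_ENDPOINTS:
        if projection_hr is not None:
            base_fit = inputs.fits[(ep, inputs.treatment_arm)]
            hr = hr_shift / projection_hr[ep]
        else:
            base_fit = inputs.fits[(ep, arm)]
            hr = hr_shift
        base = apply_hazard_ratio(base_fit, hr) if hr != 1.0 else base_fit
        bound[ep] = blend_with_life_table(
            base,
            inputs.life_table,
            config.starting_age,
            t_obs=config.t_obs,
            t_conv=config.t_conv,
            horizon=max(config.horizon, config.t_conv + config.cycle_length),
        )
    for ep in SUBMODEL_ENDPOINTS:
        key = (ep, arm) if (ep, arm) in inputs.fits else (ep, inputs.treatment_arm)
        bound[ep] = inputs.fits[key]
    return bound


def _split_overrides(overrides: dict) -> tuple[dict, dict, dict]:
    model = {k: v for k, v in overrides.items() if k in _MODEL_KEYS}
    econ = {k: v for k, v in overrides.items() if k in _ECON_KEYS}
    special = {k: v for k, v in overrides.items() if k in _SPECIAL_KEYS}
    return model, econ, special


def _run_strategy(
    inputs: AnalysisInputs,
    config: ModelConfig,
    econ: EconomicsConfig,
    arm: str,
    hr_shift: float = 1.0,
    projection_hr: dict[str, float] | None = None,
) -> CEResult:
    curves = bind_curves(inputs, config, arm, hr_shift=hr_shift, projection_hr=projection_hr)
    trace = run_cohort(config, curves)
    return accumulate(trace, econ, strategy=arm)


def run_base_case(
    inputs: AnalysisInputs,
    overrides: dict | None = None,
) -> tuple[CEResult, CEResult, ICERRecord]:
    """Run treated and comparator strategies and compare them.

    Returns (CEResult treatment, CEResult comparator, ICER record) with
    the state-wise decomposition carried on each CEResult.
    """
    model_ov, econ_ov, special = _split_overrides(overrides or {})
    config = inputs.config.with_overrides(**model_ov)
    econ = inputs.econ.with_overrides(**econ_ov)
    hr_shift = float(special.get("hr_shift", 1.0))

    ce_t = _run_strategy(inputs, config, econ, inputs.treatment_arm, hr_shift=hr_shift)
    ce_c = _run_strategy(inputs, config, econ, inputs.comparator_arm, hr_shift=hr_shift)
    icer = compute_icer(ce_t, ce_c)
    return ce_t, ce_c, icer


def run_projection_case(
    inputs: AnalysisInputs,
    projected_label: str = "projected",
    hr_scale: float = 1.0,
    overrides: dict | None = None,
) -> tuple[CEResult, CEResult, ICERRecord]:
    """Evaluate a strategy projected onto the reference arm's fitted curves.

    The projected strategy's trial-endpoint curves are the reference
    (treatment) arm's fits under proportional hazards with
    HR(reference vs projected) from ``inputs.projection_hrs``, i.e.
    S_proj = S_ref^(1/HR); it is compared against the comparator arm
    fitted from its own curves.  ``hr_scale`` rescales the HR set (the
    +/-20% scenarios) with two-decimal rounding after scaling.
    Treatment costs apply to the projected strategy if
    ``projected_label`` appears in the economics treatment-cost map.
    """
    if inputs.projection_hrs is None:
        raise ValueError("AnalysisInputs.projection_hrs is not set")
    model_ov, econ_ov, special = _split_overrides(overrides or {})
    config = inputs.config.with_overrides(**model_ov)
    econ = inputs.econ.with_overrides(**econ_ov)
    hr_scale = float(special.get("projection_hr_scale", hr_scale))
    proj = (
        scale_projection_hrs(inputs.projection_hrs, hr_scale)
        if hr_scale != 1.0
        else dict(inputs.projection_hrs)
    )

    curves = bind_curves(inputs, config, inputs.treatment_arm, projection_hr=proj)
    trace = run_cohort(config, curves)
    ce_p = accumulate(trace, econ, strategy=projected_label)
    ce_c = _run_strategy(inputs, config, econ, inputs.comparator_arm)
    return ce_p, ce_c, compute_icer(ce_p, ce_c)


def run_dsa(inputs: AnalysisInputs, scenarios: list[ScenarioSpec]) -> pd.DataFrame:
    """Run the base case plus every scenario; one validated row each.

    Columns: scenario, cost_treatment, cost_comparator, qaly_treatment,
    qaly_comparator, icer (full precision) plus display-rounded
    companions (costs to 0.1 T-euro, QALY to 0.01, ICER to 0.1
    T-euro/QALY).  Each row's ICER is recomputed from its own columns.
    """
    rows = []
    for spec in [ScenarioSpec("base case"), *scenarios]:
        ce_t, ce_c, icer = run_base_case(inputs, spec.overrides)
        check = compute_icer(ce_t.total_cost, ce_c.total_cost,
                             qaly_a=ce_t.total_qaly, qaly_b=ce_c.total_qaly)
        assert icer.icer is None or abs(check.icer - icer.icer) < 1e-9
        rows.append(
            {
                "scenario": spec.name,
                "cost_treatment": ce_t.total_cost,
                "cost_comparator": ce_c.total_cost,
                "qaly_treatment": ce_t.total_qaly,
                "qaly_comparator": ce_c.total_qaly,
                "icer": icer.icer,
                "cost_treatment_te": round(ce_t.total_cost / 1000.0, 1),
                "cost_comparator_te": round(ce_c.total_cost / 1000.0, 1),
                "qaly_treatment_rounded": round(ce_t.total_qaly, 2),
                "qaly_comparator_rounded": round(ce_c.total_qaly, 2),
                "icer_te_per_qaly": None if icer.icer is None else round(icer.icer / 1000.0, 1),
            }
        )
    return pd.DataFrame(rows)


def project_comparator(
    inputs: AnalysisInputs,
    hr_set: dict[str, float] | dict[str, HazardRatio],
    scale: float = 1.0,
) -> dict[str, object]:
    """Bound curve set for a comparator projected from the reference arm.

    ``hr_set`` gives HR(reference vs comparator) per trial endpoint;
    the comparator's survival is S_ref(t)^(1/HR).  ``scale`` rescales
    the HRs (the +/-20% sensitivity scenarios), with two-decimal
    rounding applied after scaling, matching the display convention of
    reported hazard ratios.
    """
    missing = [ep for ep in TRIAL_ENDPOINTS if ep not in hr_set]
    if missing:
        raise KeyError(f"projection hazard ratios missing for endpoint(s): {missing}")
    points = {
        ep: (h.point if isinstance(h, HazardRatio) else float(h)) for ep, h in hr_set.items()
    }
    hrs = scale_projection_hrs(points, scale) if scale != 1.0 else points
    return bind_curves(inputs, inputs.config, inputs.comparator_arm, projection_hr=hrs)


def scale_projection_hrs(hr_set: dict[str, float], scale: float) -> dict[str, float]:
    """Rescale projection HRs by ``scale`` and round to two decimals."""
    return {ep: round(hr * scale, 2) for ep, hr in hr_set.items()}


def dsa_bar_chart(table: pd.DataFrame, path: str) -> None:
    """Horizontal bar chart of scenario ICERs (simple tornado-style helper)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = table.dropna(subset=["icer"])
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(df) + 1.5))
    ax.barh(df["scenario"], df["icer"] / 1000.0, color="#4878d0")
    ax.set_xlabel("ICER (thousand € per QALY)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
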