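"""Synthetic trial, life-table and economics inputs for end-to-end testing.

Real inputs to the pipeline are digitized survival curves with their
at-risk tables, a national life table, and a cost/utility
configuration.  None of these ship with the package: this module
generates shape-plausible stand-ins — two-arm adjuvant-melanoma-like
trials with proportional-hazards arm effects and right-censoring,
progression curves for the Markov sub-model, a Gompertz–Makeham life
table, and a placeholder economics configuration — with every ground
truth recorded so recovery tests can compare against it.

The generated curves emulate the published trial inputs (five-year
follow-up, monthly curve grid, six-monthly at-risk counts) but are not
reconstructions of any actual trial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .curves import AtRiskTable, DigitizedCurve, PseudoIPD, km_estimate
from .economics import EconomicsConfig
from .survival import LifeTable

#: per-endpoint event-time distributions for the reference (observation) arm
#: and treatment-arm hazard ratios, loosely shaped like five-year adjuvant
#: melanoma follow-up (events in months).
DEFAULT_ENDPOINT_SPECS = {
    # ~45% relapse-free at 5 years under observation; strong treatment effect
    "RFS": {"family": "weibull", "params": {"shape": 0.9, "scale": 75.0}, "hr": 0.51},
    "OS": {"family": "weibull", "params": {"shape": 1.2, "scale": 160.0}, "hr": 0.57},
    "DMFS": {"family": "weibull", "params": {"shape": 0.95, "scale": 90.0}, "hr": 0.53},
    # progression curves: first-line PFS and second-line OS after distant relapse
    "1LPFS": {"family": "lognormal", "params": {"mu": 2.6, "sigma": 1.1}, "hr": 1.0},
    "2LOS": {"family": "lognormal", "params": {"mu": 3.0, "sigma": 1.0}, "hr": 1.0},
}


@dataclass(frozen=True)
class TrialSpec:
    """Specification of a simulated two-arm trial.

    ``endpoint_specs`` maps endpoint name to a dict with keys
    ``family`` (weibull/exponential/lognormal/loglogistic/gamma),
    ``params`` (reference-arm parameters) and ``hr`` (treatment-arm
    hazard ratio).  Censoring combines administrative cut-off at
    ``admin_censor_months`` with uniform dropout over follow-up at rate
    ``dropout_rate`` (fraction of subjects).
    """

    n_per_arm: int = 450
    endpoint_specs: dict = field(default_factory=lambda: dict(DEFAULT_ENDPOINT_SPECS))
    admin_censor_months: float = 60.0
    dropout_rate: float = 0.15
    seed: int = 0
    arms: tuple[str, str] = ("treatment", "observation")
    curve_grid_months: float = 1.0
    at_risk_every_months: float = 6.0

    def __post_init__(self):
        if self.n_per_arm < 2:
            raise ValueError("need at least 2 subjects per arm")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        for ep, spec in self.endpoint_specs.items():
            if spec.get("hr", 1.0) <= 0:
                raise ValueError(f"{ep}: hazard ratio must be positive")


@dataclass
class SyntheticBundle:
    """Everything one pipeline run needs, with the generating truth attached."""

    spec: TrialSpec
    ipd: dict[tuple[str, str], PseudoIPD]  # (endpoint, arm) -> subject records
    curves: dict[tuple[str, str], DigitizedCurve]
    at_risk: dict[tuple[str, str], AtRiskTable]
    life_table: LifeTable
    economics: EconomicsConfig
    true_event_counts: dict[tuple[str, str], int]


def _draw_event_times(rng, family: str, params: dict, hr: float, n: int) -> np.ndarray:
    """Inverse-CDF sampling of S_ref(t)^hr via U^(1/hr) on the reference CDF."""
    u = rng.uniform(size=n) ** (1.0 / hr)  # S(T) ~ U^(1/hr) under PH
    if family == "exponential":
        return -np.log(u) / params["rate"]
    if family == "weibull":
        return params["scale"] * (-np.log(u)) ** (1.0 / params["shape"])
    if family == "lognormal":
        from scipy import stats

        return stats.lognorm.isf(u, params["sigma"], scale=math.exp(params["mu"]))
    if family == "loglogistic":
        return params["alpha"] * (1.0 / u - 1.0) ** (1.0 / params["beta"])
    if family == "gamma":
        from scipy import stats

        return stats.gamma.isf(u, params["shape"], scale=params["scale"])
    raise ValueError(f"unknown family {family!r}")


def simulate_trial(spec: TrialSpec) -> SyntheticBundle:
    """Simulate the trial and package curves, at-risk tables and configs.

    Deterministic given ``spec.seed``: the same spec always yields an
    identical bundle.
    """
    rng = np.random.default_rng(spec.seed)
    ipd: dict[tuple[str, str], PseudoIPD] = {}
    curves: dict[tuple[str, str], DigitizedCurve] = {}
    at_risk: dict[tuple[str, str], AtRiskTable] = {}
    true_events: dict[tuple[str, str], int] = {}

    for endpoint, espec in spec.endpoint_specs.items():
        for arm in spec.arms:
            hr = espec.get("hr", 1.0) if arm == spec.arms[0] else 1.0
            t_event = _draw_event_times(rng, espec["family"], espec["params"], hr, spec.n_per_arm)
            t_cens = np.full(spec.n_per_arm, spec.admin_censor_months)
            n_drop = rng.binomial(spec.n_per_arm, spec.dropout_rate)
            if n_drop > 0:
                drop_idx = rng.choice(spec.n_per_arm, size=n_drop, replace=False)
                t_cens[drop_idx] = np.minimum(
                    t_cens[drop_idx],
                    rng.uniform(0.0, spec.admin_censor_months, size=n_drop),
                )
            time = np.minimum(t_event, t_cens)
            event = t_event <= t_cens
            time = np.maximum(time, 1e-6)
            records = tuple(zip(time.tolist(), event.tolist()))
            key = (endpoint, arm)
            ipd[key] = PseudoIPD(endpoint, arm, records)
            true_events[key] = int(event.sum())
            curves[key] = _sample_curve(ipd[key], spec)
            at_risk[key] = _sample_at_risk(ipd[key], spec)

    return SyntheticBundle(
        spec=spec,
        ipd=ipd,
        curves=curves,
        at_risk=at_risk,
        life_table=synthetic_life_table(),
        economics=fixture_economics(),
        true_event_counts=true_events,
    )


def _sample_curve(ipd: PseudoIPD, spec: TrialSpec) -> DigitizedCurve:
    """KM estimate of the simulated arm sampled on the monthly figure grid."""
    km = km_estimate(ipd)
    t_max = min(spec.admin_censor_months, float(ipd.times.max()))
    grid = np.arange(0.0, t_max + spec.curve_grid_months / 2, spec.curve_grid_months)
    pts = tuple((float(t), km.survival_at(float(t))) for t in grid)
    return DigitizedCurve(ipd.endpoint, ipd.arm, pts)


def _sample_at_risk(ipd: PseudoIPD, spec: TrialSpec) -> AtRiskTable:
    t_max = min(spec.admin_censor_months, float(ipd.times.max()))
    grid = np.arange(0.0, t_max + 1e-9, spec.at_risk_every_months)
    counts = [(ipd.times >= t - 1e-12).sum() for t in grid]
    entries = tuple((float(t), int(c)) for t, c in zip(grid, counts))
    return AtRiskTable(ipd.endpoint, ipd.arm, entries)


def synthetic_life_table(
    a: float = 5e-4, b: float = 3e-5, c: float = 0.1, max_age: int = 110
) -> LifeTable:
    """Gompertz–Makeham annual death probabilities q = 1 - exp(-(a + b e^{c age})).

    The defaults give adult mortality of a plausible modern national
    life table (q(50) < 1%, q(95) > 20%), standing in for official
    period life tables.
    """
    ages = tuple(range(0, max_age + 1))
    qx = []
    for age in ages:
        q = 1.0 - math.exp(-(a + b * math.exp(c * age)))
        if not (0.0 <= q <= 1.0):
            raise ValueError(f"Makeham parameters give q={q:.3g} at age {age}")
        qx.append(q)
    return LifeTable(ages, tuple(qx))


def fixture_economics() -> EconomicsConfig:
    """Synthetic placeholder cost/utility configuration.

    Utility ordering (relapse-free > locoregional > distant metastasis)
    and the ~700 euro one-off adverse-event cost follow the modelled
    setting; all other figures are round placeholder values on the
    right order of magnitude for a European payer perspective, intended
    for tests and worked examples, not for policy conclusions.
    """
    return EconomicsConfig(
        utility_rfs=0.87,
        utility_lr=0.80,
        utility_dm=0.68,
        cost_rfs_per_cycle=250.0,  # follow-up visits, per 6 months
        cost_lr_per_cycle=400.0,
        cost_dm1_per_cycle=14000.0,  # 1st-line treatment mix, per 6 months
        cost_dm2_per_cycle=3000.0,  # best supportive care, per 6 months
        treatment_cost_per_cycle={"treatment": 42000.0},  # adjuvant phase, per 6 months
        treatment_duration=12.0,
        ae_cost=700.0,
        palliative_cost=4000.0,
        discount_rate=0.03,
    )
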