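"""Costs, utilities, discounting and cost-effectiveness endpoints.

Person-time in each model state is valued with a state utility
(QALY weight per year) and a half-year state cost; adjuvant treatment
cost accrues over the 12-month treatment phase weighted by relapse-free
occupancy (treatment stops at relapse); a one-off adverse-event cost is
charged at treatment start; palliative care is one 6-month block
attached to each cycle's death inflow.  Everything is discounted at the
configured annual rate, evaluated at cycle start times.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import CohortTrace


@dataclass(frozen=True)
class EconomicsConfig:
    """Cost and utility inputs, in euros and QALY weights per year.

    ``treatment_cost_per_cycle`` maps a strategy label to the adjuvant
    drug cost per model cycle during the 12-month treatment phase
    (untreated strategies are simply absent).  State costs are per
    6-month cycle of occupancy and are rescaled proportionally for
    other cycle lengths.
    """

    utility_rfs: float
    utility_lr: float
    utility_dm: float
    cost_rfs_per_cycle: float
    cost_lr_per_cycle: float
    cost_dm1_per_cycle: float
    cost_dm2_per_cycle: float
    treatment_cost_per_cycle: dict[str, float] = field(default_factory=dict)
    treatment_duration: float = 12.0  # months of adjuvant therapy
    ae_cost: float = 700.0  # one-off adverse-event cost per treated patient
    palliative_cost: float = 0.0  # per 6-month terminal block
    discount_rate: float = 0.03
    age_decrement: float = 0.00029  # QALY per life-year beyond the threshold age
    age_decrement_enabled: bool = False
    age_decrement_threshold: float = 65.0
    ae_utility_decrement: float = 0.0  # optional lifetime QALY decrement per treated patient
    reference_cycle_length: float = 6.0

    def __post_init__(self):
        for u in (self.utility_rfs, self.utility_lr, self.utility_dm):
            if not (0.0 <= u <= 1.0):
                raise ValueError(f"utilities must lie in [0, 1], got {u}")
        for c in (
            self.cost_rfs_per_cycle,
            self.cost_lr_per_cycle,
            self.cost_dm1_per_cycle,
            self.cost_dm2_per_cycle,
            self.ae_cost,
            self.palliative_cost,
        ):
            if c < 0:
                raise ValueError("costs must be non-negative")

    def with_overrides(self, **kw) -> "EconomicsConfig":
        return replace(self, **kw)


@dataclass
class CEResult:
    """Discounted life-years, QALYs and costs, broken down by health state.

    Mirrors the usual table layout of partitioned-survival evaluations:
    life-years and QALYs by relapse-free / locoregional / distant-
    metastasis state, costs by treatment / follow-up / state category.
    Distant metastasis pools DM1 and DM2; palliative care is included
    in the distant-metastasis cost category.
    """

    strategy: str
    ly: dict[str, float]
    qaly: dict[str, float]
    costs: dict[str, float]
    age_decrement_qaly: float = 0.0

    @property
    def total_ly(self) -> float:
        return sum(self.ly.values())

    @property
    def total_qaly(self) -> float:
        return sum(self.qaly.values()) - self.age_decrement_qaly

    @property
    def total_cost(self) -> float:
        return sum(self.costs.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for state, v in self.ly.items():
            rows.append({"measure": "LY", "component": state, "value": v})
        for state, v in self.qaly.items():
            rows.append({"measure": "QALY", "component": state, "value": v})
        if self.age_decrement_qaly:
            rows.append(
                {"measure": "QALY", "component": "age_decrement", "value": -self.age_decrement_qaly}
            )
        for cat, v in self.costs.items():
            rows.append({"measure": "cost_eur", "component": cat, "value": v})
        rows.append({"measure": "LY", "component": "total", "value": self.total_ly})
        rows.append({"measure": "QALY", "component": "total", "value": self.total_qaly})
        rows.append({"measure": "cost_eur", "component": "total", "value": self.total_cost})
        df = pd.DataFrame(rows)
        df.insert(0, "strategy", self.strategy)
        return df


def discount_factor(t_years, rate: float):
    """Present-value factor (1+rate)^(-t) for time in years."""
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    t = np.asarray(t_years, dtype=float)
    out = np.power(1.0 + rate, -t)
    return out if out.shape else float(out)


def apply_age_decrement(
    ly_by_cycle: np.ndarray,
    times_months: np.ndarray,
    age0: float,
    decrement: float,
    rate: float = 0.0,
    threshold: float = 65.0,
) -> float:
    """QALY subtraction for discounted person-years lived beyond the threshold age.

    ``ly_by_cycle`` holds undiscounted person-years alive per cycle
    (cycle start times in ``times_months``); the decrement applies only
    to person-time at ages beyond ``threshold``.
    """
    if decrement < 0:
        raise ValueError("decrement must be non-negative")
    ages = age0 + np.asarray(times_months, dtype=float) / 12.0
    over = ages >= threshold
    disc = discount_factor(np.asarray(times_months, dtype=float) / 12.0, rate)
    return float(decrement * np.sum(ly_by_cycle[over] * disc[over]))


def accumulate(trace: CohortTrace, econ: EconomicsConfig, strategy: str = "treatment") -> CEResult:
    """Value a cohort trace: discounted LY, QALY and costs by state.

    State membership is measured at cycle start; with the half-cycle
    convention off, each cycle contributes occupancy x cycle_length.
    The final boundary point (end of horizon) accrues no person-time.
    """
    dt = trace.cycle_length
    years_per_cycle = dt / 12.0
    t = trace.times[:-1]  # accruing cycles; last boundary closes the horizon
    occ = trace.occupancy.iloc[:-1]
    disc = discount_factor(t / 12.0, econ.discount_rate)
    cost_scale = dt / econ.reference_cycle_length

    def person_years(col):
        return occ[col].to_numpy() * years_per_cycle

    ly = {
        "rfs": float(np.sum(person_years("rfs") * disc)),
        "lr": float(np.sum(person_years("lr") * disc)),
        "dm": float(np.sum((person_years("dm1") + person_years("dm2")) * disc)),
    }
    qaly = {
        "rfs": econ.utility_rfs * ly["rfs"],
        "lr": econ.utility_lr * ly["lr"],
        "dm": econ.utility_dm * ly["dm"],
    }

    treated = strategy in econ.treatment_cost_per_cycle
    treatment_cost = 0.0
    if treated:
        per_cycle = econ.treatment_cost_per_cycle[strategy] * cost_scale
        on_treatment = t < econ.treatment_duration - 1e-9
        treatment_cost = float(
            np.sum(occ["rfs"].to_numpy()[on_treatment] * per_cycle * disc[on_treatment])
        )
        treatment_cost += econ.ae_cost  # one-off at treatment start, t=0

    dead = trace.occupancy["dead"].to_numpy()
    death_inflow = np.diff(dead, prepend=0.0)  # includes any mass dead at t=0
    disc_all = discount_factor(trace.times / 12.0, econ.discount_rate)
    palliative = float(np.sum(death_inflow * econ.palliative_cost * disc_all))

    costs = {
        "treatment": treatment_cost,
        "rfs": float(np.sum(occ["rfs"].to_numpy() * econ.cost_rfs_per_cycle * cost_scale * disc)),
        "lr": float(np.sum(occ["lr"].to_numpy() * econ.cost_lr_per_cycle * cost_scale * disc)),
        "dm": float(
            np.sum(
                (
                    occ["dm1"].to_numpy() * econ.cost_dm1_per_cycle
                    + occ["dm2"].to_numpy() * econ.cost_dm2_per_cycle
                )
                * cost_scale
                * disc
            )
        )
        + palliative,
    }

    age_dec = 0.0
    if econ.age_decrement_enabled and econ.age_decrement > 0:
        alive_py = (1.0 - occ["dead"].to_numpy()) * years_per_cycle
        age_dec = apply_age_decrement(
            alive_py,
            t,
            trace.starting_age,
            econ.age_decrement,
            rate=econ.discount_rate,
            threshold=econ.age_decrement_threshold,
        )
    if treated and econ.ae_utility_decrement:
        age_dec += econ.ae_utility_decrement

    return CEResult(strategy=strategy, ly=ly, qaly=qaly, costs=costs, age_decrement_qaly=age_dec)


@dataclass(frozen=True)
class ICERRecord:
    """Incremental comparison of two strategies (a vs b)."""

    strategy_a: str
    strategy_b: str
    delta_cost: float
    delta_qaly: float
    icer: float | None  # euros per QALY; None when delta_qaly == 0
    dominant: bool  # a cheaper and more effective
    dominated: bool  # a costlier and less effective


def compute_icer(a, b, qaly_a=None, qaly_b=None, label_a="a", label_b="b") -> ICERRecord:
    """ICER of strategy a vs b: (cost_a - cost_b) / (qaly_a - qaly_b).

    Accepts either two CEResult objects or explicit (cost, qaly) numbers
    (pass costs as ``a``/``b`` and QALYs via the keyword arguments).
    """
    if isinstance(a, CEResult):
        cost_a, q_a, label_a = a.total_cost, a.total_qaly, a.strategy
        cost_b, q_b, label_b = b.total_cost, b.total_qaly, b.strategy
    else:
        cost_a, q_a = float(a), float(qaly_a)
        cost_b, q_b = float(b), float(qaly_b)
    d_cost = cost_a - cost_b
    d_qaly = q_a - q_b
    dominant = d_cost < 0 and d_qaly > 0
    dominated = d_cost > 0 and d_qaly < 0
    icer = None if d_qaly == 0 else d_cost / d_qaly
    return ICERRecord(label_a, label_b, d_cost, d_qaly, icer, dominant, dominated)
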