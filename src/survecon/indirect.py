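"""Bucher indirect treatment comparisons on the log-hazard-ratio scale.

An anchored (Bucher) comparison of treatments A and B through a shared
comparator C combines the trial-level hazard ratios

    ln HR(A vs B) = ln HR(A vs C) - ln HR(B vs C)
    se^2(A vs B)  = se^2(A vs C) + se^2(B vs C)

with standard errors recovered from the reported 95% confidence
intervals, which are treated as log-symmetric Wald intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

Z_975 = 1.959964  # 97.5% standard-normal quantile


@dataclass(frozen=True)
class HazardRatio:
    """A reported hazard ratio with its 95% confidence interval."""

    comparison: str  # e.g. "nivolumab vs observation"
    endpoint: str  # OS, RFS or DMFS
    point: float
    ci_low: float
    ci_high: float

    def __post_init__(self):
        if min(self.point, self.ci_low, self.ci_high) <= 0:
            raise ValueError("hazard ratios and CI bounds must be positive")
        if not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError(
                f"point {self.point} outside CI [{self.ci_low}, {self.ci_high}]"
            )


def log_se_from_ci(hr: HazardRatio) -> float:
    """Standard error of ln(HR) from a 95% Wald CI: (ln hi - ln lo) / (2 z)."""
    if hr.ci_low == hr.ci_high:
        warnings.warn(
            f"degenerate CI for {hr.comparison} ({hr.endpoint}): se set to 0",
            stacklevel=2,
        )
        return 0.0
    return (math.log(hr.ci_high) - math.log(hr.ci_low)) / (2.0 * Z_975)


def bucher(hr_ac: HazardRatio, hr_bc: HazardRatio) -> HazardRatio:
    """Anchored indirect comparison A vs B from A-vs-C and B-vs-C hazard ratios."""
    if hr_ac.endpoint != hr_bc.endpoint:
        raise ValueError(
            f"endpoint mismatch: {hr_ac.endpoint} vs {hr_bc.endpoint}"
        )
    log_point = math.log(hr_ac.point) - math.log(hr_bc.point)
    se = math.sqrt(log_se_from_ci(hr_ac) ** 2 + log_se_from_ci(hr_bc) ** 2)
    a = hr_ac.comparison.split(" vs ")[0]
    b = hr_bc.comparison.split(" vs ")[0]
    return HazardRatio(
        comparison=f"{a} vs {b}",
        endpoint=hr_ac.endpoint,
        point=math.exp(log_point),
        ci_low=math.exp(log_point - Z_975 * se),
        ci_high=math.exp(log_point + Z_975 * se),
    )


def hazard_ratios_from_config(rows: list[dict]) -> list[HazardRatio]:
    """Build HazardRatio objects from config rows (comparison, endpoint, point, ci_low, ci_high)."""
    return [
        HazardRatio(
            comparison=r["comparison"],
            endpoint=r["endpoint"],
            point=float(r["point"]),
            ci_low=float(r["ci_low"]),
            ci_high=float(r["ci_high"]),
        )
        for r in rows
    ]


def results_table(hrs: list[HazardRatio]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "comparison": h.comparison,
                "endpoint": h.endpoint,
                "hr": h.point,
                "ci_low": h.ci_low,
                "ci_high": h.ci_high,
                "log_se": log_se_from_ci(h),
            }
            for h in hrs
        ]
    )
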