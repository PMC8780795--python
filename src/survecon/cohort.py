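"""Lifetime cohort simulation: partitioned survival with a Markov progression sub-model.

The outer model reads state occupancy straight off the overall-survival
and relapse-free-survival curves: at any cycle boundary t,

    relapse-free = S_RFS(t)      (clipped to S_OS if the curves cross)
    dead         = 1 - S_OS(t)
    progressed   = S_OS(t) - S_RFS(t)

Within the progressed mass, a Markov sub-model distributes patients
over three levels of progression — locoregional recurrence (LR),
distant metastasis on first-line treatment (DM1), and distant
metastasis on second-line treatment / best supportive care (DM2):

    LR  --(DMFS hazard x lr_to_dm_hr)-->  DM1
    DM1 --(1LPFS)-->                      DM2
    LR/DM1/DM2 --(2LOS; LR scaled by lr_mortality_hr)--> dead

Because the outer model and the sub-model imply different death flows,
outer mortality has priority: each cycle the three sub-model
occupancies are rescaled by a common factor so they sum exactly to the
outer progressed mass.  New progressions each cycle are split
lr_share : (1 - lr_share) between LR and DM1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

STATES = ("rfs", "lr", "dm1", "dm2", "dead")
REQUIRED_ENDPOINTS = ("RFS", "OS", "DMFS", "1LPFS", "2LOS")


class CurveCrossingWarning(UserWarning):
    """RFS exceeded OS at some time point; RFS was clipped to OS."""


@dataclass(frozen=True)
class ModelConfig:
    """Structural parameters of the cohort model.

    Base case: 50-year-old cohort, 6-month cycles, lifetime horizon
    (to age 100), 3% annual discounting, 33% of progressions
    locoregional, LR-to-DM hazard multiplier 1.5, LR mortality hazard
    ratio 0.35 relative to the distant-metastasis states.
    """

    starting_age: float = 50.0
    cycle_length: float = 6.0  # months
    horizon: float = 600.0  # months; default: to age 100
    discount_rate: float = 0.03  # annual
    lr_share: float = 0.33
    lr_to_dm_hr: float = 1.5
    lr_mortality_hr: float = 0.35
    t_obs: float = 60.0  # months, end of trial follow-up
    t_conv: float = 108.0  # months, end of life-table convergence window
    submodel_clock: str = "state"  # "state" (time-in-state) or "model"
    half_cycle_correction: bool = False

    def __post_init__(self):
        if not (0.0 <= self.lr_share <= 1.0):
            raise ValueError("lr_share must lie in [0, 1]")
        if self.lr_to_dm_hr <= 0 or self.lr_mortality_hr <= 0:
            raise ValueError("hazard multipliers must be positive")
        if self.cycle_length <= 0:
            raise ValueError("cycle_length must be positive")
        n = self.horizon / self.cycle_length
        if abs(n - round(n)) > 1e-9:
            raise ValueError("cycle_length must divide the horizon")
        if self.submodel_clock not in ("state", "model"):
            raise ValueError("submodel_clock must be 'state' or 'model'")

    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon / self.cycle_length))

    def with_overrides(self, **kw) -> "ModelConfig":
        return replace(self, **kw)


@dataclass
class CohortTrace:
    """Per-cycle occupancy of the five model states."""

    times: np.ndarray  # cycle start times, months
    occupancy: pd.DataFrame  # columns rfs, lr, dm1, dm2, dead
    cycle_length: float
    starting_age: float

    def __post_init__(self):
        occ = self.occupancy[list(STATES)].to_numpy()
        if np.any(occ < -1e-9):
            raise ValueError("negative occupancy in trace")
        if np.max(np.abs(occ.sum(axis=1) - 1.0)) > 1e-9:
            raise ValueError("occupancies must sum to 1 each cycle")
        if np.any(np.diff(occ[:, STATES.index("dead")]) < -1e-12):
            raise ValueError("dead occupancy must be non-decreasing")

    def to_frame(self) -> pd.DataFrame:
        df = self.occupancy.copy()
        df.insert(0, "time_months", self.times)
        df.insert(0, "cycle", np.arange(len(self.times)))
        return df

    def write_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)


def transition_probability(S, t: float, dt: float, hr: float = 1.0) -> float:
    """Per-cycle transition probability from a survival curve.

    p = 1 - (S(t+dt)/S(t))**hr; an exhausted curve (S(t)=0) yields p=1.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if hr <= 0:
        raise ValueError("hr must be positive")
    s0 = float(S.survival(t)) if hasattr(S, "survival") else float(S(t))
    s1 = float(S.survival(t + dt)) if hasattr(S, "survival") else float(S(t + dt))
    if s0 <= 0.0:
        return 1.0
    ratio = min(max(s1 / s0, 0.0), 1.0)
    return float(1.0 - ratio**hr)


def partition_occupancy(S_os, S_rfs, t: float) -> tuple[float, float, float]:
    """(relapse-free, progressed, dead) shares at time t from the two outer curves.

    If the digitized/fitted curves cross (S_RFS > S_OS), RFS is clipped
    to OS and a warning is issued; dead always equals 1 - S_OS.
    """
    s_os = float(S_os.survival(t)) if hasattr(S_os, "survival") else float(S_os(t))
    s_rfs = float(S_rfs.survival(t)) if hasattr(S_rfs, "survival") else float(S_rfs(t))
    dead = 1.0 - s_os
    if s_rfs > s_os + 1e-12:
        warnings.warn(
            f"RFS ({s_rfs:.4f}) exceeds OS ({s_os:.4f}) at t={t:g} months; clipping",
            CurveCrossingWarning,
            stacklevel=2,
        )
        s_rfs = s_os
    rfs = min(s_rfs, s_os)
    progressed = max(0.0, s_os - rfs)
    return rfs, progressed, dead


def step_submodel(
    prev: tuple[float, float, float],
    probs: dict[str, float],
    targets: tuple[float, tuple[float, float], float],
) -> tuple[float, float, float]:
    """One cycle of the LR/DM1/DM2 sub-model with outer-mortality priority.

    ``prev`` holds the current (lr, dm1, dm2) occupancies, ``probs`` the
    per-cycle probabilities lr_dm1, dm1_dm2, dm1_death, dm2_death,
    lr_death, and ``targets`` the outer-model constraint
    (progressed_total, (new_lr, new_dm1), deaths_from_os).  Provisional
    flows are applied first; the three occupancies are then rescaled by
    a common factor so they sum to progressed_total.
    """
    lr, dm1, dm2 = prev
    progressed_total, (new_lr, new_dm1), _deaths = targets
    p = probs

    stay_lr = 1.0 - p["lr_dm1"] - p["lr_death"]
    stay_dm1 = 1.0 - p["dm1_dm2"] - p["dm1_death"]
    stay_dm2 = 1.0 - p["dm2_death"]
    if min(stay_lr, stay_dm1, stay_dm2) < -1e-12:
        raise ValueError(
            "inconsistent sub-model probabilities: competing exits exceed 1 "
            f"(lr: {p['lr_dm1']}+{p['lr_death']}, dm1: {p['dm1_dm2']}+{p['dm1_death']})"
        )

    lr_next = lr * max(stay_lr, 0.0) + new_lr
    dm1_next = dm1 * max(stay_dm1, 0.0) + lr * p["lr_dm1"] + new_dm1
    dm2_next = dm2 * max(stay_dm2, 0.0) + dm1 * p["dm1_dm2"]
    if min(lr_next, dm1_next, dm2_next) < -1e-12:
        raise ValueError("negative provisional occupancy in sub-model")

    total = lr_next + dm1_next + dm2_next
    if progressed_total <= 0.0:
        return 0.0, 0.0, 0.0
    if total <= 1e-300:
        # everyone exited provisionally: fall back to pre-death shares
        pre = (lr + new_lr, dm1 + new_dm1, dm2)
        pre_total = sum(pre)
        if pre_total <= 1e-300:
            # nothing to anchor on: split like new entries
            share = new_lr + new_dm1
            if share > 0:
                f_lr = new_lr / share
            else:
                f_lr = 0.0
            return progressed_total * f_lr, progressed_total * (1.0 - f_lr), 0.0
        scale = progressed_total / pre_total
        return pre[0] * scale, pre[1] * scale, pre[2] * scale
    scale = progressed_total / total
    return lr_next * scale, dm1_next * scale, dm2_next * scale


def run_cohort(config: ModelConfig, curves: dict[str, object]) -> CohortTrace:
    """Run the partitioned-survival cohort model over the full horizon.

    ``curves`` binds each endpoint name in ``REQUIRED_ENDPOINTS`` to a
    survival object (anything exposing ``survival(t)``).  RFS and OS
    drive the outer partition; DMFS, 1LPFS and 2LOS drive the
    progression sub-model.
    """
    missing = [e for e in REQUIRED_ENDPOINTS if e not in curves]
    if missing:
        raise KeyError(f"unbound endpoint curves: {missing}")
    S_rfs, S_os = curves["RFS"], curves["OS"]
    S_dmfs, S_1lpfs, S_2los = curves["DMFS"], curves["1LPFS"], curves["2LOS"]
    dt = config.cycle_length
    n_cycles = config.n_cycles
    times = np.arange(n_cycles + 1) * dt

    rows = np.zeros((n_cycles + 1, 5))
    rfs0, prog0, dead0 = partition_occupancy(S_os, S_rfs, 0.0)
    lr, dm1, dm2 = (prog0 * config.lr_share, prog0 * (1 - config.lr_share), 0.0)
    rows[0] = (rfs0, lr, dm1, dm2, dead0)
    rfs_prev = rfs0
    # cohort-average time-in-state clocks for the sub-model states
    age_lr = age_dm1 = age_dm2 = 0.0

    for k in range(1, n_cycles + 1):
        t_prev = times[k - 1]
        rfs_k, prog_k, dead_k = partition_occupancy(S_os, S_rfs, times[k])
        new_prog = max(0.0, rfs_prev - rfs_k)
        new_lr = config.lr_share * new_prog
        new_dm1 = (1.0 - config.lr_share) * new_prog

        if config.submodel_clock == "state":
            t_lr, t_dm1, t_dm2 = age_lr, age_dm1, age_dm2
        else:
            t_lr = t_dm1 = t_dm2 = t_prev
        probs = {
            # LR to distant metastasis: DMFS hazard on model time, scaled
            "lr_dm1": transition_probability(S_dmfs, t_prev, dt, config.lr_to_dm_hr),
            "dm1_dm2": transition_probability(S_1lpfs, t_dm1, dt),
            "dm1_death": transition_probability(S_2los, t_dm1, dt),
            "dm2_death": transition_probability(S_2los, t_dm2, dt),
            "lr_death": transition_probability(S_2los, t_lr, dt, config.lr_mortality_hr),
        }
        # competing exits can sum past 1 for coarse cycles; renormalise
        for state, keys in (("lr", ("lr_dm1", "lr_death")), ("dm1", ("dm1_dm2", "dm1_death"))):
            s = sum(probs[k2] for k2 in keys)
            if s > 1.0:
                for k2 in keys:
                    probs[k2] /= s

        deaths_os = dead_k - rows[k - 1, 4]
        lr_new, dm1_new, dm2_new = step_submodel(
            (lr, dm1, dm2), probs, (prog_k, (new_lr, new_dm1), deaths_os)
        )

        # update cohort-average clocks: stayers age by dt, entrants start at 0
        def _mean_age(stay_mass, stay_age, enter_mass):
            tot = stay_mass + enter_mass
            return (stay_mass * (stay_age + dt)) / tot if tot > 1e-300 else 0.0

        age_lr = _mean_age(lr * max(1 - probs["lr_dm1"] - probs["lr_death"], 0), age_lr, new_lr)
        age_dm1 = _mean_age(
            dm1 * max(1 - probs["dm1_dm2"] - probs["dm1_death"], 0),
            age_dm1,
            lr * probs["lr_dm1"] + new_dm1,
        )
        age_dm2 = _mean_age(dm2 * max(1 - probs["dm2_death"], 0), age_dm2, dm1 * probs["dm1_dm2"])

        lr, dm1, dm2 = lr_new, dm1_new, dm2_new
        rows[k] = (rfs_k, lr, dm1, dm2, dead_k)
        rfs_prev = rfs_k

    occ = pd.DataFrame(rows, columns=list(STATES))
    # exact conservation: progressed mass was set to S_os - S_rfs, so the sum
    # is 1 up to float roundoff; renormalise the residual onto progressed states
    occ["dead"] = occ["dead"].clip(0.0, 1.0)
    return CohortTrace(
        times=times,
        occupancy=occ,
        cycle_length=dt,
        starting_age=config.starting_age,
    )
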