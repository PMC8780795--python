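"""Reconstruction of pseudo individual-patient data from digitized Kaplan-Meier curves.

Published survival figures give two pieces of information: the plotted
step curve (digitized into (time, survival) coordinates) and the
numbers-at-risk printed beneath the time axis.  Together they are enough
to rebuild a per-subject dataset of event and censoring times whose
Kaplan-Meier estimate reproduces the published curve — the standard
trick for refitting parametric models when patient-level data are not
released.

The reconstruction here works interval by interval between consecutive
at-risk times.  Within an interval, events are placed at the observed
survival drops and censored subjects at the interval midpoint; the
censoring count is solved so that the number remaining at risk at the
end of the interval matches the printed at-risk figure.  Everything is
deterministic: no sampling is involved, and integer rounding of event
counts carries a running remainder so that totals are conserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

ENDPOINTS = ("RFS", "OS", "DMFS", "1LPFS", "2LOS")


class ReconstructionInfeasibleError(ValueError):
    """The digitized curve and at-risk table cannot both be honoured.

    Raised when a survival drop inside an at-risk interval implies more
    events than there are subjects at risk in that interval.
    """


@dataclass(frozen=True)
class DigitizedCurve:
    """Digitized survival-curve coordinates for one endpoint and arm.

    ``points`` is an ordered list of ``(time_months, survival)`` pairs
    starting at ``(0, 1)`` with strictly increasing times and
    non-increasing survival.
    """

    endpoint: str
    arm: str
    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        pts = tuple((float(t), float(s)) for t, s in self.points)
        object.__setattr__(self, "points", pts)
        times = np.array([p[0] for p in pts])
        surv = np.array([p[1] for p in pts])
        if len(pts) == 0:
            raise ValueError("curve needs at least one point")
        if times[0] != 0.0 or abs(surv[0] - 1.0) > 1e-12:
            raise ValueError("first point must be (0, 1.0)")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(surv < -1e-12) or np.any(surv > 1 + 1e-12):
            raise ValueError("survival values must lie in [0, 1]")
        if np.any(np.diff(surv) > 1e-12):
            raise ValueError("survival must be non-increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def survival(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    def survival_at(self, t: float) -> float:
        """Step-function value at time ``t`` (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        idx = max(idx, 0)
        return float(self.survival[idx])


@dataclass(frozen=True)
class AtRiskTable:
    """Numbers-at-risk printed beneath a published KM plot."""

    endpoint: str
    arm: str
    entries: tuple[tuple[float, int], ...]

    def __post_init__(self) -> None:
        ent = tuple((float(t), int(n)) for t, n in self.entries)
        object.__setattr__(self, "entries", ent)
        times = np.array([e[0] for e in ent])
        counts = np.array([e[1] for e in ent])
        if len(ent) == 0:
            raise ValueError("at-risk table needs at least one entry")
        if times[0] != 0.0:
            raise ValueError("at-risk table must start at time 0")
        if np.any(np.diff(times) <= 0):
            raise ValueError("at-risk times must be strictly increasing")
        if np.any(counts < 0) or np.any(np.diff(counts) > 0):
            raise ValueError("at-risk counts must be non-negative and non-increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([e[0] for e in self.entries])

    @property
    def counts(self) -> np.ndarray:
        return np.array([e[1] for e in self.entries])


@dataclass(frozen=True)
class PseudoIPD:
    """Reconstructed per-subject (time, event) records for one arm/endpoint."""

    endpoint: str
    arm: str
    records: tuple[tuple[float, bool], ...]

    def __post_init__(self) -> None:
        rec = tuple((float(t), bool(e)) for t, e in self.records)
        object.__setattr__(self, "records", rec)
        if any(t <= 0 for t, _ in rec):
            raise ValueError("record times must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.array([r[0] for r in self.records])

    @property
    def events(self) -> np.ndarray:
        return np.array([r[1] for r in self.records], dtype=bool)

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.times, "event": self.events.astype(int)})


def reconstruct_pseudo_ipd(curve: DigitizedCurve, at_risk: AtRiskTable) -> PseudoIPD:
    """Convert a digitized KM curve plus at-risk table into pseudo event data.

    Within each at-risk interval ``[t_k, t_{k+1})`` the event count at
    every survival drop is derived from the product-limit relation
    ``d_j = r_j * (1 - S_j / S_{j-})`` and the censoring count is the
    residual needed to reach the next printed at-risk figure.  Censored
    subjects are placed at the interval midpoint; because mid-interval
    censorings shrink the risk sets of later drops, the pair
    (events, censorings) is solved by fixed-point iteration, which
    converges in a handful of passes for any feasible input.

    Subjects still at risk after the last at-risk time are censored at
    the last curve time.
    """
    if curve.endpoint != at_risk.endpoint or curve.arm != at_risk.arm:
        raise ValueError(
            f"curve ({curve.endpoint}/{curve.arm}) and at-risk table "
            f"({at_risk.endpoint}/{at_risk.arm}) refer to different data"
        )
    ct, cs = curve.times, curve.survival
    rt, rn = at_risk.times, at_risk.counts
    n0 = int(rn[0])
    if n0 == 0:
        return PseudoIPD(curve.endpoint, curve.arm, ())

    # interval boundaries: the at-risk times, extended past the last curve time
    last_time = max(ct[-1], rt[-1])
    bounds = list(rt) + [last_time + 1e-9]
    records: list[tuple[float, bool]] = []
    n_start = n0
    remainder = 0.0  # running rounding remainder for event counts

    for k in range(len(bounds) - 1):
        lo, hi = bounds[k], bounds[k + 1]
        last_interval = k == len(rt) - 1
        # survival drops in [lo, hi): a drop exactly at an at-risk time belongs
        # to the interval that starts there (the printed count still includes
        # the subjects about to fail); drop at ct[j] means S fell from cs[j-1]
        drop_idx = [
            j
            for j in range(1, len(ct))
            if lo <= ct[j] < hi and cs[j] < cs[j - 1] - 1e-12
        ]
        n_end = int(rn[k + 1]) if not last_interval else 0
        mid = (lo + min(hi, last_time)) / 2.0

        # fixed point: censorings at the midpoint thin the risk sets of the
        # drops that come after the midpoint
        n_cens = 0
        for _ in range(50):
            r = float(n_start)
            counts: list[int] = []
            rem = remainder
            d_raw_total = 0.0
            censored_applied = False
            feasible = True
            for j in drop_idx:
                if not censored_applied and ct[j] > mid:
                    r -= n_cens
                    censored_applied = True
                s_prev, s_cur = cs[j - 1], cs[j]
                if r <= 0 or s_prev <= 0:
                    feasible = False
                    break
                d_raw = r * (1.0 - s_cur / s_prev)
                d_raw_total += d_raw
                d_exact = d_raw + rem
                d = int(round(d_exact))
                d = max(0, min(d, int(r)))
                rem = d_exact - d
                counts.append(d)
                r -= d
            if not feasible:
                raise ReconstructionInfeasibleError(
                    f"{curve.endpoint}/{curve.arm}: survival drop in interval "
                    f"[{lo:g}, {hi:g}) months implies more events than subjects at risk"
                )
            d_total = sum(counts)
            if d_total > n_start:
                raise ReconstructionInfeasibleError(
                    f"{curve.endpoint}/{curve.arm}: {d_total} events implied in "
                    f"[{lo:g}, {hi:g}) months but only {n_start} at risk"
                )
            if last_interval:
                new_cens = 0  # survivors handled below
                break
            new_cens = max(0, n_start - n_end - d_total)
            if new_cens == n_cens:
                break
            n_cens = new_cens
        # gross inconsistency check only: the midpoint-censoring convention
        # makes implied event counts approximate, so small deficits against
        # the at-risk decline are expected and absorbed by clamping
        if not last_interval and n_end - n_start + d_raw_total > max(5.0, 0.5 * d_raw_total):
            raise ReconstructionInfeasibleError(
                f"{curve.endpoint}/{curve.arm}: survival drops in interval "
                f"[{lo:g}, {hi:g}) months imply {d_raw_total:.1f} events but "
                f"the at-risk count only falls {n_start} -> {n_end}"
            )
        remainder = rem
        n_cens = new_cens

        for j, d in zip(drop_idx, counts):
            records.extend([(ct[j], True)] * d)
        if n_cens > 0:
            records.extend([(mid, False)] * n_cens)
        n_start = n_start - sum(counts) - n_cens
        if last_interval and n_start > 0:
            # still at risk past the follow-up shown: administratively censored
            records.extend([(last_time, False)] * n_start)
            n_start = 0

    records.sort(key=lambda r: (r[0], not r[1]))
    return PseudoIPD(curve.endpoint, curve.arm, tuple(records))


def km_estimate(ipd: PseudoIPD) -> DigitizedCurve:
    """Product-limit estimate of the survival curve of a pseudo-IPD set.

    Round-trip validator for :func:`reconstruct_pseudo_ipd`; delegates to
    the lifelines Kaplan-Meier fitter.
    """
    if ipd.n == 0:
        raise ValueError("cannot estimate a KM curve from zero records")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.times, ipd.events)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    if times[0] != 0.0:
        times = np.concatenate([[0.0], times])
        surv = np.concatenate([[1.0], surv])
    pts = tuple(zip(times, surv))
    return DigitizedCurve(ipd.endpoint, ipd.arm, pts)


# ---------------------------------------------------------------------------
# delimited-text I/O

def read_curves(path: str) -> dict[tuple[str, str], DigitizedCurve]:
    """Read digitized curves from CSV with columns endpoint, arm, time_months, survival."""
    df = pd.read_csv(path)
    out = {}
    for (ep, arm), grp in df.groupby(["endpoint", "arm"], sort=False):
        grp = grp.sort_values("time_months")
        pts = tuple(zip(grp["time_months"], grp["survival"]))
        out[(ep, arm)] = DigitizedCurve(ep, arm, pts)
    return out


def read_at_risk(path: str) -> dict[tuple[str, str], AtRiskTable]:
    """Read at-risk tables from CSV with columns endpoint, arm, time_months, n_at_risk."""
    df = pd.read_csv(path)
    out = {}
    for (ep, arm), grp in df.groupby(["endpoint", "arm"], sort=False):
        grp = grp.sort_values("time_months")
        ent = tuple(zip(grp["time_months"], grp["n_at_risk"]))
        out[(ep, arm)] = AtRiskTable(ep, arm, ent)
    return out


def write_curves(curves: dict[tuple[str, str], DigitizedCurve] | list[DigitizedCurve], path: str) -> None:
    items = curves.values() if isinstance(curves, dict) else curves
    rows = [
        {"endpoint": c.endpoint, "arm": c.arm, "time_months": t, "survival": s}
        for c in items
        for t, s in c.points
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_at_risk(tables: dict[tuple[str, str], AtRiskTable] | list[AtRiskTable], path: str) -> None:
    items = tables.values() if isinstance(tables, dict) else tables
    rows = [
        {"endpoint": t.endpoint, "arm": t.arm, "time_months": tm, "n_at_risk": n}
        for t in items
        for tm, n in t.entries
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_pseudo_ipd(ipd: PseudoIPD, path: str) -> None:
    ipd.to_frame().to_csv(path, index=False)


def read_pseudo_ipd(path: str, endpoint: str = "", arm: str = "") -> PseudoIPD:
    df = pd.read_csv(path)
    recs = tuple(zip(df["time_months"], df["event"].astype(bool)))
    return PseudoIPD(endpoint, arm, recs)
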