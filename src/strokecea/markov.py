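"""Cohort-level Markov engine over coarse disability states.

The health states are the three coarse modified Rankin Scale (mRS) bands used
throughout the model: mRS0-2 (functionally independent), mRS3-5 (disabled) and
mRS6 (dead, absorbing).  The engine propagates a cohort occupancy vector one
month at a time through a per-cycle sequence of 3x3 row-stochastic transition
matrices, and can split the two living bands into fine mRS grades 0..6 with
fixed within-band proportions for downstream utility weighting and long-term
care costing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, ModelConstructionError

_ATOL = 1e-9

FINE_GRADES = ("mRS0", "mRS1", "mRS2", "mRS3", "mRS4", "mRS5", "mRS6")


class CoarseState(enum.IntEnum):
    """Coarse disability band. Ordering matches matrix row/column indices."""

    MRS02 = 0
    MRS35 = 1
    DEAD = 2


@dataclass(frozen=True)
class MRSDistribution:
    """Occupancy probabilities over the three coarse states at one cycle."""

    p_mrs02: float
    p_mrs35: float
    p_dead: float

    def __post_init__(self):
        probs = (self.p_mrs02, self.p_mrs35, self.p_dead)
        for name, p in zip(("p_mrs02", "p_mrs35", "p_dead"), probs):
            if not (-_ATOL <= p <= 1.0 + _ATOL):
                raise InvalidParameterError(f"{name}={p} outside [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise InvalidParameterError(
                f"state probabilities sum to {sum(probs)}, expected 1"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.p_mrs02, self.p_mrs35, self.p_dead], dtype=float)


def derive_initial_distribution(
    control_p02: float, risk_ratio: float, p_dead: float
) -> MRSDistribution:
    """Initial distribution of the intervention arm from the control arm.

    The independent (mRS0-2) share is the control arm's share scaled by the
    risk ratio of functional independence; the death share is assumed equal
    between arms; the disabled share takes the remainder.
    """
    if not 0.0 <= control_p02 <= 1.0:
        raise InvalidParameterError(f"control_p02={control_p02} outside [0, 1]")
    if risk_ratio <= 0.0:
        raise InvalidParameterError(f"risk_ratio={risk_ratio} must be positive")
    if not 0.0 <= p_dead <= 1.0:
        raise InvalidParameterError(f"p_dead={p_dead} outside [0, 1]")
    p02 = control_p02 * risk_ratio
    if p02 + p_dead > 1.0 + _ATOL:
        raise InvalidParameterError(
            f"control_p02*risk_ratio + p_dead = {p02 + p_dead:.6f} exceeds 1"
        )
    return MRSDistribution(p02, 1.0 - p02 - p_dead, p_dead)


def odds_ratio_to_risk_ratio(odds_ratio: float, baseline_risk: float) -> float:
    """Convert an odds ratio to a risk ratio at a given baseline risk.

    RR = OR / (1 - p0 + p0 * OR), the standard conversion for a binary
    outcome with control-arm risk p0.
    """
    if odds_ratio <= 0.0:
        raise InvalidParameterError(f"odds_ratio={odds_ratio} must be positive")
    if not 0.0 < baseline_risk < 1.0:
        raise InvalidParameterError(
            f"baseline_risk={baseline_risk} must lie strictly in (0, 1)"
        )
    return odds_ratio / (1.0 - baseline_risk + baseline_risk * odds_ratio)


@dataclass(frozen=True)
class FineSplit:
    """Fixed proportions dividing each living coarse band into fine grades.

    ``split02`` holds the mRS0:1:2 shares, ``split35`` the mRS3:4:5 shares.
    Shares are renormalized to sum exactly to 1 before use, so slightly
    rounded published triples (e.g. summing to 99.9%) conserve probability.
    """

    split02: tuple[float, float, float]
    split35: tuple[float, float, float]

    def __post_init__(self):
        for name, triple in (("split02", self.split02), ("split35", self.split35)):
            arr = np.asarray(triple, dtype=float)
            if arr.shape != (3,):
                raise InvalidParameterError(f"{name} must have three entries")
            if (arr < 0).any():
                raise InvalidParameterError(f"{name} has negative shares: {triple}")
            if arr.sum() <= 0:
                raise InvalidParameterError(f"{name} shares sum to zero")

    @property
    def norm02(self) -> np.ndarray:
        arr = np.asarray(self.split02, dtype=float)
        return arr / arr.sum()

    @property
    def norm35(self) -> np.ndarray:
        arr = np.asarray(self.split35, dtype=float)
        return arr / arr.sum()


@dataclass(frozen=True)
class TransitionSchedule:
    """Per-cycle 3x3 transition matrices with their destination months.

    ``months[k]`` is the month-since-onset the k-th transition lands on; the
    first cycle of the base case takes the cohort from month 3 to month 4.
    """

    matrices: np.ndarray  # (n_cycles, 3, 3)
    months: np.ndarray  # (n_cycles,) destination month of each transition

    def __post_init__(self):
        mats = np.asarray(self.matrices, dtype=float)
        months = np.asarray(self.months, dtype=int)
        object.__setattr__(self, "matrices", mats)
        object.__setattr__(self, "months", months)
        if mats.ndim != 3 or mats.shape[1:] != (3, 3):
            raise ModelConstructionError(f"matrices shape {mats.shape} is not (n,3,3)")
        if months.shape != (mats.shape[0],):
            raise ModelConstructionError("months length does not match matrices")
        if len(months) and np.any(np.diff(months) != 1):
            raise ModelConstructionError("destination months must increase by 1")
        if (mats < -_ATOL).any() or (mats > 1.0 + _ATOL).any():
            raise ModelConstructionError("transition probabilities outside [0, 1]")
        rowsums = mats.sum(axis=2)
        if not np.allclose(rowsums, 1.0, atol=1e-9):
            bad = np.argwhere(np.abs(rowsums - 1.0) > 1e-9)[0]
            raise ModelConstructionError(
                f"row {bad[1]} of cycle {bad[0]} sums to {rowsums[tuple(bad)]}"
            )
        dead = mats[:, CoarseState.DEAD, :]
        if not np.allclose(dead, [0.0, 0.0, 1.0], atol=1e-12):
            raise ModelConstructionError("DEAD state must be absorbing in every cycle")

    @property
    def n_cycles(self) -> int:
        return self.matrices.shape[0]

    @property
    def start_month(self) -> int:
        return int(self.months[0]) - 1

    @property
    def end_month(self) -> int:
        return int(self.months[-1])


@dataclass
class CohortTrace:
    """Occupancy trajectory: one row per time point (month since onset).

    ``coarse`` has columns (mRS0-2, mRS3-5, dead); ``fine`` (when populated by
    :func:`split_fine`) has columns mRS0..mRS6.
    """

    months: np.ndarray  # (T,)
    coarse: np.ndarray  # (T, 3)
    fine: np.ndarray | None = field(default=None)

    @property
    def p_dead(self) -> np.ndarray:
        return self.coarse[:, CoarseState.DEAD]

    def survival(self, conditional_on_start: bool = False) -> np.ndarray:
        """Probability of being alive at each time point."""
        alive = 1.0 - self.p_dead
        if conditional_on_start:
            return alive / alive[0]
        return alive

    def p02_among_alive(self) -> np.ndarray:
        alive = 1.0 - self.p_dead
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(alive > 0, self.coarse[:, CoarseState.MRS02] / alive, 0.0)

    def at_month(self, month: int) -> int:
        """Row index of a given month since onset."""
        idx = np.flatnonzero(self.months == month)
        if idx.size == 0:
            raise InvalidParameterError(f"month {month} not in trace")
        return int(idx[0])

    def to_frame(self) -> pd.DataFrame:
        """Tabular export: month, mRS0..mRS6, mRS02, mRS35, dead."""
        data = {"month": self.months}
        if self.fine is not None:
            for j, name in enumerate(FINE_GRADES):
                data[name] = self.fine[:, j]
        data["mRS02"] = self.coarse[:, 0]
        data["mRS35"] = self.coarse[:, 1]
        data["dead"] = self.coarse[:, 2]
        return pd.DataFrame(data)


def run_cohort(initial: MRSDistribution, schedule: TransitionSchedule) -> CohortTrace:
    """Propagate the cohort through every cycle of the schedule.

    Row t+1 of the trace is row t times the t-th transition matrix; row 0 is
    the initial distribution at the schedule's start month.
    """
    n = schedule.n_cycles
    coarse = np.empty((n + 1, 3), dtype=float)
    coarse[0] = initial.as_array()
    for t in range(n):
        coarse[t + 1] = coarse[t] @ schedule.matrices[t]
    months = np.concatenate(([schedule.start_month], schedule.months))
    return CohortTrace(months=months, coarse=coarse)


def split_fine(trace: CohortTrace, split: FineSplit) -> CohortTrace:
    """Divide living coarse occupancy into fine mRS grades 0..6.

    The within-band proportions are constant over the horizon; the fine dead
    share equals the coarse one, so every fine row sums to 1.
    """
    s02, s35 = split.norm02, split.norm35
    fine = np.empty((trace.coarse.shape[0], 7), dtype=float)
    fine[:, 0:3] = trace.coarse[:, [CoarseState.MRS02]] * s02
    fine[:, 3:6] = trace.coarse[:, [CoarseState.MRS35]] * s35
    fine[:, 6] = trace.coarse[:, CoarseState.DEAD]
    return CohortTrace(months=trace.months, coarse=trace.coarse, fine=fine)
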