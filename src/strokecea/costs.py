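"""Acute rehabilitation fee arithmetic and long-term-care costing.

Acute-stage rehabilitation is billed per 20-minute unit under a national fee
schedule, with an add-on for units delivered within 30 days of onset and a
further add-on within 14 days.  The number of chargeable days depends on the
weekday pattern of service delivery and on which weekday the stroke occurred,
so the weekday-only arm's cost is an expectation over a uniform onset weekday.

Long-term-care costs attach monthly cost rates to fine mRS grades via a
care-needs-level mapping (utilization rate times a share-weighted mix of
care-level monthly costs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .markov import CohortTrace

# Weekday indices follow ISO order, Monday=0 .. Sunday=6.
WEEKDAY_NAMES = ("mon", "tue", "wed", "thu", "fri", "sat", "sun")
ALL_WEEK = frozenset(range(7))
MON_FRI = frozenset(range(5))


def parse_weekdays(names) -> frozenset[int]:
    """Map weekday names ('mon'..'sun') or indices to an index set."""
    out = set()
    for n in names:
        if isinstance(n, int):
            if not 0 <= n <= 6:
                raise InvalidParameterError(f"weekday index {n} outside 0..6")
            out.add(n)
        else:
            key = str(n).lower()[:3]
            if key not in WEEKDAY_NAMES:
                raise InvalidParameterError(f"unknown weekday {n!r}")
            out.add(WEEKDAY_NAMES.index(key))
    return frozenset(out)


@dataclass(frozen=True)
class FeeSchedule:
    """Per-unit rehabilitation fees (USD) and daily service volume."""

    base_fee_per_unit: float = 18.6
    surcharge_30d_per_unit: float = 2.41
    surcharge_14d_per_unit: float = 3.62
    units_per_day: float = 4.3

    def __post_init__(self):
        for name in (
            "base_fee_per_unit",
            "surcharge_30d_per_unit",
            "surcharge_14d_per_unit",
        ):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.units_per_day <= 0:
            raise InvalidParameterError("units_per_day must be positive")


@dataclass(frozen=True)
class RehabPattern:
    """Weekly rehabilitation calendar for one arm.

    Day 1 is the onset day; rehabilitation is delivered on ``rehab_weekdays``
    during the first ``duration_days`` days.
    """

    rehab_weekdays: frozenset[int]
    duration_days: int = 30
    onset_weekday: int = 0

    def __post_init__(self):
        object.__setattr__(self, "rehab_weekdays", frozenset(self.rehab_weekdays))
        if not self.rehab_weekdays or not self.rehab_weekdays <= ALL_WEEK:
            raise InvalidParameterError("rehab_weekdays must be a non-empty subset of 0..6")
        if self.duration_days < 1:
            raise InvalidParameterError("duration_days must be >= 1")
        if self.onset_weekday not in ALL_WEEK:
            raise InvalidParameterError("onset_weekday must be in 0..6")


def rehab_days(pattern: RehabPattern) -> tuple[int, int]:
    """Count rehabilitation days in onset-days 1-14 and 15-30.

    Day d falls on weekday (onset_weekday + d - 1) mod 7; a day is a
    rehabilitation day when that weekday is in the pattern.
    """
    n14 = n30 = 0
    for d in range(1, min(pattern.duration_days, 30) + 1):
        weekday = (pattern.onset_weekday + d - 1) % 7
        if weekday in pattern.rehab_weekdays:
            if d <= 14:
                n14 += 1
            else:
                n30 += 1
    return n14, n30


def acute_cost(pattern: RehabPattern, fees: FeeSchedule) -> float:
    """Acute-stage rehabilitation cost (USD) for one onset weekday."""
    n14, n30 = rehab_days(pattern)
    full = fees.base_fee_per_unit + fees.surcharge_30d_per_unit + fees.surcharge_14d_per_unit
    late = fees.base_fee_per_unit + fees.surcharge_30d_per_unit
    return fees.units_per_day * (n14 * full + n30 * late)


def expected_acute_cost(
    pattern_weekdays: frozenset[int], fees: FeeSchedule, duration_days: int = 30
) -> float:
    """Mean acute cost over the 7 equiprobable onset weekdays."""
    costs = [
        acute_cost(
            RehabPattern(pattern_weekdays, duration_days, onset_weekday=w), fees
        )
        for w in range(7)
    ]
    return float(np.mean(costs))


def acute_cost_breakdown(
    pattern_weekdays: frozenset[int], fees: FeeSchedule, duration_days: int = 30
) -> pd.DataFrame:
    """Per-onset-weekday chargeable-day counts and costs."""
    rows = []
    for w in range(7):
        p = RehabPattern(pattern_weekdays, duration_days, onset_weekday=w)
        n14, n30 = rehab_days(p)
        rows.append(
            {
                "onset_weekday": WEEKDAY_NAMES[w],
                "days_1_14": n14,
                "days_15_30": n30,
                "cost_usd": acute_cost(p, fees),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CareLevel:
    """One care-needs level inside a grade's mix."""

    level: str
    share: float
    monthly_cost: float
    gamma_shape: float | None = None
    gamma_rate: float | None = None


@dataclass(frozen=True)
class CareNeedsMap:
    """mRS grade -> long-term-care utilization and care-level cost mix.

    ``mixes[g]`` lists the care levels grade g maps to, with shares summing
    to 1; grades 0 and 6 must incur no cost.
    """

    utilization: tuple[float, ...]  # length 7, per mRS grade
    mixes: tuple[tuple[CareLevel, ...], ...]  # length 7

    def __post_init__(self):
        if len(self.utilization) != 7 or len(self.mixes) != 7:
            raise InvalidParameterError("care map needs entries for mRS grades 0..6")
        for g, u in enumerate(self.utilization):
            if not 0.0 <= u <= 1.0:
                raise InvalidParameterError(f"utilization for mRS{g} outside [0, 1]")
        for g, mix in enumerate(self.mixes):
            if mix:
                total = sum(cl.share for cl in mix)
                if abs(total - 1.0) > 1e-9:
                    raise InvalidParameterError(
                        f"care-level shares for mRS{g} sum to {total}, expected 1"
                    )
                if any(cl.monthly_cost < 0 or cl.share < 0 for cl in mix):
                    raise InvalidParameterError(f"negative cost/share for mRS{g}")
        for g in (0, 6):
            if self.utilization[g] != 0.0:
                raise InvalidParameterError(f"mRS{g} must have zero LTC utilization")

    def monthly_cost_per_grade(self) -> np.ndarray:
        """Expected monthly LTC cost (USD) per fine mRS grade."""
        out = np.zeros(7)
        for g in range(7):
            mix_cost = sum(cl.share * cl.monthly_cost for cl in self.mixes[g])
            out[g] = self.utilization[g] * mix_cost
        return out


def discount_factors(months: np.ndarray, annual_rate: float) -> np.ndarray:
    """Discount factor (1+r)^(-(m-1)/12) for cashflows in month m."""
    m = np.asarray(months, dtype=float)
    return (1.0 + annual_rate) ** (-(m - 1.0) / 12.0)


def ltc_cost_of_trace(
    trace: CohortTrace,
    care_map: CareNeedsMap,
    discount_rate: float = 0.02,
    start_month: int = 4,
    grade_costs: np.ndarray | None = None,
) -> float:
    """Discounted long-term-care cost (USD) accrued by the traced cohort.

    Sums, over months from ``start_month`` to the end of the trace, the fine
    occupancy times per-grade monthly cost times the discount factor.
    ``grade_costs`` overrides the map's expected per-grade costs (used by the
    probabilistic sensitivity analysis).
    """
    if trace.fine is None:
        raise InvalidParameterError("trace has no fine occupancy; call split_fine first")
    costs = care_map.monthly_cost_per_grade() if grade_costs is None else grade_costs
    mask = trace.months >= start_month
    occ = trace.fine[mask]
    disc = discount_factors(trace.months[mask], discount_rate)
    return float((occ @ costs) @ disc)
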