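"""Cost-utility assembly: QALYs, incremental results, ICER verdicts.

Each arm's trace is weighted by grade-specific quality-of-life utilities to
give discounted QALYs, combined with acute medical and long-term-care costs,
and the two arms are compared under two payer perspectives: public healthcare
only (rehabilitation fees) and healthcare plus long-term care.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from . import calibration as cal
from . import costs as costmod
from . import markov
from .errors import InvalidParameterError

if TYPE_CHECKING:  # pragma: no cover
    from .config import RunConfig


class Verdict(str, enum.Enum):
    """Qualitative ICER outcomes when the ratio is not informative."""

    DOMINANT = "Dominant"  # cheaper and more effective
    DOMINATED = "Dominated"  # dearer and less effective
    UNDEFINED = "Undefined"  # no QALY difference


@dataclass(frozen=True)
class UtilityTable:
    """Quality-of-life utility per fine mRS grade, with PSA gamma parameters.

    Utilities are QALY weights in [0, 1], weakly decreasing with disability;
    death carries utility 0.  The gamma (shape, rate) pairs parameterize the
    probabilistic sensitivity draws for grades 0-5 and must have means within
    0.01 of the point utilities.
    """

    utilities: tuple[float, ...]  # length 7, mRS0..mRS6
    gamma_shape: tuple[float, ...] | None = None  # length 6, mRS0..mRS5
    gamma_rate: tuple[float, ...] | None = None

    def __post_init__(self):
        u = np.asarray(self.utilities, dtype=float)
        if u.shape != (7,):
            raise InvalidParameterError("need one utility per mRS grade 0..6")
        if (u < 0).any() or (u > 1).any():
            raise InvalidParameterError("utilities must lie in [0, 1]")
        if u[6] != 0.0:
            raise InvalidParameterError("mRS6 (death) utility must be 0")
        if (np.diff(u) > 1e-9).any():
            raise InvalidParameterError("utilities must be weakly decreasing in grade")
        if (self.gamma_shape is None) != (self.gamma_rate is None):
            raise InvalidParameterError("gamma_shape and gamma_rate go together")
        if self.gamma_shape is not None:
            shape = np.asarray(self.gamma_shape, dtype=float)
            rate = np.asarray(self.gamma_rate, dtype=float)
            if shape.shape != (6,) or rate.shape != (6,):
                raise InvalidParameterError("gamma parameters cover grades 0..5")
            if (shape <= 0).any() or (rate <= 0).any():
                raise InvalidParameterError("gamma parameters must be positive")
            if (np.abs(shape / rate - u[:6]) > 0.01).any():
                raise InvalidParameterError(
                    "gamma mean (shape/rate) must be within 0.01 of the utility"
                )

    def as_array(self) -> np.ndarray:
        return np.asarray(self.utilities, dtype=float)


@dataclass(frozen=True)
class EconParams:
    """Discounting, horizon and willingness-to-pay settings."""

    discount_rate: float = 0.02
    horizon_months: int = 60
    wtp_jpy_per_qaly: float = 5_000_000.0
    exchange_rate_jpy_per_usd: float = 131.88

    def __post_init__(self):
        if self.discount_rate < 0:
            raise InvalidParameterError("discount_rate must be >= 0")
        if self.horizon_months < 4:
            raise InvalidParameterError("horizon_months must be >= 4")
        if self.wtp_jpy_per_qaly < 0 or self.exchange_rate_jpy_per_usd <= 0:
            raise InvalidParameterError("WTP and exchange rate must be positive")

    @property
    def wtp_usd_per_qaly(self) -> float:
        return convert_wtp(self.wtp_jpy_per_qaly, self.exchange_rate_jpy_per_usd)


def convert_wtp(wtp_jpy: float, rate_jpy_per_usd: float) -> float:
    """Willingness-to-pay threshold in whole USD per QALY."""
    if rate_jpy_per_usd <= 0:
        raise InvalidParameterError("exchange rate must be positive")
    return float(round(wtp_jpy / rate_jpy_per_usd))


def qalys_of_trace(
    trace: markov.CohortTrace,
    utilities,
    discount_rate: float = 0.02,
    start_month: int = 4,
) -> float:
    """Discounted QALYs accrued by the traced cohort from ``start_month`` on.

    Each month contributes 1/12 of a year weighted by the occupancy-utility
    product and the discount factor (1+r)^(-(m-1)/12).
    """
    if trace.fine is None:
        raise InvalidParameterError("trace has no fine occupancy; call split_fine first")
    u = utilities.as_array() if isinstance(utilities, UtilityTable) else np.asarray(
        utilities, dtype=float
    )
    mask = trace.months >= start_month
    occ = trace.fine[mask]
    disc = costmod.discount_factors(trace.months[mask], discount_rate)
    return float((occ @ u) @ disc / 12.0)


def icer(delta_cost: float, delta_qaly: float):
    """Incremental cost-effectiveness ratio or its qualitative verdict."""
    if delta_qaly == 0.0:
        return Verdict.UNDEFINED
    if delta_cost < 0.0 and delta_qaly > 0.0:
        return Verdict.DOMINANT
    if delta_cost > 0.0 and delta_qaly < 0.0:
        return Verdict.DOMINATED
    return delta_cost / delta_qaly


def icer_below_wtp(value, wtp_usd: float) -> bool:
    """Whether an ICER (or verdict) is acceptable at the WTP threshold."""
    if value is Verdict.DOMINANT:
        return True
    if value in (Verdict.DOMINATED, Verdict.UNDEFINED):
        return False
    return value < wtp_usd


@dataclass(frozen=True)
class ArmResult:
    """Per-arm discounted costs by category and QALYs (per patient, USD)."""

    acute_medical_cost: float
    ltc_cost: float
    qalys: float

    @property
    def total_cost(self) -> float:
        return self.acute_medical_cost + self.ltc_cost


@dataclass(frozen=True)
class CEAResult:
    """Two-arm incremental cost-utility result under both perspectives."""

    seven_day: ArmResult
    control: ArmResult

    @property
    def delta_medical(self) -> float:
        return self.seven_day.acute_medical_cost - self.control.acute_medical_cost

    @property
    def delta_ltc(self) -> float:
        return self.seven_day.ltc_cost - self.control.ltc_cost

    @property
    def delta_total(self) -> float:
        return self.seven_day.total_cost - self.control.total_cost

    @property
    def delta_qaly(self) -> float:
        return self.seven_day.qalys - self.control.qalys

    @property
    def icer_healthcare(self):
        return icer(self.delta_medical, self.delta_qaly)

    @property
    def icer_combined(self):
        return icer(self.delta_total, self.delta_qaly)

    def to_dict(self) -> dict:
        def fmt(v):
            return v.value if isinstance(v, Verdict) else round(v)

        return {
            "seven_day": {
                "medical_cost_usd": self.seven_day.acute_medical_cost,
                "ltc_cost_usd": self.seven_day.ltc_cost,
                "total_cost_usd": self.seven_day.total_cost,
                "qalys": self.seven_day.qalys,
            },
            "five_six_day": {
                "medical_cost_usd": self.control.acute_medical_cost,
                "ltc_cost_usd": self.control.ltc_cost,
                "total_cost_usd": self.control.total_cost,
                "qalys": self.control.qalys,
            },
            "incremental": {
                "delta_medical_usd": self.delta_medical,
                "delta_ltc_usd": self.delta_ltc,
                "delta_total_usd": self.delta_total,
                "delta_qaly": self.delta_qaly,
            },
            "icer_healthcare_perspective": fmt(self.icer_healthcare),
            "icer_combined_perspective": fmt(self.icer_combined),
        }


def evaluate_arms(
    initial_seven: markov.MRSDistribution,
    initial_control: markov.MRSDistribution,
    schedule: markov.TransitionSchedule,
    split: markov.FineSplit,
    acute_cost_seven: float,
    acute_cost_control: float,
    care_map: costmod.CareNeedsMap,
    utilities,
    discount_rate: float,
    accrue_from_month: int = 4,
    ltc_grade_costs: np.ndarray | None = None,
) -> CEAResult:
    """Core engine: run both arms through a shared schedule and compare.

    The arms differ only in their initial distribution and acute-stage cost;
    transition probabilities, splits, utilities and care costs are shared.
    """
    arms = {}
    for name, initial, acute in (
        ("seven", initial_seven, acute_cost_seven),
        ("control", initial_control, acute_cost_control),
    ):
        trace = markov.split_fine(markov.run_cohort(initial, schedule), split)
        q = qalys_of_trace(trace, utilities, discount_rate, accrue_from_month)
        ltc = costmod.ltc_cost_of_trace(
            trace,
            care_map,
            discount_rate,
            start_month=accrue_from_month,
            grade_costs=ltc_grade_costs,
        )
        arms[name] = ArmResult(acute_medical_cost=acute, ltc_cost=ltc, qalys=q)
    return CEAResult(seven_day=arms["seven"], control=arms["control"])


def run_cea(
    config: "RunConfig",
    life_table: cal.LifeTable | None = None,
    calibrated: cal.CalibratedParams | None = None,
    schedule: markov.TransitionSchedule | None = None,
) -> CEAResult:
    """Base-case cost-utility analysis for a full configuration.

    Resolves the life table and calibrated transition parameters from the
    configuration when not supplied (pass them in to reuse one calibration
    across many runs, e.g. in sensitivity analyses).
    """
    if life_table is None:
        life_table = config.resolve_life_table()
    if calibrated is None:
        calibrated = config.resolve_calibrated_params(life_table)
    m = config.model
    if schedule is None:
        schedule = cal.build_schedule(
            calibrated,
            life_table,
            start_age=m.start_age,
            horizon_months=min(m.horizon_months, 60),
            recovery_window_months=m.recovery_window_months,
            start_month=m.start_month,
        )
        if m.horizon_months > schedule.end_month:
            schedule = cal.extend_schedule(
                calibrated, schedule, life_table, m.horizon_months, start_age=m.start_age
            )
    fees = config.costs.fee_schedule()
    pattern7 = config.costs.pattern_seven_weekdays()
    patternc = config.costs.pattern_control_weekdays()
    dur = config.costs.rehab_duration_days
    return evaluate_arms(
        initial_seven=config.initial_seven(),
        initial_control=config.initial_control(),
        schedule=schedule,
        split=config.fine_split(),
        acute_cost_seven=costmod.expected_acute_cost(pattern7, fees, dur),
        acute_cost_control=costmod.expected_acute_cost(patternc, fees, dur),
        care_map=config.costs.care_needs_map(),
        utilities=config.utility_table(),
        discount_rate=m.discount_rate,
        accrue_from_month=m.accrue_from_month,
    )
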