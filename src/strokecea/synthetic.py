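"""Generators for every input the pipeline needs, with no downloads.

Provides a two-parameter Gompertz-form synthetic life table, forward-model
calibration targets generated from a known ground truth (the oracle for the
calibration parameter-recovery tests), seeded onset-weekday cohorts for
cross-checking the expected acute cost, and the packaged base-case
configuration fixture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .calibration import (
    CalibratedParams,
    CalibrationTargets,
    LifeTable,
    build_schedule,
)
from .errors import InvalidParameterError
from .markov import MRSDistribution, run_cohort

import pandas as pd


def gen_life_table(q75: float, slope: float, ages) -> LifeTable:
    """Synthetic life table with Gompertz-form mortality growth.

    q(age) = min(1, q75 * exp(slope * (age - 75))); ages where q would reach
    1 are dropped with a warning, leaving a valid truncated table.
    """
    if not 0.0 < q75 < 1.0:
        raise InvalidParameterError("q75 must lie in (0, 1)")
    if slope < 0:
        raise InvalidParameterError("gompertz slope must be >= 0")
    ages = np.asarray(list(ages), dtype=int)
    q = q75 * np.exp(slope * (ages - 75.0))
    valid = q < 1.0
    if not valid.all():
        warnings.warn(
            "synthetic life table truncated where q(age) would reach 1",
            stacklevel=2,
        )
        keep = int(np.argmin(valid))  # first invalid index; ages are increasing
        ages, q = ages[:keep], q[:keep]
    if ages.size == 0:
        raise InvalidParameterError("no valid ages remain in synthetic life table")
    return LifeTable(ages=ages, qx=q)


@dataclass(frozen=True)
class SyntheticTruth:
    """Known ground-truth parameters behind a synthetic target set."""

    rr_mort_mrs02: float = 1.5
    rr_mort_mrs35: float = 4.0
    p_recover_monthly: float = 0.02
    p_worsen_monthly: float = 0.0
    q75: float = 0.018
    gompertz_slope: float = 0.115
    seed: int = 0

    def params(self) -> CalibratedParams:
        return CalibratedParams(
            rr_mort_mrs02=self.rr_mort_mrs02,
            rr_mort_mrs35=self.rr_mort_mrs35,
            p_recover_monthly=self.p_recover_monthly,
            p_worsen_monthly=self.p_worsen_monthly,
        )

    def life_table(self, start_age: int = 75, horizon_months: int = 60) -> LifeTable:
        years = (horizon_months + 11) // 12
        return gen_life_table(
            self.q75, self.gompertz_slope, range(start_age, start_age + years + 1)
        )


def gen_calibration_targets(
    truth: SyntheticTruth,
    initial: MRSDistribution,
    landmark_months=(12, 24, 36, 48, 60),
    p02_months=(12,),
    start_age: int = 75,
    recovery_window_months: int = 12,
    start_month: int = 3,
    life_table: LifeTable | None = None,
) -> CalibrationTargets:
    """Forward-model targets: run the truth and read off the landmarks.

    Survival targets are conditional on being alive at the model start;
    independence-among-survivors targets are emitted at ``p02_months``.
    Deterministic by construction.
    """
    landmark_months = sorted(int(m) for m in landmark_months)
    if life_table is None:
        horizon = max(landmark_months) if landmark_months else 60
        life_table = truth.life_table(start_age, horizon)
    horizon = max(landmark_months) if landmark_months else start_month + 1
    schedule = build_schedule(
        truth.params(),
        life_table,
        start_age=start_age,
        horizon_months=max(horizon, start_month + 1),
        recovery_window_months=recovery_window_months,
        start_month=start_month,
    )
    trace = run_cohort(initial, schedule)
    surv = trace.survival(conditional_on_start=True)
    p02 = trace.p02_among_alive()
    rows = []
    for m in landmark_months:
        i = trace.at_month(m)
        rows.append(
            {
                "month": m,
                "survival": surv[i],
                "p02_among_alive": p02[i] if m in set(p02_months) else np.nan,
            }
        )
    return CalibrationTargets(pd.DataFrame(rows, columns=["month", "survival", "p02_among_alive"]))


def gen_onset_cohort(n: int, seed: int) -> np.ndarray:
    """Seeded i.i.d. uniform onset weekdays (0=Monday .. 6=Sunday)."""
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.integers(0, 7, size=n)


def paper_fixture():
    """The complete base-case configuration with all published parameters."""
    from .config import RunConfig

    return RunConfig()
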