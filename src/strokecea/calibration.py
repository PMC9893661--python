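"""Transition-probability construction anchored to a general-population life table.

Monthly death probabilities for each living state are the age-matched
general-population monthly mortality multiplied by a state-specific
disease-related mortality risk ratio.  The two risk ratios and a first-year
monthly recovery probability (disabled -> independent) are free parameters,
estimated by least-squares calibration against landmark survival (and,
optionally, independence-among-survivors) targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import CalibrationError, InvalidParameterError, ModelConstructionError
from .markov import MRSDistribution, TransitionSchedule, run_cohort


def annual_to_monthly_prob(q_annual):
    """Convert an annual death probability to a monthly one.

    Uses the constant-hazard identity 1 - (1 - q)**(1/12), so compounding
    twelve monthly cycles reproduces the annual probability exactly.
    Accepts scalars or arrays.
    """
    q = np.asarray(q_annual, dtype=float)
    if (q < 0).any() or (q >= 1).any():
        raise InvalidParameterError("q_annual must lie in [0, 1)")
    out = 1.0 - (1.0 - q) ** (1.0 / 12.0)
    return float(out) if np.isscalar(q_annual) else out


@dataclass(frozen=True)
class LifeTable:
    """Age-indexed annual death probabilities q(age)."""

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        if ages.shape != qx.shape or ages.ndim != 1 or ages.size == 0:
            raise InvalidParameterError("life table must be 1-D and non-empty")
        if np.any(np.diff(ages) != 1):
            raise InvalidParameterError("ages must be strictly increasing and contiguous")
        if (qx < 0).any() or (qx >= 1).any():
            raise InvalidParameterError("annual death probabilities must lie in [0, 1)")

    def q_annual(self, age: int) -> float:
        idx = age - int(self.ages[0])
        if idx < 0 or idx >= self.ages.size:
            raise InvalidParameterError(
                f"age {age} outside life table range "
                f"[{self.ages[0]}, {self.ages[-1]}]"
            )
        return float(self.qx[idx])

    def q_monthly(self, age: int) -> float:
        return annual_to_monthly_prob(self.q_annual(age))

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path, comment="#")
        if not {"age", "qx"}.issubset(df.columns):
            raise InvalidParameterError(f"{path}: expected columns age,qx")
        return cls(ages=df["age"].to_numpy(), qx=df["qx"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"age": self.ages, "qx": self.qx}).to_csv(path, index=False)


@dataclass(frozen=True)
class CalibrationTargets:
    """Landmark calibration targets.

    One row per landmark month since onset: cohort survival conditional on
    being alive at the model start (month 3), and optionally the proportion
    functionally independent among survivors.
    """

    table: pd.DataFrame  # columns: month, survival, p02_among_alive (NaN ok)

    def __post_init__(self):
        df = self.table.copy()
        required = {"month", "survival"}
        if not required.issubset(df.columns):
            raise InvalidParameterError("targets need columns month,survival")
        if "p02_among_alive" not in df.columns:
            df["p02_among_alive"] = np.nan
        df = df[["month", "survival", "p02_among_alive"]].reset_index(drop=True)
        object.__setattr__(self, "table", df)
        vals = pd.concat([df["survival"].dropna(), df["p02_among_alive"].dropna()])
        if ((vals < 0) | (vals > 1)).any():
            raise InvalidParameterError("target probabilities must lie in [0, 1]")

    @property
    def n_values(self) -> int:
        return int(
            self.table["survival"].notna().sum()
            + self.table["p02_among_alive"].notna().sum()
        )

    @classmethod
    def from_csv(cls, path) -> "CalibrationTargets":
        return cls(pd.read_csv(path, comment="#"))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass(frozen=True)
class CalibratedParams:
    """Free transition parameters of the Markov model."""

    rr_mort_mrs02: float
    rr_mort_mrs35: float
    p_recover_monthly: float
    p_worsen_monthly: float = 0.0

    def __post_init__(self):
        if self.rr_mort_mrs02 < 0 or self.rr_mort_mrs35 < 0:
            raise InvalidParameterError("mortality risk ratios must be >= 0")
        for name in ("p_recover_monthly", "p_worsen_monthly"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name}={v} outside [0, 1]")


def build_schedule(
    params: CalibratedParams,
    life_table: LifeTable,
    start_age: int = 75,
    horizon_months: int = 60,
    recovery_window_months: int = 12,
    start_month: int = 3,
) -> TransitionSchedule:
    """Per-cycle transition matrices from the life table and free parameters.

    The transition landing on month m (since onset) uses the life-table row
    for attained age ``start_age + (m - 1) // 12``; recovery is allowed only
    while the destination month is within the recovery window.
    """
    if horizon_months <= start_month:
        raise ModelConstructionError("horizon must exceed the start month")
    months = np.arange(start_month + 1, horizon_months + 1)
    mats = np.empty((months.size, 3, 3), dtype=float)
    for k, m in enumerate(months):
        age = start_age + (m - 1) // 12
        qm = life_table.q_monthly(age)
        d02 = qm * params.rr_mort_mrs02
        d35 = qm * params.rr_mort_mrs35
        rec = params.p_recover_monthly if m <= recovery_window_months else 0.0
        wor = params.p_worsen_monthly
        if d02 > 1.0 or d35 > 1.0:
            raise ModelConstructionError(
                f"cycle landing on month {m}: risk-ratio-scaled monthly death "
                f"probability exceeds 1 (mRS0-2: {d02:.4f}, mRS3-5: {d35:.4f})"
            )
        if d02 + wor > 1.0 or d35 + rec > 1.0:
            raise ModelConstructionError(
                f"cycle landing on month {m}: outgoing probabilities exceed 1"
            )
        mats[k] = [
            [1.0 - wor - d02, wor, d02],
            [rec, 1.0 - rec - d35, d35],
            [0.0, 0.0, 1.0],
        ]
    return TransitionSchedule(matrices=mats, months=months)


def extend_schedule(
    params: CalibratedParams,
    schedule: TransitionSchedule,
    life_table: LifeTable,
    to_month: int,
    start_age: int = 75,
) -> TransitionSchedule:
    """Extend a schedule beyond its horizon for longer scenario runs.

    Extension cycles reuse the final-year non-mortality parameters (recovery
    is over, worsening unchanged) while death probabilities keep tracking
    attained-age life-table mortality times the same risk ratios.
    """
    if to_month <= schedule.end_month:
        raise InvalidParameterError(
            f"to_month={to_month} must exceed current horizon {schedule.end_month}"
        )
    tail = build_schedule(
        params,
        life_table,
        start_age=start_age,
        horizon_months=to_month,
        recovery_window_months=0,  # extension is always past the recovery window
        start_month=schedule.end_month,
    )
    return TransitionSchedule(
        matrices=np.concatenate([schedule.matrices, tail.matrices]),
        months=np.concatenate([schedule.months, tail.months]),
    )


@dataclass
class CalibrationResult:
    params: CalibratedParams
    objective: float
    residuals: pd.DataFrame = field(repr=False)
    n_evaluations: int = 0


def _predict_targets(
    params: CalibratedParams,
    targets: CalibrationTargets,
    life_table: LifeTable,
    initial: MRSDistribution,
    **schedule_kwargs,
) -> pd.DataFrame:
    schedule = build_schedule(params, life_table, **schedule_kwargs)
    trace = run_cohort(initial, schedule)
    surv = trace.survival(conditional_on_start=True)
    p02 = trace.p02_among_alive()
    rows = []
    for _, row in targets.table.iterrows():
        i = trace.at_month(int(row["month"]))
        rows.append(
            {
                "month": int(row["month"]),
                "survival_model": surv[i],
                "survival_target": row["survival"],
                "p02_model": p02[i],
                "p02_target": row["p02_among_alive"],
            }
        )
    return pd.DataFrame(rows)


def _objective_from_residuals(pred: pd.DataFrame) -> float:
    res = pred["survival_model"] - pred["survival_target"]
    sse = float((res.dropna() ** 2).sum())
    mask = pred["p02_target"].notna()
    if mask.any():
        res2 = pred.loc[mask, "p02_model"] - pred.loc[mask, "p02_target"]
        sse += float((res2**2).sum())
    return sse


def calibrate(
    targets: CalibrationTargets,
    life_table: LifeTable,
    initial: MRSDistribution,
    start_age: int = 75,
    horizon_months: int = 60,
    recovery_window_months: int = 12,
    start_month: int = 3,
    rr_bounds: tuple[float, float] = (1.0, 20.0),
    p_bounds: tuple[float, float] = (0.0, 0.2),
    grid_points: int = 10,
    tie_mortality_ratios: bool = False,
    fit_worsening: bool = False,
    tol: float = 1e-8,
    max_objective: float | None = None,
) -> CalibrationResult:
    """Least-squares calibration of the free transition parameters.

    Minimizes the unweighted sum of squared differences between the model's
    and the targets' landmark values (survival, plus independence-among-
    survivors where given).  A coarse grid over the parameter bounds seeds a
    bounded Nelder-Mead refinement from the best few grid points; the search
    is fully deterministic.
    """
    names = ["rr_mort_mrs02"]
    bounds = [rr_bounds]
    if not tie_mortality_ratios:
        names.append("rr_mort_mrs35")
        bounds.append(rr_bounds)
    names.append("p_recover_monthly")
    bounds.append(p_bounds)
    if fit_worsening:
        names.append("p_worsen_monthly")
        bounds.append(p_bounds)

    if targets.n_values < len(names):
        raise InvalidParameterError(
            f"insufficient targets: {targets.n_values} values for "
            f"{len(names)} free parameters"
        )

    sched_kwargs = dict(
        start_age=start_age,
        horizon_months=horizon_months,
        recovery_window_months=recovery_window_months,
        start_month=start_month,
    )
    n_eval = 0

    def to_params(x) -> CalibratedParams:
        d = dict(zip(names, x))
        if tie_mortality_ratios:
            d["rr_mort_mrs35"] = d["rr_mort_mrs02"]
        d.setdefault("p_worsen_monthly", 0.0)
        return CalibratedParams(**d)

    # Fast objective: per-cycle general-population monthly mortality and the
    # recovery-window mask are fixed, so each candidate needs only a scalar
    # recursion over the two living states.  The full schedule/trace engine
    # recomputes the reported residuals at the optimum, keeping the two
    # paths mutually checking.
    months = np.arange(start_month + 1, horizon_months + 1)
    qm = np.array(
        [life_table.q_monthly(start_age + (m - 1) // 12) for m in months]
    )
    rec_open = months <= recovery_window_months
    t_months = targets.table["month"].to_numpy(dtype=int)
    if (t_months <= start_month).any() or (t_months > horizon_months).any():
        raise InvalidParameterError("target months must lie within the model horizon")
    landmark_idx = {m: i + 1 for i, m in enumerate(months)}
    t_idx = np.array([landmark_idx[m] for m in t_months])
    t_surv = targets.table["survival"].to_numpy(dtype=float)
    t_p02 = targets.table["p02_among_alive"].to_numpy(dtype=float)

    def objective(x) -> float:
        nonlocal n_eval
        n_eval += 1
        x = np.clip(x, [b[0] for b in bounds], [b[1] for b in bounds])
        p = to_params(x)
        d02 = qm * p.rr_mort_mrs02
        d35 = qm * p.rr_mort_mrs35
        if d02.max() > 1.0 or d35.max() > 1.0:
            return 1e6
        p02 = np.empty(months.size + 1)
        p35 = np.empty(months.size + 1)
        p02[0], p35[0] = initial.p_mrs02, initial.p_mrs35
        w = p.p_worsen_monthly
        for k in range(months.size):
            rec = p.p_recover_monthly if rec_open[k] else 0.0
            p02[k + 1] = p02[k] * (1.0 - w - d02[k]) + p35[k] * rec
            p35[k + 1] = p02[k] * w + p35[k] * (1.0 - rec - d35[k])
        alive = p02 + p35
        surv = alive / alive[0]
        sse = float(np.nansum((surv[t_idx] - t_surv) ** 2))
        mask = ~np.isnan(t_p02)
        if mask.any():
            idx = t_idx[mask]
            sse += float(np.sum((p02[idx] / alive[idx] - t_p02[mask]) ** 2))
        return sse

    axes = [np.linspace(lo, hi, grid_points) for lo, hi in bounds]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, len(bounds))
    # Multiple refinement starts guard against near-symmetric local minima
    # (the two mortality ratios can nearly swap roles on sparse targets).
    grid_obj = np.array([objective(x) for x in grid])
    starts = grid[np.argsort(grid_obj)[:8]]

    best_x, best_f = None, np.inf
    for x0 in starts:
        res = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            bounds=bounds,
            options={"xatol": 1e-9, "fatol": tol, "maxiter": 4000},
        )
        if res.fun < best_f:
            best_x, best_f = res.x, float(res.fun)

    params = to_params(np.clip(best_x, [b[0] for b in bounds], [b[1] for b in bounds]))
    residuals = _predict_targets(params, targets, life_table, initial, **sched_kwargs)
    result = CalibrationResult(
        params=params, objective=best_f, residuals=residuals, n_evaluations=n_eval
    )
    if max_objective is not None and best_f > max_objective:
        raise CalibrationError(
            f"calibration objective {best_f:.3e} above tolerance {max_objective:.3e}",
            result=result,
        )
    return result
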