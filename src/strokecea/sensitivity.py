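"""Deterministic and probabilistic sensitivity analysis, plus scenarios.

One-way deterministic sensitivity analysis (DSA) re-runs the cost-utility
analysis with a single parameter moved to its lower/upper setting, producing
tornado-ordered rows.  Probabilistic sensitivity analysis (PSA) draws the
efficacy risk ratio, daily rehabilitation units, utilities and long-term-care
costs from their published distributions and summarizes the share of
iterations acceptable at the willingness-to-pay threshold.  Scenario runs
change the discount rate and extend the horizon to ten years.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import calibration as cal
from . import cea
from . import costs as costmod
from .config import RunConfig
from .errors import InvalidParameterError
from .markov import MRSDistribution


@dataclass(frozen=True)
class DSASpec:
    """One tornado parameter: named lower/upper config transforms."""

    parameter: str
    lower: Callable[[RunConfig], RunConfig]
    upper: Callable[[RunConfig], RunConfig]


def _with(config: RunConfig, mutate: Callable[[RunConfig], None]) -> RunConfig:
    out = config.model_copy(deep=True)
    mutate(out)
    return out


def _scale_fees(factor):
    def mutate(cfg):
        f = cfg.costs.fees
        f.base_fee_per_unit *= factor
        f.surcharge_30d_per_unit *= factor
        f.surcharge_14d_per_unit *= factor

    return mutate


def _scale_ltc_fees(factor):
    def mutate(cfg):
        for grade in cfg.costs.care.values():
            for lv in grade.levels:
                lv.monthly_cost *= factor

    return mutate


def _scale_utilization(factor):
    def mutate(cfg):
        for grade in cfg.costs.care.values():
            grade.utilization = min(1.0, grade.utilization * factor)

    return mutate


def _set_units(units):
    def mutate(cfg):
        cfg.costs.fees.units_per_day = units

    return mutate


def _set_initial_seven(p02, p35, pdead):
    def mutate(cfg):
        cfg.model.initial_seven = (p02, p35, pdead)

    return mutate


def _set_split(attr, triple):
    def mutate(cfg):
        setattr(cfg.model, attr, triple)

    return mutate


def default_dsa_specs(config: RunConfig) -> list[DSASpec]:
    """The published one-way sensitivity grid.

    Efficacy bounds are applied directly as intervention-arm initial
    distributions; fine splits move to all-best / all-worst grade;
    utilization rates shift by +/-10% (capped at 1); rehabilitation and
    long-term-care fees scale by -50%/+100%; units/day spans 1 to 9.
    """
    pdead = config.model.p_dead_initial
    return [
        DSASpec(
            "efficacy_initial_mrs02",
            lambda c: _with(c, _set_initial_seven(0.450, 1 - 0.450 - pdead, pdead)),
            lambda c: _with(c, _set_initial_seven(0.538, 1 - 0.538 - pdead, pdead)),
        ),
        DSASpec(
            "split_mrs35",
            lambda c: _with(c, _set_split("split35", (1.0, 0.0, 0.0))),
            lambda c: _with(c, _set_split("split35", (0.0, 0.0, 1.0))),
        ),
        DSASpec(
            "split_mrs02",
            lambda c: _with(c, _set_split("split02", (1.0, 0.0, 0.0))),
            lambda c: _with(c, _set_split("split02", (0.0, 0.0, 1.0))),
        ),
        DSASpec(
            "ltc_utilization",
            lambda c: _with(c, _scale_utilization(0.9)),
            lambda c: _with(c, _scale_utilization(1.1)),
        ),
        DSASpec(
            "rehab_fees",
            lambda c: _with(c, _scale_fees(0.5)),
            lambda c: _with(c, _scale_fees(2.0)),
        ),
        DSASpec(
            "ltc_fees",
            lambda c: _with(c, _scale_ltc_fees(0.5)),
            lambda c: _with(c, _scale_ltc_fees(2.0)),
        ),
        DSASpec(
            "units_per_day",
            lambda c: _with(c, _set_units(1.0)),
            lambda c: _with(c, _set_units(9.0)),
        ),
    ]


def _verdict_or_value(v):
    return v.value if isinstance(v, cea.Verdict) else float(v)


def run_dsa(
    config: RunConfig,
    specs: list[DSASpec] | None = None,
    life_table: cal.LifeTable | None = None,
    calibrated: cal.CalibratedParams | None = None,
) -> pd.DataFrame:
    """One-way DSA over the spec list; rows in tornado order.

    Calibration is shared across rows (no DSA parameter enters the
    calibration), so the transition schedule is computed once.  A row whose
    derived configuration is invalid is recorded as an error entry and the
    run continues.
    """
    if specs is None:
        specs = default_dsa_specs(config)
    if life_table is None:
        life_table = config.resolve_life_table()
    if calibrated is None:
        calibrated = config.resolve_calibrated_params(life_table)

    rows = []
    for spec in specs:
        for bound, transform in (("lower", spec.lower), ("upper", spec.upper)):
            row = {"parameter": spec.parameter, "bound": bound}
            try:
                modified = transform(config)
                result = cea.run_cea(modified, life_table=life_table, calibrated=calibrated)
                row.update(
                    icer_healthcare=_verdict_or_value(result.icer_healthcare),
                    verdict_healthcare=str(
                        result.icer_healthcare.value
                        if isinstance(result.icer_healthcare, cea.Verdict)
                        else "value"
                    ),
                    icer_combined=_verdict_or_value(result.icer_combined),
                    verdict_combined=str(
                        result.icer_combined.value
                        if isinstance(result.icer_combined, cea.Verdict)
                        else "value"
                    ),
                    delta_qaly=result.delta_qaly,
                    delta_total=result.delta_total,
                    error="",
                )
            except Exception as exc:  # row-level failure must not stop the grid
                row.update(
                    icer_healthcare=np.nan,
                    verdict_healthcare="error",
                    icer_combined=np.nan,
                    verdict_combined="error",
                    delta_qaly=np.nan,
                    delta_total=np.nan,
                    error=str(exc),
                )
            rows.append(row)
    df = pd.DataFrame(rows)

    # Tornado order: widest healthcare-perspective ICER span first.
    def span(group):
        vals = pd.to_numeric(group["icer_healthcare"], errors="coerce")
        return float(vals.max() - vals.min()) if vals.notna().any() else np.inf

    spans = df.groupby("parameter", sort=False).apply(span, include_groups=False)
    order = spans.sort_values(ascending=False).index
    df["parameter"] = pd.Categorical(df["parameter"], categories=order, ordered=True)
    df = df.sort_values(["parameter", "bound"]).reset_index(drop=True)
    df["parameter"] = df["parameter"].astype(str)
    return df


@dataclass(frozen=True)
class PSAConfig:
    """Distributional settings for the probabilistic sensitivity analysis."""

    n_iterations: int = 1000
    seed: int = 0
    risk_ratio_mean: float = 1.31
    risk_ratio_sd: float = 0.05
    units_per_day_mean: float = 4.3
    units_per_day_sd: float = 1.0
    draw_utilities: bool = True
    draw_ltc_costs: bool = True
    max_redraws: int = 100

    def __post_init__(self):
        if self.n_iterations < 1:
            raise InvalidParameterError("n_iterations must be >= 1")
        if min(self.risk_ratio_sd, self.units_per_day_sd) < 0:
            raise InvalidParameterError("standard deviations must be >= 0")


@dataclass
class PSAOutput:
    """Per-iteration draws/outcomes and the acceptability summary."""

    draws: pd.DataFrame = field(repr=False)
    summary: dict

    def ce_plane(self, perspective: str = "combined") -> pd.DataFrame:
        col = "delta_total" if perspective == "combined" else "delta_medical"
        return self.draws[["delta_qaly", col]].rename(columns={col: "delta_cost"})


def run_psa(
    config: RunConfig,
    psa: PSAConfig | None = None,
    life_table: cal.LifeTable | None = None,
    calibrated: cal.CalibratedParams | None = None,
) -> PSAOutput:
    """Seeded Monte-Carlo PSA; identical seeds give identical output.

    Each iteration independently draws the efficacy risk ratio (normal,
    clipped so the derived initial distribution stays valid), units per day
    (normal, re-drawn while non-positive), grade utilities (gamma, capped at
    1) and care-level monthly costs (gamma), then rebuilds both arms on the
    shared calibrated schedule.
    """
    if psa is None:
        p = config.psa
        psa = PSAConfig(
            n_iterations=p.n_iterations,
            seed=config.seed,
            risk_ratio_mean=p.risk_ratio_mean,
            risk_ratio_sd=p.risk_ratio_sd,
            units_per_day_mean=p.units_per_day_mean,
            units_per_day_sd=p.units_per_day_sd,
            draw_utilities=p.draw_utilities,
            draw_ltc_costs=p.draw_ltc_costs,
        )
    if life_table is None:
        life_table = config.resolve_life_table()
    if calibrated is None:
        calibrated = config.resolve_calibrated_params(life_table)

    m = config.model
    schedule = cal.build_schedule(
        calibrated,
        life_table,
        start_age=m.start_age,
        horizon_months=m.horizon_months,
        recovery_window_months=m.recovery_window_months,
        start_month=m.start_month,
    )
    split = config.fine_split()
    care_map = config.costs.care_needs_map()
    utable = config.utility_table()
    base_utilities = utable.as_array()
    fees = config.costs.fee_schedule()
    pattern7 = config.costs.pattern_seven_weekdays()
    patternc = config.costs.pattern_control_weekdays()
    dur = config.costs.rehab_duration_days
    initial_control = config.initial_control()
    econ = config.econ_params()
    wtp_usd = econ.wtp_usd_per_qaly

    # Acute cost is linear in units/day: precompute per-unit-rate costs.
    unit_fees = costmod.FeeSchedule(
        fees.base_fee_per_unit,
        fees.surcharge_30d_per_unit,
        fees.surcharge_14d_per_unit,
        units_per_day=1.0,
    )
    acute7_per_unit = costmod.expected_acute_cost(pattern7, unit_fees, dur)
    acutec_per_unit = costmod.expected_acute_cost(patternc, unit_fees, dur)

    # Gamma draw setup for utilities (grades 0..5) and care-level costs.
    u_shape = np.asarray(utable.gamma_shape) if utable.gamma_shape else None
    u_rate = np.asarray(utable.gamma_rate) if utable.gamma_rate else None
    levels = []  # flat list of (grade, mix index, CareLevel)
    for g, mix in enumerate(care_map.mixes):
        for j, cl in enumerate(mix):
            levels.append((g, j, cl))

    rr_max = (1.0 - m.p_dead_initial) / m.control_p02  # keeps initial valid
    rng = np.random.default_rng(psa.seed)
    n_rr_clipped = n_units_redrawn = n_util_capped = 0
    records = []
    for it in range(psa.n_iterations):
        rr = rng.normal(psa.risk_ratio_mean, psa.risk_ratio_sd)
        rr_clipped = min(max(rr, 1e-9), rr_max)
        if rr_clipped != rr:
            n_rr_clipped += 1
        rr = rr_clipped

        units = rng.normal(psa.units_per_day_mean, psa.units_per_day_sd)
        tries = 0
        while units <= 0.0:
            tries += 1
            if tries > psa.max_redraws:
                raise InvalidParameterError("units/day re-draw limit exceeded")
            units = rng.normal(psa.units_per_day_mean, psa.units_per_day_sd)
        n_units_redrawn += tries

        utilities = base_utilities.copy()
        if psa.draw_utilities and u_shape is not None:
            draws = rng.gamma(u_shape, 1.0 / u_rate)
            n_util_capped += int((draws > 1.0).sum())
            utilities[:6] = np.minimum(draws, 1.0)

        grade_costs = None
        level_draws = {}
        if psa.draw_ltc_costs:
            grade_costs = np.zeros(7)
            for g, j, cl in levels:
                if cl.gamma_shape is not None and cl.gamma_rate is not None:
                    cost = rng.gamma(cl.gamma_shape, 1.0 / cl.gamma_rate)
                else:
                    cost = cl.monthly_cost
                level_draws[cl.level] = cost
                grade_costs[g] += care_map.utilization[g] * cl.share * cost

        initial7 = MRSDistribution(
            m.control_p02 * rr,
            1.0 - m.control_p02 * rr - m.p_dead_initial,
            m.p_dead_initial,
        )
        result = cea.evaluate_arms(
            initial_seven=initial7,
            initial_control=initial_control,
            schedule=schedule,
            split=split,
            acute_cost_seven=units * acute7_per_unit,
            acute_cost_control=units * acutec_per_unit,
            care_map=care_map,
            utilities=utilities,
            discount_rate=m.discount_rate,
            accrue_from_month=m.accrue_from_month,
            ltc_grade_costs=grade_costs,
        )
        rec = {
            "iteration": it,
            "risk_ratio": rr,
            "units_per_day": units,
            **{f"u_mrs{g}": utilities[g] for g in range(6)},
            **{f"cost_{k}": v for k, v in level_draws.items()},
            "delta_medical": result.delta_medical,
            "delta_ltc": result.delta_ltc,
            "delta_total": result.delta_total,
            "delta_qaly": result.delta_qaly,
            "icer_healthcare": _verdict_or_value(result.icer_healthcare),
            "icer_combined": _verdict_or_value(result.icer_combined),
            "below_wtp_healthcare": cea.icer_below_wtp(result.icer_healthcare, wtp_usd),
            "below_wtp_combined": cea.icer_below_wtp(result.icer_combined, wtp_usd),
        }
        records.append(rec)

    draws = pd.DataFrame(records)
    summary = {
        "n_iterations": psa.n_iterations,
        "seed": psa.seed,
        "wtp_usd_per_qaly": wtp_usd,
        "prob_below_wtp_healthcare_pct": 100.0 * draws["below_wtp_healthcare"].mean(),
        "prob_below_wtp_combined_pct": 100.0 * draws["below_wtp_combined"].mean(),
        "mean_delta_qaly": float(draws["delta_qaly"].mean()),
        "mean_delta_medical": float(draws["delta_medical"].mean()),
        "mean_delta_total": float(draws["delta_total"].mean()),
        "truncations": {
            "risk_ratio_clipped": n_rr_clipped,
            "units_per_day_redrawn": n_units_redrawn,
            "utilities_capped": n_util_capped,
        },
    }
    return PSAOutput(draws=draws, summary=summary)


def run_scenarios(
    config: RunConfig,
    life_table: cal.LifeTable | None = None,
    calibrated: cal.CalibratedParams | None = None,
) -> pd.DataFrame:
    """Scenario table: base case, 0%/4% discounting, 10-year horizon."""
    if life_table is None:
        life_table = config.resolve_life_table()
    if calibrated is None:
        calibrated = config.resolve_calibrated_params(life_table)

    scenarios = [
        ("base_case", lambda c: c),
        ("discount_0pct", lambda c: _with(c, lambda x: setattr(x.model, "discount_rate", 0.0))),
        ("discount_4pct", lambda c: _with(c, lambda x: setattr(x.model, "discount_rate", 0.04))),
        ("horizon_10yr", lambda c: _with(c, lambda x: setattr(x.model, "horizon_months", 120))),
    ]
    rows = []
    for name, transform in scenarios:
        modified = transform(config)
        lt = modified.resolve_life_table() if name == "horizon_10yr" else life_table
        result = cea.run_cea(modified, life_table=lt, calibrated=calibrated)
        rows.append(
            {
                "scenario": name,
                "delta_qaly": result.delta_qaly,
                "delta_medical": result.delta_medical,
                "delta_total": result.delta_total,
                "icer_healthcare": _verdict_or_value(result.icer_healthcare),
                "icer_combined": _verdict_or_value(result.icer_combined),
                "qalys_seven_day": result.seven_day.qalys,
                "qalys_control": result.control.qalys,
            }
        )
    return pd.DataFrame(rows)
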