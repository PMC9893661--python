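"""Run configuration: schema, validation, defaults, YAML round-trip.

The default-constructed :class:`RunConfig` carries the complete base-case
parameterization (initial disability distributions, fee schedule, care-needs
mapping, utilities with gamma parameters, discounting, horizon,
willingness-to-pay); a YAML file needs to state only the keys it overrides.
Unknown keys are rejected and every constraint failure names the offending
key.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import calibration as cal
from . import costs as costmod
from . import markov
from .cea import EconParams, UtilityTable
from .errors import ConfigError

PACKAGED_TARGETS = "packaged-synthetic"


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ModelBlock(_Block):
    """Markov structure and epidemiological inputs."""

    control_p02: float = Field(0.376, ge=0, le=1)
    p_dead_initial: float = Field(0.039, ge=0, le=1)
    odds_ratio: float = Field(1.62, gt=0)
    risk_ratio: float = Field(1.31, gt=0)
    # Direct override of the intervention arm's initial (p02, p35, p_dead);
    # when None it is derived as control_p02 * risk_ratio.
    initial_seven: Optional[tuple[float, float, float]] = None
    split02: tuple[float, float, float] = (0.305, 0.298, 0.396)
    split35: tuple[float, float, float] = (0.375, 0.369, 0.256)
    start_age: int = Field(75, ge=0)
    start_month: int = Field(3, ge=0)
    horizon_months: int = Field(60, ge=4)
    recovery_window_months: int = Field(12, ge=0)
    discount_rate: float = Field(0.02, ge=0)
    accrue_from_month: int = Field(4, ge=1)


class SyntheticInputsBlock(_Block):
    """Parameters of the generated stand-in life table and targets."""

    q75: float = Field(0.018, gt=0, lt=1)
    gompertz_slope: float = Field(0.115, ge=0)
    # Ground-truth transition parameters used only when targets == "synthetic".
    rr_mort_mrs02: float = Field(1.5, ge=0)
    rr_mort_mrs35: float = Field(4.0, ge=0)
    p_recover_monthly: float = Field(0.02, ge=0, le=1)
    p_worsen_monthly: float = Field(0.0, ge=0, le=1)
    landmark_months: tuple[int, ...] = (12, 24, 36, 48, 60)
    p02_landmark_months: tuple[int, ...] = (12,)


class CalibrationParamsBlock(_Block):
    rr_mort_mrs02: float = Field(ge=0)
    rr_mort_mrs35: float = Field(ge=0)
    p_recover_monthly: float = Field(ge=0, le=1)
    p_worsen_monthly: float = Field(0.0, ge=0, le=1)

    def to_params(self) -> cal.CalibratedParams:
        return cal.CalibratedParams(**self.model_dump())


class CalibrationBlock(_Block):
    """Where transition parameters come from.

    ``life_table`` is a CSV path or "synthetic"; ``targets`` is a CSV path,
    "synthetic" (generated from the synthetic ground truth) or the packaged
    stand-in set; ``params`` short-circuits calibration entirely.
    """

    life_table: str = "synthetic"
    targets: str = PACKAGED_TARGETS
    params: Optional[CalibrationParamsBlock] = None
    synthetic: SyntheticInputsBlock = SyntheticInputsBlock()
    rr_bounds: tuple[float, float] = (1.0, 20.0)
    p_bounds: tuple[float, float] = (0.0, 0.2)
    grid_points: int = Field(10, ge=2)
    tie_mortality_ratios: bool = False
    fit_worsening: bool = False


class FeeBlock(_Block):
    base_fee_per_unit: float = Field(18.6, ge=0)
    surcharge_30d_per_unit: float = Field(2.41, ge=0)
    surcharge_14d_per_unit: float = Field(3.62, ge=0)
    units_per_day: float = Field(4.3, gt=0)


class CareLevelBlock(_Block):
    level: str
    share: float = Field(ge=0, le=1)
    monthly_cost: float = Field(ge=0)
    gamma_shape: Optional[float] = Field(None, gt=0)
    gamma_rate: Optional[float] = Field(None, gt=0)


class GradeCareBlock(_Block):
    utilization: float = Field(ge=0, le=1)
    levels: list[CareLevelBlock] = []


def _default_care() -> dict[str, GradeCareBlock]:
    def level(name, share, cost, shape, rate):
        return CareLevelBlock(
            level=name, share=share, monthly_cost=cost, gamma_shape=shape, gamma_rate=rate
        )

    return {
        "mrs0": GradeCareBlock(utilization=0.0, levels=[]),
        "mrs1": GradeCareBlock(
            utilization=0.216, levels=[level("support1", 1.0, 219.0, 34.5, 0.2)]
        ),
        "mrs2": GradeCareBlock(
            utilization=0.915, levels=[level("support2", 1.0, 376.0, 36.4, 0.1)]
        ),
        "mrs3": GradeCareBlock(
            utilization=0.985, levels=[level("care1", 1.0, 806.0, 167.2, 0.2)]
        ),
        "mrs4": GradeCareBlock(
            utilization=1.0,
            levels=[
                level("care2", 0.608, 1090.0, 306.1, 0.2),
                level("care3", 0.392, 1596.0, 655.6, 0.4),
            ],
        ),
        "mrs5": GradeCareBlock(
            utilization=1.0,
            levels=[
                level("care4", 0.610, 1914.0, 517.3, 0.3),
                level("care5", 0.390, 2205.0, 686.3, 0.3),
            ],
        ),
        "mrs6": GradeCareBlock(utilization=0.0, levels=[]),
    }


class CostBlock(_Block):
    fees: FeeBlock = FeeBlock()
    rehab_duration_days: int = Field(30, ge=1)
    pattern_seven: list[str] = ["mon", "tue", "wed", "thu", "fri", "sat", "sun"]
    pattern_control: list[str] = ["mon", "tue", "wed", "thu", "fri"]
    care: dict[str, GradeCareBlock] = Field(default_factory=_default_care)
    ltc_start_month: int = Field(4, ge=1)

    @model_validator(mode="after")
    def _check_care_keys(self):
        expected = {f"mrs{g}" for g in range(7)}
        if set(self.care) != expected:
            raise ValueError(f"care must have exactly the keys {sorted(expected)}")
        return self

    def fee_schedule(self) -> costmod.FeeSchedule:
        return costmod.FeeSchedule(**self.fees.model_dump())

    def pattern_seven_weekdays(self) -> frozenset[int]:
        return costmod.parse_weekdays(self.pattern_seven)

    def pattern_control_weekdays(self) -> frozenset[int]:
        return costmod.parse_weekdays(self.pattern_control)

    def care_needs_map(self) -> costmod.CareNeedsMap:
        utilization = tuple(self.care[f"mrs{g}"].utilization for g in range(7))
        mixes = tuple(
            tuple(
                costmod.CareLevel(
                    level=cl.level,
                    share=cl.share,
                    monthly_cost=cl.monthly_cost,
                    gamma_shape=cl.gamma_shape,
                    gamma_rate=cl.gamma_rate,
                )
                for cl in self.care[f"mrs{g}"].levels
            )
            for g in range(7)
        )
        return costmod.CareNeedsMap(utilization=utilization, mixes=mixes)


class UtilityEntry(_Block):
    utility: float = Field(ge=0, le=1)
    gamma_shape: Optional[float] = Field(None, gt=0)
    gamma_rate: Optional[float] = Field(None, gt=0)


def _default_utilities() -> dict[str, UtilityEntry]:
    vals = {
        "mrs0": (0.89, 61.0, 68.5),
        "mrs1": (0.797, 90.0, 113.0),
        "mrs2": (0.65, 77.1, 118.7),
        "mrs3": (0.588, 77.0, 131.0),
        "mrs4": (0.363, 24.7, 68.1),
        "mrs5": (0.092, 1.32, 14.4),
        "mrs6": (0.0, None, None),
    }
    return {
        k: UtilityEntry(utility=u, gamma_shape=a, gamma_rate=b)
        for k, (u, a, b) in vals.items()
    }


class EconBlock(_Block):
    wtp_jpy_per_qaly: float = Field(5_000_000.0, ge=0)
    exchange_rate_jpy_per_usd: float = Field(131.88, gt=0)


class PSABlock(_Block):
    n_iterations: int = Field(1000, ge=1)
    risk_ratio_mean: float = Field(1.31, gt=0)
    risk_ratio_sd: float = Field(0.05, ge=0)
    units_per_day_mean: float = Field(4.3, gt=0)
    units_per_day_sd: float = Field(1.0, ge=0)
    draw_utilities: bool = True
    draw_ltc_costs: bool = True


class RunConfig(_Block):
    """Complete, validated model configuration."""

    seed: int = 0
    output_dir: str = "results"
    model: ModelBlock = ModelBlock()
    calibration: CalibrationBlock = CalibrationBlock()
    costs: CostBlock = CostBlock()
    utilities: dict[str, UtilityEntry] = Field(default_factory=_default_utilities)
    econ: EconBlock = EconBlock()
    psa: PSABlock = PSABlock()

    @model_validator(mode="after")
    def _check_utility_keys(self):
        expected = {f"mrs{g}" for g in range(7)}
        if set(self.utilities) != expected:
            raise ValueError(f"utilities must have exactly the keys {sorted(expected)}")
        return self

    # -- builders ---------------------------------------------------------

    def initial_control(self) -> markov.MRSDistribution:
        m = self.model
        return markov.MRSDistribution(
            m.control_p02, 1.0 - m.control_p02 - m.p_dead_initial, m.p_dead_initial
        )

    def initial_seven(self) -> markov.MRSDistribution:
        m = self.model
        if m.initial_seven is not None:
            return markov.MRSDistribution(*m.initial_seven)
        return markov.derive_initial_distribution(
            m.control_p02, m.risk_ratio, m.p_dead_initial
        )

    def fine_split(self) -> markov.FineSplit:
        return markov.FineSplit(split02=self.model.split02, split35=self.model.split35)

    def utility_table(self) -> UtilityTable:
        u = tuple(self.utilities[f"mrs{g}"].utility for g in range(7))
        shapes = [self.utilities[f"mrs{g}"].gamma_shape for g in range(6)]
        rates = [self.utilities[f"mrs{g}"].gamma_rate for g in range(6)]
        if any(s is None for s in shapes) or any(r is None for r in rates):
            return UtilityTable(utilities=u)
        return UtilityTable(
            utilities=u, gamma_shape=tuple(shapes), gamma_rate=tuple(rates)
        )

    def econ_params(self) -> EconParams:
        return EconParams(
            discount_rate=self.model.discount_rate,
            horizon_months=self.model.horizon_months,
            wtp_jpy_per_qaly=self.econ.wtp_jpy_per_qaly,
            exchange_rate_jpy_per_usd=self.econ.exchange_rate_jpy_per_usd,
        )

    # -- input resolution -------------------------------------------------

    def resolve_life_table(self) -> cal.LifeTable:
        src = self.calibration.life_table
        if src == "synthetic":
            from .synthetic import gen_life_table

            syn = self.calibration.synthetic
            years_needed = (self.model.horizon_months + 11) // 12
            ages = range(
                self.model.start_age, self.model.start_age + years_needed + 1
            )
            return gen_life_table(syn.q75, syn.gompertz_slope, ages)
        if not Path(src).is_file():
            raise ConfigError(f"calibration.life_table: file not found: {src}")
        return cal.LifeTable.from_csv(src)

    def resolve_calibration_targets(self) -> cal.CalibrationTargets:
        src = self.calibration.targets
        if src == PACKAGED_TARGETS:
            ref = resources.files("strokecea.data") / "calibration_targets_synthetic.csv"
            with resources.as_file(ref) as path:
                return cal.CalibrationTargets.from_csv(path)
        if src == "synthetic":
            from .synthetic import SyntheticTruth, gen_calibration_targets

            syn = self.calibration.synthetic
            truth = SyntheticTruth(
                rr_mort_mrs02=syn.rr_mort_mrs02,
                rr_mort_mrs35=syn.rr_mort_mrs35,
                p_recover_monthly=syn.p_recover_monthly,
                p_worsen_monthly=syn.p_worsen_monthly,
                q75=syn.q75,
                gompertz_slope=syn.gompertz_slope,
            )
            return gen_calibration_targets(
                truth,
                self.initial_control(),
                landmark_months=list(syn.landmark_months),
                p02_months=list(syn.p02_landmark_months),
                start_age=self.model.start_age,
                recovery_window_months=self.model.recovery_window_months,
                start_month=self.model.start_month,
            )
        if not Path(src).is_file():
            raise ConfigError(f"calibration.targets: file not found: {src}")
        return cal.CalibrationTargets.from_csv(src)

    def resolve_calibrated_params(
        self, life_table: cal.LifeTable | None = None
    ) -> cal.CalibratedParams:
        c = self.calibration
        if c.params is not None:
            return c.params.to_params()
        if life_table is None:
            life_table = self.resolve_life_table()
        targets = self.resolve_calibration_targets()
        result = cal.calibrate(
            targets,
            life_table,
            self.initial_control(),
            start_age=self.model.start_age,
            horizon_months=min(self.model.horizon_months, 60),
            recovery_window_months=self.model.recovery_window_months,
            start_month=self.model.start_month,
            rr_bounds=c.rr_bounds,
            p_bounds=c.p_bounds,
            grid_points=c.grid_points,
            tie_mortality_ratios=c.tie_mortality_ratios,
            fit_worsening=c.fit_worsening,
        )
        return result.params

    # -- serialization ----------------------------------------------------

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False)


def load_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON) configuration file.

    Missing keys fall back to the base-case defaults; unknown keys and
    constraint violations raise :class:`ConfigError` naming the key.
    """
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except FileNotFoundError as exc:
        raise ConfigError(f"config file not found: {path}") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return validate_config(data)


def validate_config(data: dict) -> RunConfig:
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        lines = []
        for err in exc.errors():
            key = ".".join(str(p) for p in err["loc"]) or "<root>"
            lines.append(f"{key}: {err['msg']}")
        raise ConfigError("invalid configuration: " + "; ".join(lines)) from exc
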