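"""Life-table anchoring, schedule construction, calibration and extension."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import strokecea as sc
from strokecea.errors import (
    CalibrationError,
    InvalidParameterError,
    ModelConstructionError,
)


def flat_life_table(q: float, ages=range(75, 87)) -> sc.LifeTable:
    return sc.LifeTable(ages=np.array(list(ages)), qx=np.full(len(list(ages)), q))


CONTROL = sc.MRSDistribution(0.376, 0.585, 0.039)


class TestAnnualToMonthly:
    @pytest.mark.parametrize(
        "q, expected",
        [
            (0.0, 0.0),
            (0.05, 1.0 - 0.95 ** (1.0 / 12.0)),
            (0.02, 1.0 - 0.98 ** (1.0 / 12.0)),
        ],
    )
    def test_closed_form(self, q, expected):
        assert sc.annual_to_monthly_prob(q) == pytest.approx(expected, abs=1e-15)

    @given(q=st.floats(0.0, 0.999))
    def test_compounding_twelve_cycles_inverts_exactly(self, q):
        qm = sc.annual_to_monthly_prob(q)
        assert 1.0 - (1.0 - qm) ** 12 == pytest.approx(q, abs=1e-12)

    def test_certain_death_rejected(self):
        with pytest.raises(InvalidParameterError):
            sc.annual_to_monthly_prob(1.0)


class TestBuildSchedule:
    def test_monthly_death_is_life_table_times_risk_ratio(self):
        """Flat q=0.024 and risk ratio 5 give monthly disabled-state death
        probability 5*(1-0.976^(1/12))."""
        lt = flat_life_table(0.024)
        params = sc.CalibratedParams(1.0, 5.0, 0.0)
        sched = sc.build_schedule(params, lt)
        expected = 5.0 * (1.0 - 0.976 ** (1.0 / 12.0))
        assert sched.matrices[0, 1, 2] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.010112, abs=5e-7)
        assert np.allclose(sched.matrices.sum(axis=2), 1.0, atol=1e-12)

    def test_recovery_confined_to_window(self):
        lt = flat_life_table(0.02)
        sched = sc.build_schedule(
            sc.CalibratedParams(1.0, 1.0, 0.05), lt, recovery_window_months=12
        )
        rec = sched.matrices[:, 1, 0]
        assert np.all(rec[sched.months <= 12] == 0.05)
        assert np.all(rec[sched.months > 12] == 0.0)

    def test_null_disease_effect_tracks_life_table(self):
        """With both risk ratios 1 and no recovery, cohort survival equals
        the general-population survival product at every landmark."""
        lt = flat_life_table(0.024)
        sched = sc.build_schedule(sc.CalibratedParams(1.0, 1.0, 0.0), lt)
        trace = sc.run_cohort(CONTROL, sched)
        qm = 1.0 - 0.976 ** (1.0 / 12.0)
        for month in (12, 24, 36, 48, 60):
            i = trace.at_month(month)
            expected = (1.0 - qm) ** (month - 3)
            assert trace.survival(conditional_on_start=True)[i] == pytest.approx(
                expected, abs=1e-9
            )

    def test_attained_age_advances_annually(self):
        ages = np.arange(75, 87)
        lt = sc.LifeTable(ages=ages, qx=0.01 + 0.002 * (ages - 75))
        sched = sc.build_schedule(sc.CalibratedParams(1.0, 1.0, 0.0), lt)
        d = sched.matrices[:, 0, 2]
        # months 4..12 use age 75, months 13..24 age 76
        assert np.allclose(d[sched.months <= 12], sc.annual_to_monthly_prob(0.01))
        m13_24 = (sched.months >= 13) & (sched.months <= 24)
        assert np.allclose(d[m13_24], sc.annual_to_monthly_prob(0.012))

    def test_excess_mortality_error_names_cycle(self):
        lt = flat_life_table(0.5)
        with pytest.raises(ModelConstructionError, match="month"):
            sc.build_schedule(sc.CalibratedParams(1.0, 20.0, 0.0), lt)

    def test_monotone_in_disabled_mortality_ratio(self):
        lt = flat_life_table(0.02)
        surv = []
        for rr35 in (2.0, 4.0, 8.0):
            sched = sc.build_schedule(sc.CalibratedParams(1.5, rr35, 0.01), lt)
            trace = sc.run_cohort(CONTROL, sched)
            surv.append(trace.survival()[-1])
        assert surv[0] > surv[1] > surv[2]


class TestCalibrate:
    def test_recovers_known_parameters(self):
        """Round-trip: targets generated from known transition parameters are
        fitted back to those parameters."""
        truth = sc.SyntheticTruth(
            rr_mort_mrs02=1.5, rr_mort_mrs35=4.0, p_recover_monthly=0.02
        )
        lt = truth.life_table()
        targets = sc.gen_calibration_targets(truth, CONTROL, life_table=lt)
        result = sc.calibrate(targets, lt, CONTROL)
        assert result.params.rr_mort_mrs02 == pytest.approx(1.5, abs=1e-4)
        assert result.params.rr_mort_mrs35 == pytest.approx(4.0, abs=1e-4)
        assert result.params.p_recover_monthly == pytest.approx(0.02, abs=1e-5)
        assert result.objective < 1e-12

    def test_null_targets_give_null_parameters(self):
        """Targets equal to general-population survival with a constant
        independence share calibrate to unit risk ratios and no recovery."""
        truth = sc.SyntheticTruth(
            rr_mort_mrs02=1.0, rr_mort_mrs35=1.0, p_recover_monthly=0.0
        )
        lt = truth.life_table()
        targets = sc.gen_calibration_targets(truth, CONTROL, life_table=lt)
        result = sc.calibrate(targets, lt, CONTROL)
        assert result.params.rr_mort_mrs02 == pytest.approx(1.0, abs=1e-3)
        assert result.params.rr_mort_mrs35 == pytest.approx(1.0, abs=1e-3)
        assert result.params.p_recover_monthly == pytest.approx(0.0, abs=1e-4)

    def test_duplicated_targets_leave_argmin_unchanged(self):
        """Duplicating every target row (equivalent to doubling least-squares
        weights) does not move the optimum."""
        truth = sc.SyntheticTruth()
        lt = truth.life_table()
        targets = sc.gen_calibration_targets(truth, CONTROL, life_table=lt)
        doubled = sc.CalibrationTargets(
            pd.concat([targets.table, targets.table], ignore_index=True)
        )
        a = sc.calibrate(targets, lt, CONTROL).params
        b = sc.calibrate(doubled, lt, CONTROL).params
        assert a.rr_mort_mrs02 == pytest.approx(b.rr_mort_mrs02, abs=1e-5)
        assert a.rr_mort_mrs35 == pytest.approx(b.rr_mort_mrs35, abs=1e-5)
        assert a.p_recover_monthly == pytest.approx(b.p_recover_monthly, abs=1e-6)

    def test_insufficient_targets_refused(self):
        lt = flat_life_table(0.02)
        empty = sc.CalibrationTargets(
            pd.DataFrame(columns=["month", "survival", "p02_among_alive"])
        )
        with pytest.raises(InvalidParameterError, match="insufficient"):
            sc.calibrate(empty, lt, CONTROL)

    def test_failure_carries_best_found_parameters(self):
        truth = sc.SyntheticTruth()
        lt = truth.life_table()
        targets = sc.gen_calibration_targets(truth, CONTROL, life_table=lt)
        with pytest.raises(CalibrationError) as exc:
            sc.calibrate(targets, lt, CONTROL, max_objective=1e-30)
        assert exc.value.result is not None
        assert exc.value.result.params.rr_mort_mrs35 > 0
        assert not exc.value.result.residuals.empty


class TestExtendSchedule:
    def test_extension_cycle_count_and_recovery(self):
        lt = flat_life_table(0.02)
        params = sc.CalibratedParams(1.5, 4.0, 0.02)
        base = sc.build_schedule(params, lt, horizon_months=60)
        ext = sc.extend_schedule(params, base, lt, to_month=120)
        assert ext.n_cycles == 117
        assert ext.months[-1] == 120
        # recovery stays off in every extended cycle
        assert np.all(ext.matrices[base.n_cycles:, 1, 0] == 0.0)

    def test_flat_life_table_extension_repeats_fifth_year(self):
        """With age-constant mortality the extended cycles equal the final
        base-case cycle exactly."""
        lt = flat_life_table(0.02)
        params = sc.CalibratedParams(1.5, 4.0, 0.02)
        base = sc.build_schedule(params, lt, horizon_months=60)
        ext = sc.extend_schedule(params, base, lt, to_month=72)
        assert np.allclose(ext.matrices[base.n_cycles:], base.matrices[-1])

    def test_life_table_too_short_raises_range_error(self):
        lt = flat_life_table(0.02, ages=range(75, 80))
        params = sc.CalibratedParams(1.0, 1.0, 0.0)
        base = sc.build_schedule(params, lt, horizon_months=48)
        with pytest.raises(InvalidParameterError, match="life table"):
            sc.extend_schedule(params, base, lt, to_month=120)

    def test_non_extension_rejected(self):
        lt = flat_life_table(0.02)
        params = sc.CalibratedParams(1.0, 1.0, 0.0)
        base = sc.build_schedule(params, lt, horizon_months=60)
        with pytest.raises(InvalidParameterError):
            sc.extend_schedule(params, base, lt, to_month=60)


class TestLifeTableIO:
    def test_csv_round_trip(self, tmp_path):
        lt = sc.gen_life_table(0.018, 0.115, range(75, 86))
        path = tmp_path / "lt.csv"
        lt.to_csv(path)
        back = sc.LifeTable.from_csv(path)
        assert np.array_equal(back.ages, lt.ages)
        assert np.allclose(back.qx, lt.qx)

    def test_gap_in_ages_rejected(self):
        with pytest.raises(InvalidParameterError):
            sc.LifeTable(ages=np.array([75, 77]), qx=np.array([0.01, 0.02]))

    def test_age_outside_range_rejected(self):
        lt = flat_life_table(0.02, ages=range(75, 80))
        with pytest.raises(InvalidParameterError):
            lt.q_annual(85)
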