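"""Markov engine: initial distributions, OR->RR conversion, traces, fine splits."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import strokecea as sc
from strokecea.errors import InvalidParameterError, ModelConstructionError

from conftest import random_distribution, random_schedule


class TestDeriveInitialDistribution:
    @pytest.mark.parametrize(
        "control_p02, rr, p_dead, expected",
        [
            (0.376, 1.31, 0.039, (0.49256, 0.46844, 0.039)),
            (0.376, 1.0, 0.039, (0.376, 0.585, 0.039)),
            (0.376, 1.43, 0.039, (0.53768, 0.42332, 0.039)),
        ],
    )
    def test_published_initial_distributions(self, control_p02, rr, p_dead, expected):
        """Intervention-arm month-3 distribution: control share times risk ratio,
        equal death share, remainder disabled."""
        d = sc.derive_initial_distribution(control_p02, rr, p_dead)
        assert d.p_mrs02 == pytest.approx(expected[0], abs=1e-12)
        assert d.p_mrs35 == pytest.approx(expected[1], abs=1e-12)
        assert d.p_dead == pytest.approx(expected[2], abs=1e-12)

    def test_impossible_distribution_is_rejected_not_clipped(self):
        with pytest.raises(InvalidParameterError):
            sc.derive_initial_distribution(0.8, 1.3, 0.1)

    @pytest.mark.parametrize("bad", [-0.1, 0.0])
    def test_nonpositive_risk_ratio_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            sc.derive_initial_distribution(0.376, bad, 0.039)


class TestOddsRatioToRiskRatio:
    def test_published_conversion(self):
        """OR 1.62 at 37.6% baseline reproduces the printed RR 1.31."""
        rr = sc.odds_ratio_to_risk_ratio(1.62, 0.376)
        assert rr == pytest.approx(1.313740755157649, abs=1e-12)
        assert round(rr, 2) == 1.31

    def test_null_and_ci_bound(self):
        assert sc.odds_ratio_to_risk_ratio(1.0, 0.376) == pytest.approx(1.0)
        # lower CI bound of the published odds ratio maps to the printed 1.20
        assert round(sc.odds_ratio_to_risk_ratio(1.36, 0.376), 2) == 1.20

    @pytest.mark.parametrize("p0", [0.0, 1.0, -0.2, 1.5])
    def test_degenerate_baseline_rejected(self, p0):
        with pytest.raises(InvalidParameterError):
            sc.odds_ratio_to_risk_ratio(1.62, p0)

    @given(
        odds_ratio=st.floats(0.05, 20.0),
        p0=st.floats(0.01, 0.99),
    )
    def test_exact_inverse_of_forward_odds(self, odds_ratio, p0):
        """Converting p0 and RR*p0 back to an odds ratio recovers the input."""
        rr = sc.odds_ratio_to_risk_ratio(odds_ratio, p0)
        p1 = rr * p0
        assert 0.0 < p1 < 1.0
        recovered = (p1 / (1.0 - p1)) / (p0 / (1.0 - p0))
        assert recovered == pytest.approx(odds_ratio, rel=1e-9)


class TestRunCohort:
    def test_identity_schedule_keeps_distribution(self):
        sched = sc.TransitionSchedule(
            matrices=np.broadcast_to(np.eye(3), (57, 3, 3)).copy(),
            months=np.arange(4, 61),
        )
        trace = sc.run_cohort(sc.MRSDistribution(0.5, 0.46, 0.04), sched)
        assert trace.coarse.shape == (58, 3)
        assert np.allclose(trace.coarse, [0.5, 0.46, 0.04])
        assert trace.months[0] == 3 and trace.months[-1] == 60

    def test_geometric_death_closed_form(self):
        """Constant 1%/cycle death from the independent state: survival after
        57 cycles is 0.99^57 (closed-form geometric)."""
        m = np.array([[0.99, 0.0, 0.01], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        sched = sc.TransitionSchedule(
            matrices=np.broadcast_to(m, (57, 3, 3)).copy(), months=np.arange(4, 61)
        )
        trace = sc.run_cohort(sc.MRSDistribution(1.0, 0.0, 0.0), sched)
        assert trace.p_dead[-1] == pytest.approx(1.0 - 0.99**57, abs=1e-12)

    @given(seed=st.integers(0, 2**31 - 1))
    def test_conservation_and_death_monotonicity(self, seed):
        """Occupancy rows stay on the simplex and death never decreases, for
        arbitrary valid schedules."""
        rng = np.random.default_rng(seed)
        sched = random_schedule(rng, n_cycles=20)
        trace = sc.run_cohort(random_distribution(rng), sched)
        assert np.allclose(trace.coarse.sum(axis=1), 1.0, atol=1e-9)
        assert (trace.coarse >= -1e-12).all()
        assert (np.diff(trace.p_dead) >= -1e-12).all()

    def test_non_stochastic_matrix_rejected_before_simulation(self):
        m = np.array([[0.9, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        with pytest.raises(ModelConstructionError):
            sc.TransitionSchedule(
                matrices=m[None, :, :], months=np.array([4])
            )

    def test_non_absorbing_death_rejected(self):
        m = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.1, 0.0, 0.9]])
        with pytest.raises(ModelConstructionError):
            sc.TransitionSchedule(matrices=m[None, :, :], months=np.array([4]))


class TestFineSplit:
    SPLIT = sc.FineSplit(split02=(0.305, 0.298, 0.396), split35=(0.375, 0.369, 0.256))

    def _trace(self, coarse_row):
        sched = sc.TransitionSchedule(
            matrices=np.broadcast_to(np.eye(3), (1, 3, 3)).copy(), months=np.array([4])
        )
        return sc.run_cohort(sc.MRSDistribution(*coarse_row), sched)

    def test_published_base_case_product(self):
        """mRS4 occupancy is the disabled share times its fixed split weight."""
        fine = sc.split_fine(self._trace((0.493, 0.468, 0.039)), self.SPLIT).fine
        assert fine[0, 4] == pytest.approx(0.468 * 0.369, abs=1e-12)

    def test_degenerate_split(self):
        split = sc.FineSplit(split02=(1.0, 0.0, 0.0), split35=(0.375, 0.369, 0.256))
        fine = sc.split_fine(self._trace((1.0, 0.0, 0.0)), split).fine
        assert np.allclose(fine[0], [1, 0, 0, 0, 0, 0, 0])

    @given(seed=st.integers(0, 2**31 - 1))
    def test_band_sums_recover_coarse_exactly(self, seed):
        """Splitting then summing fine grades returns the coarse occupancy."""
        rng = np.random.default_rng(seed)
        trace = sc.run_cohort(random_distribution(rng), random_schedule(rng, 10))
        out = sc.split_fine(trace, self.SPLIT)
        assert np.allclose(out.fine[:, :3].sum(axis=1), trace.coarse[:, 0], atol=1e-12)
        assert np.allclose(out.fine[:, 3:6].sum(axis=1), trace.coarse[:, 1], atol=1e-12)
        assert np.allclose(out.fine.sum(axis=1), 1.0, atol=1e-9)

    def test_renormalization_of_rounded_triples(self):
        # 30.5+29.8+39.6 = 99.9: shares must be renormalized, not used raw
        assert self.SPLIT.norm02.sum() == pytest.approx(1.0, abs=1e-15)
        assert self.SPLIT.norm02[0] == pytest.approx(0.305 / 0.999, abs=1e-12)

    def test_negative_share_rejected(self):
        with pytest.raises(InvalidParameterError):
            sc.FineSplit(split02=(-0.1, 0.6, 0.5), split35=(0.4, 0.3, 0.3))


def test_trace_export_columns():
    sched = sc.TransitionSchedule(
        matrices=np.broadcast_to(np.eye(3), (2, 3, 3)).copy(), months=np.array([4, 5])
    )
    trace = sc.split_fine(
        sc.run_cohort(sc.MRSDistribution(0.5, 0.4, 0.1), sched),
        sc.FineSplit((1, 0, 0), (1, 0, 0)),
    )
    df = trace.to_frame()
    assert list(df.columns) == [
        "month", "mRS0", "mRS1", "mRS2", "mRS3", "mRS4", "mRS5", "mRS6",
        "mRS02", "mRS35", "dead",
    ]
    assert list(df["month"]) == [3, 4, 5]
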