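"""ANOVA variance components, pooled CVs, decision limits, LOD/LOQ rules."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrlvalidate.errors import (
    InsufficientDataError,
    MissingLevelError,
    NotDetectableError,
)
from mrlvalidate.precision import (
    Fitness,
    LevelStats,
    anova_precision,
    assign_limits,
    cc_limits,
    detection_flags,
    detection_threshold,
    estimate_recovery,
    pool_cv,
)


def oracle_components(groups):
    """Brute-force one-way random-effects decomposition (balanced designs)."""
    a = len(groups)
    n = len(groups[0])
    grand = sum(sum(g) for g in groups) / (a * n)
    ss_w = sum(sum((x - sum(g) / n) ** 2 for x in g) for g in groups)
    ms_w = ss_w / (a * (n - 1))
    ss_b = n * sum((sum(g) / n - grand) ** 2 for g in groups)
    ms_b = ss_b / (a - 1)
    s2_r = ms_w
    s2_l = max(0.0, (ms_b - ms_w) / n)
    return (
        100 * math.sqrt(s2_r) / grand,
        100 * math.sqrt(s2_r + s2_l) / grand,
    )


class TestAnova:
    def test_hand_computed_two_day_example(self):
        res = anova_precision([[90.0, 110.0], [190.0, 210.0]])
        assert res.ms_within == pytest.approx(200.0)
        assert res.ms_between == pytest.approx(10000.0)
        assert res.cv_r == pytest.approx(9.43, abs=0.01)
        assert res.cv_wr == pytest.approx(47.6, abs=0.05)

    def test_tuple_unpacking_interface(self):
        cv_r, cv_wr = anova_precision([[90.0, 110.0], [190.0, 210.0]])
        assert cv_r < cv_wr

    @pytest.mark.parametrize(
        "a,n", list(itertools.product([2, 3, 4, 5], [2, 3, 4, 5]))
    )
    def test_matches_brute_force_oracle_on_balanced_designs(self, a, n):
        rng = np.random.default_rng(100 * a + n)
        groups = [list(100 + 10 * rng.standard_normal(n)) for _ in range(a)]
        res = anova_precision(groups)
        cv_r, cv_wr = oracle_components(groups)
        assert res.cv_r == pytest.approx(cv_r, rel=1e-9)
        assert res.cv_wr == pytest.approx(cv_wr, rel=1e-9)

    def test_mean_squares_match_statsmodels(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(9)
        df = pd.DataFrame(
            {
                "day": np.repeat(["d1", "d2", "d3"], 4),
                "conc": 100 + 10 * rng.standard_normal(12),
            }
        )
        res = anova_precision(
            df.assign(day=df["day"]).rename(columns={"conc": "conc"})
        )
        table = sm.stats.anova_lm(ols("conc ~ C(day)", data=df).fit())
        assert res.ms_between == pytest.approx(
            table.loc["C(day)", "mean_sq"], rel=1e-9
        )
        assert res.ms_within == pytest.approx(
            table.loc["Residual", "mean_sq"], rel=1e-9
        )

    def test_no_between_day_effect_collapses_to_repeatability(self):
        rng = np.random.default_rng(2)
        groups = [list(100 + 5 * rng.standard_normal(200)) for _ in range(30)]
        res = anova_precision(groups)
        assert res.cv_wr == pytest.approx(res.cv_r, rel=0.05)

    def test_negative_between_day_component_truncated(self):
        # between-day MS below within-day MS -> component clamped at zero
        groups = [[90.0, 110.0], [91.0, 109.0]]
        res = anova_precision(groups)
        assert res.s2_between == 0.0
        assert res.cv_wr == res.cv_r

    def test_requires_two_days_and_two_replicates(self):
        with pytest.raises(InsufficientDataError):
            anova_precision([[1.0, 2.0]])
        with pytest.raises(InsufficientDataError):
            anova_precision([[1.0, 2.0], [3.0]])

    def test_zero_mean_is_undefined(self):
        with pytest.raises(NotDetectableError):
            anova_precision([[-1.0, 1.0], [-2.0, 2.0]])


class TestPooledCV:
    def test_constant_cvs_pool_to_themselves(self):
        assert pool_cv([(10.0, 4), (10.0, 12), (10.0, 7)]) == pytest.approx(10.0)

    def test_dof_weighted_rms(self):
        assert pool_cv([(10.0, 4), (20.0, 4)]) == pytest.approx(15.81, abs=0.01)

    def test_single_level_is_identity(self):
        assert pool_cv([(13.7, 12)]) == pytest.approx(13.7)

    @given(
        st.lists(
            st.tuples(
                st.floats(0.1, 50.0, allow_nan=False),
                st.integers(2, 20),
            ),
            min_size=1,
            max_size=8,
        )
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_permutation_invariant_and_bracketed(self, items):
        pooled = pool_cv(items)
        assert pooled == pytest.approx(pool_cv(list(reversed(items))), rel=1e-12)
        cvs = [cv for cv, _ in items]
        assert min(cvs) - 1e-9 <= pooled <= max(cvs) + 1e-9

    def test_empty_input_rejected(self):
        with pytest.raises(InsufficientDataError):
            pool_cv([])


class TestDecisionLimits:
    def test_zero_cv_collapses_to_mrl(self):
        assert cc_limits(100.0, 0.0) == (100.0, 100.0)

    def test_worked_example(self):
        cc_a, cc_b = cc_limits(100.0, 10.0)
        assert cc_a == pytest.approx(116.4)
        assert cc_b == pytest.approx(100.0 * 1.164**2)
        assert cc_b == pytest.approx(135.49, abs=0.01)

    @given(
        st.floats(0.1, 2000.0, allow_nan=False),
        st.floats(0.0, 60.0, allow_nan=False),
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_geometric_identity(self, mrl, cv):
        cc_a, cc_b = cc_limits(mrl, cv)
        assert cc_b * mrl == pytest.approx(cc_a**2, rel=1e-12)
        assert cc_b >= cc_a >= mrl

    def test_monotone_in_both_arguments(self):
        assert cc_limits(100.0, 10.0)[0] < cc_limits(120.0, 10.0)[0]
        assert cc_limits(100.0, 10.0)[1] < cc_limits(100.0, 12.0)[1]

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            cc_limits(-5.0, 10.0)
        with pytest.raises(ValueError):
            cc_limits(100.0, -1.0)


def frame(level_areas):
    return pd.DataFrame(
        [
            {"level": lv, "area": a}
            for lv, areas in level_areas.items()
            for a in areas
        ]
    )


class TestRecovery:
    def test_identical_areas_give_100_percent(self):
        spiked = frame({10: [100.0, 100.0], 100: [1000.0]})
        res = estimate_recovery(spiked, spiked)
        assert res.overall_recovery == pytest.approx(100.0)
        assert all(r == pytest.approx(100.0) for _, r in res.per_level_recovery)

    def test_half_signal_gives_50_percent(self):
        std = frame({10: [100.0], 100: [1000.0], 150: [1500.0]})
        spiked = frame({10: [50.0], 100: [500.0], 150: [750.0]})
        res = estimate_recovery(spiked, std)
        assert res.overall_recovery == pytest.approx(50.0)

    def test_only_shared_levels_used_by_default(self):
        std = frame({10: [100.0], 100: [1000.0]})
        spiked = frame({10: [80.0], 100: [800.0], 1500: [120000.0]})
        res = estimate_recovery(spiked, std)
        assert [lv for lv, _ in res.per_level_recovery] == [10, 100]

    def test_requested_level_missing_from_standards_is_named(self):
        std = frame({10: [100.0]})
        spiked = frame({10: [80.0], 33: [264.0]})
        with pytest.raises(MissingLevelError, match="33"):
            estimate_recovery(spiked, std, levels=[10, 33])


class TestOperativeLimits:
    def penicillin_levels(self):
        return [
            LevelStats(level=2.0, cv_r=23.0, cv_wr=26.0, detectable=True, n=12),
            LevelStats(level=10.0, cv_r=7.5, cv_wr=11.0, detectable=True, n=12),
        ]

    def test_imprecise_first_level_pushes_loq_up(self):
        res = assign_limits(self.penicillin_levels(), cv_wr_pooled=15.0)
        assert res.lod == 2.0
        assert res.loq == 10.0
        assert res.fitness is Fitness.confirmation

    def test_all_levels_passing_gives_lowest_loq(self):
        stats = [
            LevelStats(level=lv, cv_r=5.0, cv_wr=8.0, detectable=True, n=12)
            for lv in (10.0, 33.0, 100.0)
        ]
        res = assign_limits(stats, cv_wr_pooled=8.0)
        assert res.loq == 10.0

    def test_scarcely_ionizable_analyte_quantifiable_from_33(self):
        stats = [
            LevelStats(level=10.0, cv_r=30.0, cv_wr=35.0, detectable=False, n=12),
            LevelStats(level=33.0, cv_r=13.0, cv_wr=14.0, detectable=True, n=12),
            LevelStats(level=100.0, cv_r=12.0, cv_wr=13.0, detectable=True, n=12),
        ]
        res = assign_limits(stats, cv_wr_pooled=13.0)
        assert res.lod == 33.0
        assert res.loq == 33.0

    def test_high_pooled_cv_forces_screening_only(self):
        stats = [
            LevelStats(level=10.0, cv_r=19.0, cv_wr=31.0, detectable=True, n=12)
        ]
        res = assign_limits(stats, cv_wr_pooled=31.0)
        assert res.fitness is Fitness.screening_only

    def test_undetectable_everywhere_means_no_lod(self):
        stats = [
            LevelStats(level=10.0, cv_r=5.0, cv_wr=8.0, detectable=False, n=12)
        ]
        res = assign_limits(stats, cv_wr_pooled=8.0)
        assert res.lod is None
        assert res.fitness is Fitness.screening_only

    def test_mrl_attaches_decision_limits(self):
        res = assign_limits(
            self.penicillin_levels(), cv_wr_pooled=10.0, mrl=100.0
        )
        assert res.cc_alpha == pytest.approx(116.4)
        assert res.cc_beta == pytest.approx(135.49, abs=0.01)


class TestDetection:
    def test_blank_threshold_is_mean_plus_three_sd(self):
        blanks = [0.0, 10.0, 20.0]
        expected = np.mean(blanks) + 3 * np.std(blanks, ddof=1)
        assert detection_threshold(blanks) == pytest.approx(expected)

    def test_flags_require_all_replicates_of_both_transitions(self):
        rows = []
        for rank in ("quantifier", "qualifier"):
            for rep, area in enumerate([500.0, 600.0], start=1):
                rows.append(
                    {
                        "sample_kind": "spiked",
                        "level": 10.0,
                        "transition_rank": rank,
                        "area": area,
                    }
                )
        rows.append(
            {
                "sample_kind": "spiked",
                "level": 2.0,
                "transition_rank": "qualifier",
                "area": 1.0,  # below threshold -> level 2 not detectable
            }
        )
        flags = detection_flags(pd.DataFrame(rows), threshold=100.0)
        assert flags[10.0] is True
        assert flags[2.0] is False
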