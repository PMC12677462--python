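import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats as sps

from ruralscale.stats import (
    StatsError,
    compare_outcome_groups,
    ecdf,
    ks_two_sample,
    percent,
    round_half_up,
    stratum_table,
)

samples = st.lists(
    st.integers(min_value=0, max_value=10).map(float), min_size=1, max_size=50
)


def brute_force_d(a, b):
    """Oracle: double loop over all pooled points."""
    a, b = sorted(a), sorted(b)
    best = 0.0
    for x in a + b:
        f1 = sum(1 for v in a if v <= x) / len(a)
        f2 = sum(1 for v in b if v <= x) / len(b)
        best = max(best, abs(f1 - f2))
    return best


class TestEcdf:
    def test_heights_and_tie_merging(self):
        curve = ecdf([1, 2, 2, 3])
        assert curve.support.tolist() == [1, 2, 3]
        assert curve(2) == pytest.approx(0.75)
        assert curve(0.5) == 0.0
        assert curve(3) == 1.0

    def test_single_point(self):
        curve = ecdf([5])
        assert curve.support.tolist() == [5.0]
        assert curve.cum_prob.tolist() == [1.0]

    def test_empty_rejected(self):
        with pytest.raises(StatsError, match="empty_sample"):
            ecdf([])
        with pytest.raises(StatsError, match="empty_sample"):
            ecdf([float("nan")])

    @given(samples)
    @settings(max_examples=150, deadline=None)
    def test_step_function_invariants(self, values):
        curve = ecdf(values)
        assert np.all(np.diff(curve.support) > 0)
        assert np.all(np.diff(curve.cum_prob) > 0)
        assert curve.cum_prob[-1] == 1.0
        # height at x equals the definition (# obs <= x) / n
        for x in {min(values), max(values), values[0]}:
            assert curve(x) == pytest.approx(
                sum(1 for v in values if v <= x) / len(values)
            )


class TestKsTwoSample:
    def test_identical_samples_null(self):
        r = ks_two_sample([1, 2, 2, 5], [2, 1, 5, 2])
        assert r.d_statistic == 0.0
        assert r.p_value == 1.0

    def test_fully_separated_supports(self):
        r = ks_two_sample([1, 2, 3], [4, 5, 6])
        assert r.d_statistic == 1.0
        assert r.location_of_max == 3.0

    def test_interleaved_hand_case(self):
        r = ks_two_sample([1, 3], [2, 4])
        assert r.d_statistic == 0.5

    def test_empty_sample_rejected(self):
        with pytest.raises(StatsError, match="empty_sample"):
            ks_two_sample([], [1.0])

    @given(samples, samples)
    @settings(max_examples=200, deadline=None)
    def test_d_matches_brute_force_exactly(self, a, b):
        r = ks_two_sample(a, b)
        assert r.d_statistic == brute_force_d(a, b)
        assert r.n1 == len(a) and r.n2 == len(b)

    @given(samples, samples)
    @settings(max_examples=100, deadline=None)
    def test_p_matches_reference_series(self, a, b):
        """Independent reference for the asymptotic tail: scipy.special.kolmogorov."""
        r = ks_two_sample(a, b)
        ne = len(a) * len(b) / (len(a) + len(b))
        lam = (math.sqrt(ne) + 0.12 + 0.11 / math.sqrt(ne)) * r.d_statistic
        expected = min(max(float(special.kolmogorov(lam)), 1e-12), 1.0)
        assert r.p_value == pytest.approx(expected, abs=1e-9)

    def test_d_matches_scipy_on_continuous_data(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=200)
        b = rng.normal(0.4, size=150)
        ours = ks_two_sample(a, b)
        ref = sps.ks_2samp(a, b, method="asymp")
        assert ours.d_statistic == pytest.approx(ref.statistic, abs=1e-15)

    def test_p_decreases_as_d_increases(self):
        # same n1, n2; growing separation
        base = list(np.linspace(0, 1, 100))
        ps = []
        for shift in (0.05, 0.2, 0.5, 1.2):
            r = ks_two_sample(base, [x + shift for x in base])
            ps.append((r.d_statistic, r.p_value))
        ds = [d for d, _ in ps]
        pvals = [p for _, p in ps]
        assert ds == sorted(ds)
        assert pvals == sorted(pvals, reverse=True)
        assert all(p > 0 for p in pvals)


class TestCompareOutcomeGroups:
    @staticmethod
    def _frames(scores_by_pid, outcomes_by_pid):
        scores = pd.DataFrame(
            {
                "participant_id": list(scores_by_pid),
                "percent_rural": list(scores_by_pid.values()),
            }
        )
        outcomes = pd.DataFrame(
            {
                "participant_id": list(outcomes_by_pid),
                "delayed_care": pd.array(
                    list(outcomes_by_pid.values()), dtype="Int64"
                ),
            }
        )
        return scores, outcomes

    def test_identical_groups_null(self):
        scores, outcomes = self._frames(
            {f"p{i}": float(v) for i, v in enumerate([10, 20, 30, 10, 20, 30])},
            {f"p{i}": g for i, g in enumerate([0, 0, 0, 1, 1, 1])},
        )
        _, _, ks, _ = compare_outcome_groups(scores, outcomes, "delayed_care")
        assert ks.d_statistic == 0.0 and ks.p_value == 1.0

    def test_full_separation(self):
        scores, outcomes = self._frames(
            {f"p{i}": float(i) for i in range(6)},
            {f"p{i}": int(i >= 3) for i in range(6)},
        )
        _, _, ks, _ = compare_outcome_groups(scores, outcomes, "delayed_care")
        assert ks.d_statistic == 1.0

    def test_exclusions_counted(self):
        scores, outcomes = self._frames(
            {"a": 1.0, "b": 2.0, "c": float("nan"), "d": 3.0},
            {"a": 0, "b": 1, "c": 1, "d": None},
        )
        _, _, _, excl = compare_outcome_groups(scores, outcomes, "delayed_care")
        assert excl == {"no_score": 1, "not_assessed": 1, "n_group0": 1, "n_group1": 1}

    def test_empty_group_rejected(self):
        scores, outcomes = self._frames(
            {"a": 1.0, "b": 2.0}, {"a": 0, "b": 0}
        )
        with pytest.raises(StatsError, match="degenerate_grouping"):
            compare_outcome_groups(scores, outcomes, "delayed_care")


class TestRounding:
    @pytest.mark.parametrize(
        "x, decimals, expected",
        [
            (86.45, 1, 86.5),  # banker's rounding would give 86.4
            (0.05, 1, 0.1),
            (1.25, 1, 1.3),
            (56.62, 0, 57.0),
            (2.5, 0, 3.0),
        ],
    )
    def test_half_up(self, x, decimals, expected):
        assert round_half_up(x, decimals) == expected

    def test_percent_denominator_guard(self):
        with pytest.raises(StatsError):
            percent(1, 0)


class TestStratumTable:
    @pytest.fixture
    def cohort(self):
        # 6 fully-urban (one with no demographics), 3 fully-rural, 2 mid
        return pd.DataFrame(
            {
                "participant_id": [f"p{i}" for i in range(11)],
                "percent_rural": [0.0] * 6 + [100.0] * 3 + [33.3, 50.0],
                "race": ["W", "W", "B", "W", "B", None, "W", "W", "W", "W", "B"],
                "ethnicity": ["N"] * 5 + [None] + ["N"] * 5,
                "sex_at_birth": ["F", "M", "F", "F", "M", None, "F", "F", "M", "F", "M"],
                "education": ["C", "C", "H", "C", "H", None, "C", "H", "C", "C", "H"],
                "age": [40, 50, 60, 55, 45, 70, 54, 54, 54, 30, 80],
            }
        )

    def test_counts_percents_and_denominator(self, cohort):
        t = stratum_table(cohort, "FULLY_URBAN", total_enrolled=11)
        assert t.n_total == 6
        assert t.n_with_demographics == 5  # the all-missing row drops out
        count, pct = t.rows["race"]["W"]
        assert count == 3 and pct == 60.0
        count, pct = t.rows["race"]["B"]
        assert count == 2 and pct == 40.0
        # counts per category sum to the denominator
        for cat in ("race", "ethnicity", "sex_at_birth", "education"):
            assert sum(c for c, _ in t.rows[cat].values()) == 5
        _, share = t.rows["_share"]["share_of_enrollment"]
        assert share == 55.0  # 6/11 = 54.5% -> 55 whole-percent half-up

    def test_degenerate_single_level(self, cohort):
        t = stratum_table(cohort, "FULLY_RURAL")
        count, pct = t.rows["race"]["W"]
        assert count == 3 and pct == 100.0
        assert t.age_mean_sd[0] == pytest.approx(54.0)

    def test_unknown_and_empty_strata(self, cohort):
        with pytest.raises(StatsError, match="unknown_stratum"):
            stratum_table(cohort, "SUBURBAN")
        with pytest.raises(StatsError, match="empty_stratum"):
            stratum_table(cohort.loc[cohort["percent_rural"] > 0], "FULLY_URBAN")
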