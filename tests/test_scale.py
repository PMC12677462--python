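import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ruralscale.scale import (
    RuralityScale,
    ScaleError,
    Stratum,
    build_scale,
    classify_stratum,
    map_participants,
)
from helpers import make_universe

# strategy: small universes of (zip5, population, is_rural)
zip_records = st.lists(
    st.tuples(
        st.integers(min_value=0, max_value=99999),
        st.integers(min_value=0, max_value=100000),
        st.booleans(),
    ),
    min_size=1,
    max_size=20,
    unique_by=lambda t: t[0],
).map(lambda rows: [(f"{z:05d}", p, r) for z, p, r in rows])


def brute_force_scale(rows):
    """Independent oracle: dict-based grouping and summation."""
    groups = {}
    for zip5, pop, rural in rows:
        prefix = zip5[:3]
        total, rur = groups.get(prefix, (0, 0))
        groups[prefix] = (total + pop, rur + (pop if rural else 0))
    return {
        prefix: (total, rur, 100.0 * rur / total if total > 0 else None)
        for prefix, (total, rur) in groups.items()
    }


class TestBuildScale:
    def test_population_weighted_ratio(self, toy_universe):
        scale = build_scale(toy_universe)
        assert len(scale.groups) == 1
        group = scale.groups.iloc[0]
        assert group["prefix"] == "850"
        assert group["total_population"] == 15000
        assert group["rural_population"] == 5000
        assert group["percent_rural"] == pytest.approx(100 * 5000 / 15000)

    def test_all_rural_gives_100_everywhere(self):
        uni = make_universe(
            [("10001", 5, True), ("10002", 7, True), ("20001", 3, True)]
        )
        scale = build_scale(uni)
        assert (scale.groups["percent_rural"] == 100.0).all()

    def test_zero_population_group_undefined(self):
        uni = make_universe([("10001", 0, True), ("10002", 0, False)])
        scale = build_scale(uni)
        assert math.isnan(scale.groups["percent_rural"].iloc[0])
        assert scale.build_meta["n_undefined_groups"] == 1

    def test_empty_universe_rejected(self):
        uni = make_universe([("10001", 1, False)])
        uni.records = uni.records.iloc[:0]
        with pytest.raises(ScaleError, match="empty_universe"):
            build_scale(uni)

    @given(zip_records)
    @settings(max_examples=150, deadline=None)
    def test_agrees_with_brute_force_oracle(self, rows):
        scale = build_scale(make_universe(rows))
        expected = brute_force_scale(rows)
        assert set(scale.groups["prefix"]) == set(expected)
        for _, g in scale.groups.iterrows():
            total, rural, pct = expected[g["prefix"]]
            assert g["total_population"] == total
            assert g["rural_population"] == rural
            if pct is None:
                assert math.isnan(g["percent_rural"])
            else:
                assert g["percent_rural"] == pytest.approx(pct, rel=1e-12)

    @given(zip_records)
    @settings(max_examples=150, deadline=None)
    def test_conservation_and_bounds(self, rows):
        uni = make_universe(rows)
        scale = build_scale(uni)
        assert scale.total_population == uni.total_population
        assert scale.rural_population == uni.rural_population
        defined = scale.groups["percent_rural"].dropna()
        assert ((defined >= 0) & (defined <= 100)).all()
        # inverse view: 100 - percent_rural is the percent-urban score
        urban = 100.0 - defined
        np.testing.assert_allclose(
            urban,
            100.0
            * (
                scale.groups.loc[defined.index, "total_population"]
                - scale.groups.loc[defined.index, "rural_population"]
            )
            / scale.groups.loc[defined.index, "total_population"],
            rtol=1e-12,
        )

    @given(zip_records, st.data())
    @settings(max_examples=100, deadline=None)
    def test_flipping_zip_rural_monotone(self, rows, data):
        idx = data.draw(st.integers(min_value=0, max_value=len(rows) - 1))
        zip5, pop, _ = rows[idx]
        before_rows = rows[:idx] + [(zip5, pop, False)] + rows[idx + 1 :]
        after_rows = rows[:idx] + [(zip5, pop, True)] + rows[idx + 1 :]
        prefix = zip5[:3]
        before = brute_force_scale(before_rows)[prefix][2]
        g = build_scale(make_universe(after_rows)).groups
        after = g.loc[g["prefix"] == prefix, "percent_rural"].iloc[0]
        if before is None:
            assert math.isnan(after)
        else:
            assert after >= before
            if pop > 0 and before < 100:
                assert after > before


class TestMapParticipants:
    def test_lookup_and_missing_reasons(self, toy_universe):
        scale = build_scale(toy_universe)
        cohort = pd.DataFrame(
            {
                "participant_id": ["a", "b", "c", "d"],
                "zip3": ["850", "000", "999", None],
            }
        )
        scored, counts = map_participants(cohort, scale)
        by_id = scored.set_index("participant_id")
        assert by_id.loc["a", "percent_rural"] == pytest.approx(100 * 5000 / 15000)
        assert by_id.loc["b", "missing_reason"] == "suppressed_prefix"
        assert by_id.loc["c", "missing_reason"] == "unknown_prefix"
        assert by_id.loc["d", "missing_reason"] == "missing_zip3"
        assert counts == {
            "scored": 1,
            "suppressed_prefix": 1,
            "unknown_prefix": 1,
            "missing_zip3": 1,
        }

    def test_undefined_group_excluded(self):
        uni = make_universe([("11100", 0, True)])
        scale = build_scale(uni)
        cohort = pd.DataFrame({"participant_id": ["a"], "zip3": ["111"]})
        scored, counts = map_participants(cohort, scale)
        assert counts == {"scored": 0, "undefined_score": 1}
        assert math.isnan(scored["percent_rural"].iloc[0])

    def test_empty_cohort_rejected(self, toy_universe):
        scale = build_scale(toy_universe)
        with pytest.raises(ScaleError, match="empty_cohort"):
            map_participants(pd.DataFrame(columns=["participant_id", "zip3"]), scale)

    def test_exclusion_accounting_sums_to_input(self, small_world):
        _, scale, participants, _ = small_world
        scored, counts = map_participants(participants, scale)
        assert len(scored) == len(participants)
        assert sum(counts.values()) == len(participants)


class TestStratum:
    @pytest.mark.parametrize(
        "score, expected",
        [
            (0.0, Stratum.FULLY_URBAN),
            (100.0, Stratum.FULLY_RURAL),
            (100 * 5000 / 15000, Stratum.INTERMEDIATE),
            (99.99999, Stratum.INTERMEDIATE),
        ],
    )
    def test_classify(self, score, expected):
        assert classify_stratum(score) == expected

    def test_classify_undefined_rejected(self):
        with pytest.raises(ScaleError):
            classify_stratum(float("nan"))

    def test_stratum_from_integer_counts(self):
        uni = make_universe(
            [("11101", 5, False), ("22201", 5, True), ("33301", 2, True), ("33302", 1, False)]
        )
        scale = build_scale(uni)
        assert scale.stratum("111") == Stratum.FULLY_URBAN
        assert scale.stratum("222") == Stratum.FULLY_RURAL
        assert scale.stratum("333") == Stratum.INTERMEDIATE
        assert scale.stratum("999") is None
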