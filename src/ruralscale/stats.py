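"""Distributional comparison of rurality scores between outcome groups.

The question is whether participants coded 1 on a composite outcome
(delayed care, affordability) come from more rural areas than those coded
0. With scores that are heavily tied (everyone in one 3-digit prefix
shares a score) and wildly non-normal (a large spike at 0), the natural
tools are non-parametric: empirical cumulative distribution functions for
the two groups, and the two-sample Kolmogorov-Smirnov statistic

    D = sup_x |F1(x) - F2(x)|

evaluated exactly at every pooled observation (correct under ties).
Significance uses the asymptotic Kolmogorov tail

    Q(lambda) = 2 * sum_{k>=1} (-1)^(k-1) exp(-2 k^2 lambda^2),
    lambda = (sqrt(ne) + 0.12 + 0.11/sqrt(ne)) * D,  ne = n1*n2/(n1+n2),

with the series truncated when terms fall below 1e-12 and the result
clipped to (0, 1].

Also here: the stratified descriptive table for the scale's endpoints
(participants in exactly-0% and exactly-100%-rural prefixes), with
half-up rounding of percentages — the convention that reproduces standard
printed tables, where banker's rounding would not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "StatsError",
    "EcdfCurve",
    "KsResult",
    "StratumTable",
    "ecdf",
    "ks_two_sample",
    "compare_outcome_groups",
    "stratum_table",
    "round_half_up",
    "percent",
]


class StatsError(ValueError):
    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


@dataclass(frozen=True)
class EcdfCurve:
    """A right-continuous empirical CDF step function.

    ``support`` holds the sorted distinct observed values and ``cum_prob``
    the curve height at each (fraction of observations <= that value);
    the final height is exactly 1.
    """

    support: np.ndarray
    cum_prob: np.ndarray
    n: int

    def __call__(self, x) -> np.ndarray | float:
        """Curve height at x: (# observations <= x) / n."""
        idx = np.searchsorted(self.support, x, side="right")
        heights = np.concatenate([[0.0], self.cum_prob])
        return heights[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"value": self.support, "cum_prob": self.cum_prob})


@dataclass(frozen=True)
class KsResult:
    d_statistic: float
    p_value: float
    n1: int
    n2: int
    location_of_max: float

    def to_dict(self) -> dict:
        return {
            "d_statistic": self.d_statistic,
            "p_value": self.p_value,
            "n1": self.n1,
            "n2": self.n2,
            "location_of_max": self.location_of_max,
        }


def ecdf(values) -> EcdfCurve:
    """Build the ECDF of a sample; duplicates merge into one support point."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise StatsError("empty_sample")
    support, counts = np.unique(arr, return_counts=True)
    cum = np.cumsum(counts) / arr.size
    cum[-1] = 1.0  # exact despite float accumulation
    return EcdfCurve(support=support, cum_prob=cum, n=int(arr.size))


def _kolmogorov_sf(lam: float, tol: float = 1e-12) -> float:
    """Asymptotic Kolmogorov tail Q(lambda), series truncated below tol."""
    if lam < 0.2:
        # Q(0.2) = 1 - 4e-14: below this the alternating series converges
        # slowly while the answer is 1 to well within tol
        return 1.0
    total = 0.0
    sign = 1.0
    for k in range(1, 101):
        term = math.exp(-2.0 * k * k * lam * lam)
        total += sign * term
        if term < tol:
            break
        sign = -sign
    return min(max(2.0 * total, tol), 1.0)


def ks_two_sample(sample1, sample2) -> KsResult:
    """Two-sample two-sided KS test with exact pooled-point supremum.

    D is evaluated at every pooled observed value, which handles ties
    correctly; the p-value uses the asymptotic Kolmogorov distribution
    with the standard small-sample effective-size correction.
    """
    a = np.asarray(sample1, dtype=float)
    b = np.asarray(sample2, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise StatsError("empty_sample")

    a_sorted = np.sort(a)
    b_sorted = np.sort(b)
    pooled = np.unique(np.concatenate([a_sorted, b_sorted]))
    f1 = np.searchsorted(a_sorted, pooled, side="right") / a.size
    f2 = np.searchsorted(b_sorted, pooled, side="right") / b.size
    gaps = np.abs(f1 - f2)
    i_max = int(np.argmax(gaps))
    d = float(gaps[i_max])

    ne = a.size * b.size / (a.size + b.size)
    lam = (math.sqrt(ne) + 0.12 + 0.11 / math.sqrt(ne)) * d
    p = _kolmogorov_sf(lam) if d > 0 else 1.0
    return KsResult(
        d_statistic=d,
        p_value=p,
        n1=int(a.size),
        n2=int(b.size),
        location_of_max=float(pooled[i_max]),
    )


def compare_outcome_groups(
    scores: pd.DataFrame,
    outcomes: pd.DataFrame,
    domain: str,
) -> tuple[EcdfCurve, EcdfCurve, KsResult, dict[str, int]]:
    """ECDFs and KS comparison of rurality scores by coded outcome group.

    ``scores``: participant_id, percent_rural (NaN = unscored).
    ``outcomes``: participant_id plus a 0/1 column named ``domain``
    (``pd.NA`` = not assessed). Participants lacking either a defined
    score or an assessed outcome are excluded, with per-reason counts
    returned. Raises ``degenerate_grouping`` if either group is empty.

    Returns (curve for group 0, curve for group 1, KS result, exclusions).
    """
    merged = scores.merge(
        outcomes[["participant_id", domain]], on="participant_id", how="outer"
    )
    has_score = merged["percent_rural"].notna()
    has_outcome = merged[domain].notna()
    exclusions = {
        "no_score": int((~has_score).sum()),
        "not_assessed": int((has_score & ~has_outcome).sum()),
    }
    use = merged.loc[has_score & has_outcome]
    g0 = use.loc[use[domain] == 0, "percent_rural"].to_numpy(dtype=float)
    g1 = use.loc[use[domain] == 1, "percent_rural"].to_numpy(dtype=float)
    if g0.size == 0 or g1.size == 0:
        raise StatsError("degenerate_grouping", f"domain {domain}")
    exclusions["n_group0"] = int(g0.size)
    exclusions["n_group1"] = int(g1.size)
    return ecdf(g0), ecdf(g1), ks_two_sample(g0, g1), exclusions


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero at the given decimal place.

    ``round_half_up(86.45, 1) == 86.5`` whereas Python's builtin banker's
    rounding gives 86.4. Routed through Decimal(str(x)) so the decimal
    literal, not its binary float neighbour, is what gets rounded.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Printed-style percentage: 100*num/den, half-up at ``decimals``."""
    if denominator <= 0:
        raise StatsError("zero_denominator")
    return round_half_up(100.0 * numerator / denominator, decimals)


@dataclass
class StratumTable:
    """Descriptive table for one endpoint stratum (0% or 100% rural).

    ``rows`` maps category -> level -> (count, percent); percents use
    ``n_with_demographics`` as denominator, half-up to one decimal.
    """

    stratum: str
    n_total: int
    n_with_demographics: int
    rows: dict = field(default_factory=dict)
    age_mean_sd: tuple[float, float] | None = None

    def to_frame(self) -> pd.DataFrame:
        records = [
            {
                "category": category,
                "level": level,
                "count": count,
                "percent": pct,
            }
            for category, levels in self.rows.items()
            for level, (count, pct) in levels.items()
        ]
        return pd.DataFrame(records)


def stratum_table(
    cohort: pd.DataFrame,
    stratum: str,
    categories: tuple[str, ...] = ("race", "ethnicity", "sex_at_birth", "education"),
    total_enrolled: int | None = None,
) -> StratumTable:
    """Sociodemographic summary of one endpoint stratum.

    ``cohort`` must carry ``percent_rural`` plus the demographic columns;
    the stratum is selected by exact score equality (0 for FULLY_URBAN,
    100 for FULLY_RURAL). Participants with every demographic column
    missing are counted in ``n_total`` but excluded from the percentage
    denominator ``n_with_demographics``, mirroring how enrollment tables
    separate "provided sociodemographic information". Missing values
    within a category form a "Missing" level so counts sum to the
    denominator. If ``total_enrolled`` is given, a whole-percent share of
    enrollment is stored in ``rows['_share']``.
    """
    target = {"FULLY_URBAN": 0.0, "FULLY_RURAL": 100.0}.get(stratum)
    if target is None:
        raise StatsError("unknown_stratum", stratum)
    sub = cohort.loc[cohort["percent_rural"] == target]
    if sub.empty:
        raise StatsError("empty_stratum", stratum)

    present = [c for c in categories if c in sub.columns]
    has_demo = sub[present].notna().any(axis=1) if present else pd.Series(False, index=sub.index)
    demo = sub.loc[has_demo]
    n_demo = int(len(demo))

    table = StratumTable(
        stratum=stratum, n_total=int(len(sub)), n_with_demographics=n_demo
    )
    for category in present:
        col = demo[category]
        counts = col.fillna("Missing").value_counts()
        table.rows[category] = {
            str(level): (int(cnt), percent(int(cnt), n_demo))
            for level, cnt in counts.items()
        }
    if "age" in demo.columns and n_demo > 0:
        ages = pd.to_numeric(demo["age"], errors="coerce").dropna()
        if len(ages):
            table.age_mean_sd = (float(ages.mean()), float(ages.std(ddof=1)))
    if total_enrolled:
        share = percent(table.n_total, total_enrolled, decimals=0)
        table.rows["_share"] = {
            "share_of_enrollment": (table.n_total, share)
        }
    return table
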