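"""The continuous 3-digit-ZIP rurality scale.

De-identified health datasets release geography only at the 3-digit ZIP
level (HIPAA safe harbor). The scale defined here makes that coarse unit
usable for rural-health research: group every 5-digit ZIP by its first
three digits and score each prefix with the population-weighted share of
its rural-designated ZIPs,

    percent_rural(prefix) = 100 * rural_population / total_population,

a continuous 0-100 score. 100 - percent_rural is, by construction, a
percent-urban score. Prefixes whose ZIPs all have zero population get an
UNDEFINED (NaN) score rather than an arbitrary endpoint.

Participants carry a 3-digit prefix and are mapped onto the scale by
lookup; prefix "000" is the safe-harbor suppression code for
low-population areas and always maps to missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .geodata import ZipUniverse

__all__ = [
    "ScaleError",
    "Stratum",
    "SUPPRESSED_PREFIX",
    "RuralityScale",
    "build_scale",
    "map_participants",
    "classify_stratum",
]

SUPPRESSED_PREFIX = "000"


class ScaleError(ValueError):
    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


class Stratum(str, Enum):
    """Endpoint strata of the scale, defined by exact set membership."""

    FULLY_URBAN = "FULLY_URBAN"  # percent_rural == 0
    FULLY_RURAL = "FULLY_RURAL"  # percent_rural == 100
    INTERMEDIATE = "INTERMEDIATE"


@dataclass
class RuralityScale:
    """Map prefix -> population-weighted percent-rural score.

    ``groups`` has one row per 3-digit prefix: ``prefix``,
    ``total_population``, ``rural_population`` (both exact integers) and
    ``percent_rural`` (float, NaN where total_population == 0). Scores are
    kept at full float precision; rounding happens only at presentation.
    """

    groups: pd.DataFrame
    build_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = self.groups
        if (g["rural_population"] > g["total_population"]).any():
            raise ScaleError("rural_exceeds_total")

    @property
    def total_population(self) -> int:
        return int(self.groups["total_population"].sum())

    @property
    def rural_population(self) -> int:
        return int(self.groups["rural_population"].sum())

    def score(self, prefix: str) -> float:
        """percent_rural for ``prefix``; NaN if unknown or undefined."""
        row = self.groups.loc[self.groups["prefix"] == prefix]
        if row.empty:
            return float("nan")
        return float(row["percent_rural"].iloc[0])

    def stratum(self, prefix: str) -> Stratum | None:
        """Endpoint classification from exact integer population counts."""
        row = self.groups.loc[self.groups["prefix"] == prefix]
        if row.empty or row["total_population"].iloc[0] == 0:
            return None
        rural = int(row["rural_population"].iloc[0])
        total = int(row["total_population"].iloc[0])
        if rural == 0:
            return Stratum.FULLY_URBAN
        if rural == total:
            return Stratum.FULLY_RURAL
        return Stratum.INTERMEDIATE

    def to_frame(self) -> pd.DataFrame:
        """Export view sorted by prefix (percent_rural empty for UNDEFINED)."""
        return self.groups.sort_values("prefix", kind="mergesort").reset_index(
            drop=True
        )


def build_scale(universe: ZipUniverse) -> RuralityScale:
    """Aggregate a tagged ZIP universe into the prefix-level rurality scale.

    Every ZIP contributes to exactly one group (its first three digits), so
    group populations conserve the universe totals exactly; the arithmetic
    is integer until the final ratio.
    """
    if len(universe) == 0:
        raise ScaleError("empty_universe")

    rec = universe.records
    prefix = rec["zip5"].str[:3]
    rural_pop = rec["population"].where(rec["is_rural"], 0)
    agg = (
        pd.DataFrame(
            {
                "prefix": prefix,
                "total_population": rec["population"],
                "rural_population": rural_pop,
            }
        )
        .groupby("prefix", as_index=False)
        .sum()
        .sort_values("prefix", kind="mergesort")
        .reset_index(drop=True)
    )
    total = agg["total_population"].to_numpy(dtype="int64")
    rural = agg["rural_population"].to_numpy(dtype="int64")
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * rural / np.where(total > 0, total, 1), np.nan)
    agg["percent_rural"] = pct

    meta = {
        "n_prefixes": len(agg),
        "n_zips": len(rec),
        "n_undefined_groups": int((total == 0).sum()),
        "total_population": int(total.sum()),
        "rural_population": int(rural.sum()),
    }
    return RuralityScale(groups=agg, build_meta=meta)


def map_participants(
    cohort: pd.DataFrame, scale: RuralityScale
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Attach each participant's percent-rural score by 3-digit prefix lookup.

    ``cohort`` needs columns ``participant_id`` and ``zip3``. Returns a
    frame (participant_id, percent_rural, missing_reason) plus per-reason
    exclusion counts. Reasons: ``missing_zip3`` (absent/blank/non-3-digit),
    ``suppressed_prefix`` (the "000" safe-harbor code), ``unknown_prefix``
    (not in the scale), ``undefined_score`` (zero-population group).
    """
    if cohort.empty:
        raise ScaleError("empty_cohort")

    zip3 = cohort["zip3"].astype("string")
    valid3 = zip3.notna() & zip3.str.fullmatch(r"[0-9]{3}").fillna(False)
    lookup = scale.groups.set_index("prefix")["percent_rural"]

    score = pd.Series(np.nan, index=cohort.index, dtype=float)
    reason = pd.Series(pd.NA, index=cohort.index, dtype="string")

    reason[~valid3] = "missing_zip3"
    suppressed = valid3 & (zip3 == SUPPRESSED_PREFIX)
    reason[suppressed] = "suppressed_prefix"

    candidate = valid3 & ~suppressed
    known = candidate & zip3.isin(lookup.index)
    reason[candidate & ~known] = "unknown_prefix"

    mapped = zip3[known].map(lookup).astype(float)
    score[known] = mapped
    reason[mapped.index[mapped.isna()]] = "undefined_score"

    out = pd.DataFrame(
        {
            "participant_id": cohort["participant_id"].to_numpy(),
            "percent_rural": score.to_numpy(),
            "missing_reason": reason.to_numpy(),
        }
    )
    counts = reason.value_counts().to_dict()
    counts = {str(k): int(v) for k, v in counts.items()}
    counts["scored"] = int(out["percent_rural"].notna().sum())
    return out, counts


def classify_stratum(percent_rural: float) -> Stratum:
    """Classify a defined score: exactly 0 -> FULLY_URBAN, exactly 100 ->
    FULLY_RURAL, anything strictly between -> INTERMEDIATE.

    The endpoints are set-membership facts (no rural population / all rural
    population), so exact comparison is correct here: 0 and 100 arise from
    the integer ratios 0/n and n/n, both exact in floating point.
    """
    if not np.isfinite(percent_rural):
        raise ScaleError("undefined_score")
    if percent_rural == 0:
        return Stratum.FULLY_URBAN
    if percent_rural == 100:
        return Stratum.FULLY_RURAL
    return Stratum.INTERMEDIATE
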