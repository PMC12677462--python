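"""Ingestion and normalization of the 5-digit ZIP universe.

Two files feed the rurality scale: a national table of 5-digit ZIP codes
with their populations (the population-weight source) and a list of
5-digit ZIP codes designated rural by the federal rural-health grant
eligibility criteria. This module reads both, normalizes ZIP tokens to
canonical zero-padded 5-digit strings, and produces a single tagged
``ZipUniverse`` in which every ZIP is marked rural or non-rural.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "ZipNormalizationError",
    "GeodataError",
    "ZipUniverse",
    "normalize_zip",
    "try_normalize_zip",
    "read_zip_population",
    "read_rural_list",
    "apply_rural_designation",
]

_DIGITS = re.compile(r"^[0-9]+$")


class GeodataError(ValueError):
    """Raised for unrecoverable problems in the ZIP input tables."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


class ZipNormalizationError(GeodataError):
    """A token could not be coerced to a 5-digit ZIP code."""


def try_normalize_zip(raw) -> tuple[str | None, str | None]:
    """Normalize ``raw`` to a zero-padded 5-digit ZIP, or explain why not.

    Returns ``(zip5, None)`` on success and ``(None, reason)`` on failure,
    where ``reason`` is one of ``empty``, ``non_numeric``, ``too_long``.

    Accepted forms: bare digit strings of up to 5 digits (zero-padded on
    the left, so ``"501"`` becomes ``"00501"``), ZIP+4 (``"12345-6789"``
    truncated to the first five digits), and integers. Anything else is
    rejected rather than guessed at.
    """
    if raw is None:
        return None, "empty"
    if isinstance(raw, float) and raw.is_integer():
        raw = int(raw)
    token = str(raw).strip()
    if not token:
        return None, "empty"
    # ZIP+4: keep the part before the hyphen
    if "-" in token:
        token = token.split("-", 1)[0].strip()
        if not token:
            return None, "empty"
    if not _DIGITS.match(token):
        return None, "non_numeric"
    if len(token) > 5:
        return None, "too_long"
    return token.zfill(5), None


def normalize_zip(raw) -> str:
    """Normalize a ZIP token, raising :class:`ZipNormalizationError` on failure."""
    zip5, reason = try_normalize_zip(raw)
    if zip5 is None:
        raise ZipNormalizationError(reason, repr(raw))
    return zip5


@dataclass
class ZipUniverse:
    """The tagged national set of 5-digit ZIP codes.

    ``records`` has one row per unique ``zip5`` with integer ``population``
    and boolean ``is_rural``. ``source_meta`` carries provenance: file
    names, row counts, rejected-token counts, unmatched rural entries.
    """

    records: pd.DataFrame
    source_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"zip5", "population", "is_rural"}
        missing = required - set(self.records.columns)
        if missing:
            raise GeodataError("missing_columns", ", ".join(sorted(missing)))
        if self.records["zip5"].duplicated().any():
            dups = self.records.loc[self.records["zip5"].duplicated(), "zip5"]
            raise GeodataError("duplicate_zip", ", ".join(dups.head(5)))
        if (self.records["population"] < 0).any():
            raise GeodataError("negative_population")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def total_population(self) -> int:
        return int(self.records["population"].sum())

    @property
    def rural_population(self) -> int:
        return int(self.records.loc[self.records["is_rural"], "population"].sum())

    def to_frame(self) -> pd.DataFrame:
        """Normalized export view (zip5, population, is_rural), sorted by zip5."""
        return (
            self.records[["zip5", "population", "is_rural"]]
            .sort_values("zip5", kind="mergesort")
            .reset_index(drop=True)
        )


def _read_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise GeodataError("unreadable_file", str(path))
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    # dtype=str so leading zeros in quoted ZIP columns survive
    return pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)


def read_zip_population(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> ZipUniverse:
    """Read the ZIP population table into a :class:`ZipUniverse`.

    ``column_map`` maps the logical names ``zip`` and ``population`` to the
    file's column names (defaults: ``zip5`` and ``population``). All records
    start with ``is_rural=False``; see :func:`apply_rural_designation`.

    Duplicate ZIPs and negative populations are hard errors — silently
    summing duplicates could hide a mix of crosswalk vintages. Tokens that
    cannot be normalized are dropped and counted in ``source_meta``.
    """
    column_map = dict(column_map or {})
    zip_col = column_map.get("zip", "zip5")
    pop_col = column_map.get("population", "population")

    df = _read_table(path, sep=sep)
    for col in (zip_col, pop_col):
        if col not in df.columns:
            raise GeodataError("missing_columns", col)

    n_input = len(df)
    normalized = df[zip_col].map(lambda t: try_normalize_zip(t))
    ok = normalized.map(lambda pair: pair[0] is not None)
    rejected_reasons = (
        normalized[~ok].map(lambda pair: pair[1]).value_counts().to_dict()
    )
    df = df.loc[ok].copy()
    df["zip5"] = normalized[ok].map(lambda pair: pair[0])

    if df["zip5"].duplicated().any():
        dups = sorted(df.loc[df["zip5"].duplicated(), "zip5"].unique())
        raise GeodataError("duplicate_zip", ", ".join(dups[:5]))

    population = pd.to_numeric(df[pop_col], errors="coerce")
    if population.isna().any():
        raise GeodataError("non_numeric_population")
    if (population < 0).any():
        raise GeodataError("negative_population")

    records = pd.DataFrame(
        {
            "zip5": df["zip5"].to_numpy(),
            "population": population.astype("int64").to_numpy(),
            "is_rural": False,
        }
    ).reset_index(drop=True)

    meta = {
        "population_file": str(path),
        "n_input_rows": n_input,
        "n_records": len(records),
        "n_rejected": n_input - len(records),
        "rejected_reasons": rejected_reasons,
    }
    return ZipUniverse(records=records, source_meta=meta)


def read_rural_list(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> list[str]:
    """Read the rural-designation file and return normalized 5-digit ZIPs.

    Non-normalizable tokens are dropped (they can never match a universe
    record); duplicates are collapsed.
    """
    column_map = dict(column_map or {})
    zip_col = column_map.get("zip", "zip5")
    df = _read_table(path, sep=sep)
    if zip_col not in df.columns:
        raise GeodataError("missing_columns", zip_col)
    out: list[str] = []
    seen: set[str] = set()
    for token in df[zip_col]:
        zip5, _ = try_normalize_zip(token)
        if zip5 is not None and zip5 not in seen:
            seen.add(zip5)
            out.append(zip5)
    return out


def apply_rural_designation(
    universe: ZipUniverse, rural_list: Iterable[str]
) -> ZipUniverse:
    """Tag universe records rural by membership in the (normalized) rural list.

    Rural-list entries absent from the universe are counted in
    ``source_meta['n_unmatched_rural']`` and otherwise ignored: they carry
    no population, so creating zero-population records for them could not
    change any population-weighted score. The operation is idempotent and
    conserves total population (flags are the only thing it touches).
    """
    normalized: set[str] = set()
    for token in rural_list:
        zip5, _ = try_normalize_zip(token)
        if zip5 is not None:
            normalized.add(zip5)

    records = universe.records.copy()
    records["is_rural"] = records["zip5"].isin(normalized)
    n_matched = int(records["is_rural"].sum())
    meta = dict(universe.source_meta)
    meta.update(
        {
            "n_rural_list": len(normalized),
            "n_rural_matched": n_matched,
            "n_unmatched_rural": len(normalized) - n_matched,
        }
    )
    return ZipUniverse(records=records, source_meta=meta)
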