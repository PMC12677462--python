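"""Composite coding of healthcare access & utilization survey items.

Two binary outcomes are derived from per-item responses:

* delayed care — 9 designated items; 6 or more affirmative answers code
  the participant 1, fewer than 6 code 0;
* healthcare affordability — 14 designated items; 9 or more affirmative
  answers code 1, fewer than 9 code 0.

The thresholds are deliberately conservative: they flag persistent or
widespread barriers rather than isolated instances. Which items belong to
each domain is configuration (an :class:`ItemManifest`, loadable from
YAML), not code — the instrument's 114 questions are not enumerated here,
and per-item affirmative value sets accommodate reverse-worded items.

Missing, skipped, and refused responses count as non-affirmative, which
is conservative toward coding 0; ``min_answered`` lets callers require a
minimum number of answered items before a participant is assessed at all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "Domain",
    "ManifestError",
    "ItemManifest",
    "NOT_ASSESSED",
    "default_manifests",
    "load_manifests",
    "count_affirmative",
    "code_outcome",
    "code_cohort",
]


class Domain(str, Enum):
    DELAYED_CARE = "DELAYED_CARE"
    AFFORDABILITY = "AFFORDABILITY"


#: expected item count and affirmative threshold per domain
DOMAIN_SPECS: dict[Domain, tuple[int, int]] = {
    Domain.DELAYED_CARE: (9, 6),
    Domain.AFFORDABILITY: (14, 9),
}

NOT_ASSESSED = "NOT_ASSESSED"

DEFAULT_AFFIRMATIVE = frozenset({"Yes", "yes", "YES", "1", "True", "true"})


class ManifestError(ValueError):
    pass


@dataclass(frozen=True)
class ItemManifest:
    """The item set, threshold, and affirmative values for one domain."""

    domain: Domain
    item_ids: tuple[str, ...]
    threshold: int
    affirmative_values: Mapping[str, frozenset] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_expected, t_expected = DOMAIN_SPECS[self.domain]
        if len(self.item_ids) != n_expected:
            raise ManifestError(
                f"{self.domain.value} manifest must list exactly {n_expected} "
                f"items, got {len(self.item_ids)}"
            )
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ManifestError(f"{self.domain.value} manifest has duplicate items")
        if not 1 <= self.threshold <= len(self.item_ids):
            raise ManifestError(
                f"threshold {self.threshold} outside 1..{len(self.item_ids)}"
            )
        if self.threshold != t_expected:
            warnings.warn(
                f"{self.domain.value} threshold {self.threshold} differs from "
                f"the standard {t_expected}",
                stacklevel=3,
            )
        unknown = set(self.affirmative_values) - set(self.item_ids)
        if unknown:
            raise ManifestError(
                f"affirmative_values for items not in manifest: {sorted(unknown)}"
            )

    def affirmative_for(self, item_id: str) -> frozenset:
        return frozenset(self.affirmative_values.get(item_id, DEFAULT_AFFIRMATIVE))


def default_manifests(
    delayed_items: Sequence[str] | None = None,
    affordability_items: Sequence[str] | None = None,
) -> dict[Domain, ItemManifest]:
    """Manifests with standard thresholds and generated item ids.

    Default ids (``dc_01``..``dc_09``, ``af_01``..``af_14``) match the
    synthetic-data generator; real analyses supply their own via
    :func:`load_manifests`.
    """
    delayed = tuple(delayed_items or (f"dc_{i:02d}" for i in range(1, 10)))
    afford = tuple(affordability_items or (f"af_{i:02d}" for i in range(1, 15)))
    return {
        Domain.DELAYED_CARE: ItemManifest(Domain.DELAYED_CARE, delayed, 6),
        Domain.AFFORDABILITY: ItemManifest(Domain.AFFORDABILITY, afford, 9),
    }


def load_manifests(path: str | Path) -> dict[Domain, ItemManifest]:
    """Load domain manifests from a YAML file.

    Layout: one section per domain, e.g.::

        DELAYED_CARE:
          items: [q1, q2, ...]          # exactly 9
          threshold: 6                  # optional, defaults to standard
          affirmative:                  # optional per-item override
            q2: ["No"]                  # reverse-worded item
        AFFORDABILITY:
          items: [...]                  # exactly 14

    Validation errors name the offending entry.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ManifestError(f"manifest file {path} is not a mapping")
    out: dict[Domain, ItemManifest] = {}
    for key, section in raw.items():
        try:
            domain = Domain(key)
        except ValueError:
            raise ManifestError(f"unknown domain section {key!r}") from None
        if not isinstance(section, dict) or "items" not in section:
            raise ManifestError(f"section {key} must contain an 'items' list")
        items = tuple(str(i) for i in section["items"])
        threshold = int(section.get("threshold", DOMAIN_SPECS[domain][1]))
        affirm = {
            str(item): frozenset(str(v) for v in values)
            for item, values in (section.get("affirmative") or {}).items()
        }
        out[domain] = ItemManifest(domain, items, threshold, affirm)
    return out


def _is_answered(value) -> bool:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return False
    return str(value).strip().lower() not in {"", "skip", "skipped", "refused", "pmi_skip"}


def count_affirmative(responses: Mapping[str, object], manifest: ItemManifest) -> int:
    """Number of manifest items answered affirmatively.

    ``responses`` maps item_id -> response value for one participant.
    Items absent, skipped, or refused count as non-affirmative.
    """
    count = 0
    for item in manifest.item_ids:
        value = responses.get(item)
        if value is not None and str(value) in manifest.affirmative_for(item):
            count += 1
    return count


def code_outcome(
    responses: Mapping[str, object],
    manifest: ItemManifest,
    min_answered: int = 1,
) -> int | str:
    """Code one participant: 1 iff affirmative count >= threshold, else 0;
    ``NOT_ASSESSED`` if fewer than ``min_answered`` manifest items were
    answered."""
    if min_answered > len(manifest.item_ids):
        raise ManifestError("min_answered exceeds number of manifest items")
    answered = sum(
        1 for item in manifest.item_ids if _is_answered(responses.get(item))
    )
    if answered < min_answered:
        return NOT_ASSESSED
    return 1 if count_affirmative(responses, manifest) >= manifest.threshold else 0


def code_cohort(
    responses: pd.DataFrame,
    manifests: Mapping[Domain, ItemManifest],
    min_answered: int = 1,
) -> pd.DataFrame:
    """Code every participant in a long-format response table.

    ``responses`` columns: participant_id, item_id, response. Returns one
    row per participant with ``delayed_care`` / ``affordability`` coded
    values (``pd.NA`` where not assessed) and per-domain affirmative
    counts. Duplicate (participant, item) pairs are an error.
    """
    if responses.duplicated(["participant_id", "item_id"]).any():
        raise ManifestError("duplicate (participant_id, item_id) response rows")

    wide = responses.pivot(
        index="participant_id", columns="item_id", values="response"
    )
    rows = []
    col_names = {
        Domain.DELAYED_CARE: "delayed_care",
        Domain.AFFORDABILITY: "affordability",
    }
    for pid, row in wide.iterrows():
        rec: dict = {"participant_id": pid}
        resp = {k: v for k, v in row.items() if _is_answered(v)}
        for domain, manifest in manifests.items():
            coded = code_outcome(resp, manifest, min_answered=min_answered)
            name = col_names[domain]
            rec[name] = pd.NA if coded == NOT_ASSESSED else coded
            rec[f"{name}_count"] = count_affirmative(resp, manifest)
        rows.append(rec)
    out = pd.DataFrame(rows)
    for col in ("delayed_care", "affordability"):
        if col in out.columns:
            out[col] = out[col].astype("Int64")
    return out
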