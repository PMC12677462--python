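#!/usr/bin/env python
"""Describe the fully-urban (0%) and fully-rural (100%) strata.

The scale's exact endpoints give clean binary rural/urban groups:
participants whose entire 3-digit area has no rural-designated
population, versus those whose area is entirely rural-designated. For
each stratum this prints counts and half-up-rounded percentages per
sociodemographic category (denominator: participants who provided any
demographics) and the stratum's share of total enrollment.

Writes results/table_fully_urban.csv and results/table_fully_rural.csv.
"""

from pathlib import Path

import pandas as pd

from ruralscale.stats import stratum_table

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    participants = pd.read_csv(ROOT / "inputs" / "participants.csv", dtype={"zip3": str})
    scores = pd.read_csv(ROOT / "participant_scores.csv")
    cohort = participants.merge(scores, on="participant_id")

    for stratum, fname in (
        ("FULLY_URBAN", "table_fully_urban.csv"),
        ("FULLY_RURAL", "table_fully_rural.csv"),
    ):
        table = stratum_table(cohort, stratum, total_enrolled=len(cohort))
        table.to_frame().to_csv(ROOT / fname, index=False)
        _, share = table.rows["_share"]["share_of_enrollment"]
        print(f"\n{stratum}: n = {table.n_total} "
              f"({share:g}% of enrollment), "
              f"{table.n_with_demographics} with demographics")
        if table.age_mean_sd:
            mean, sd = table.age_mean_sd
            print(f"  age mean (SD): {mean:.0f} ({sd:.1f})")
        for category, levels in table.rows.items():
            if category == "_share":
                continue
            pretty = ", ".join(
                f"{level} {count} ({pct}%)" for level, (count, pct) in levels.items()
            )
            print(f"  {category}: {pretty}")


if __name__ == "__main__":
    main()
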