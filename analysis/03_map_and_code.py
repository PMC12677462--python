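#!/usr/bin/env python
"""Score participants on the rurality scale and code the two composites.

Each participant's 3-digit prefix is looked up in the scale (the "000"
safe-harbor suppression code and unknown prefixes are excluded with
logged reasons). Survey responses are then dichotomized: delayed care = 1
at >= 6 affirmative answers of 9 items, healthcare affordability = 1 at
>= 9 of 14.

Writes results/participant_scores.csv and results/coded_outcomes.csv.
"""

from pathlib import Path

import pandas as pd

from ruralscale.coding import code_cohort, default_manifests
from ruralscale.scale import RuralityScale, map_participants

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    groups = pd.read_csv(ROOT / "scale.csv", dtype={"prefix": str})
    scale = RuralityScale(groups=groups)
    participants = pd.read_csv(ROOT / "inputs" / "participants.csv", dtype={"zip3": str})
    scores, exclusions = map_participants(participants, scale)
    scores.to_csv(ROOT / "participant_scores.csv", index=False, float_format="%.10g")
    print(f"scored {exclusions['scored']} of {len(scores)} participants; "
          f"exclusions by reason: "
          f"{ {k: v for k, v in exclusions.items() if k != 'scored'} }")

    responses = pd.read_csv(ROOT / "inputs" / "responses.csv", dtype=str)
    coded = code_cohort(responses, default_manifests())
    coded.to_csv(ROOT / "coded_outcomes.csv", index=False)
    for outcome in ("delayed_care", "affordability"):
        n1 = int((coded[outcome] == 1).sum())
        print(f"{outcome}: {n1} of {len(coded)} coded 1 "
              f"({100 * n1 / len(coded):.1f}%)")


if __name__ == "__main__":
    main()
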