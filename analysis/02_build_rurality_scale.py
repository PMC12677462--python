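#!/usr/bin/env python
"""Build the continuous percent-rural scale from the ZIP tables.

Tags every 5-digit ZIP rural/non-rural by the designation list, groups
ZIPs by their first three digits, and scores each prefix with the
population-weighted rural share: 100 * rural_population / total_population.

Writes results/scale.csv and prints the scale's composition, including
how many prefixes sit at the exact 0% (fully urban) and 100% (fully
rural) endpoints.
"""

from pathlib import Path

from ruralscale.geodata import apply_rural_designation, read_rural_list, read_zip_population
from ruralscale.scale import build_scale

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    universe = read_zip_population(ROOT / "inputs" / "zip_population.csv")
    rural_list = read_rural_list(ROOT / "inputs" / "rural_zips.csv")
    universe = apply_rural_designation(universe, rural_list)
    scale = build_scale(universe)

    frame = scale.to_frame()
    frame.to_csv(ROOT / "scale.csv", index=False, float_format="%.10g")

    defined = frame["percent_rural"].dropna()
    print(f"{len(universe)} ZIPs -> {len(frame)} three-digit prefixes")
    print(f"total population {scale.total_population:,} "
          f"({scale.rural_population:,} in rural ZIPs)")
    print(f"fully urban prefixes (0%):   {(defined == 0).sum()}")
    print(f"fully rural prefixes (100%): {(defined == 100).sum()}")
    print(f"median prefix score: {defined.median():.1f}% rural")
    print(f"-> {ROOT / 'scale.csv'}")


if __name__ == "__main__":
    main()
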