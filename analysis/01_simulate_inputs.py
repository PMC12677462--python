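#!/usr/bin/env python
"""Generate the four synthetic input tables the pipeline consumes.

The real participant-level data (3-digit ZIP geolocation plus the
healthcare access & utilization survey) lives in an access-restricted
enclave, so this analysis runs on a synthetic cohort with the same
structure: a national 5-digit ZIP population table, a rural-designation
list, a participant table keyed by 3-digit prefix, and long-format survey
responses whose per-item affirmative probability rises with rurality
(logistic slope effect_beta = 1.0 on the rurality fraction).

Writes results/inputs/{zip_population,rural_zips,participants,responses}.csv
and a generator_config.json sidecar.
"""

from pathlib import Path

from ruralscale.simulate import GeneratorConfig, write_inputs

OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"


def main() -> None:
    config = GeneratorConfig(seed=42, n_participants=20000, effect_beta=1.0)
    paths = write_inputs(config, OUT)
    print(f"Synthetic world: {config.n_prefixes} prefixes, "
          f"{config.n_participants} participants, effect_beta={config.effect_beta}")
    for role, path in paths.items():
        print(f"  {role}: {path}")


if __name__ == "__main__":
    main()
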