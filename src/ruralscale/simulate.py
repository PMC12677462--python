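"""Synthetic ZIP universe, cohort, and survey responses.

The participant-level data this pipeline was designed for lives in an
access-restricted enclave, so everything downstream is exercised on
synthetic inputs with the same statistical structure:

* a ZIP universe: 3-digit prefixes, each holding a handful of 5-digit
  ZIPs with log-normal populations; each prefix draws a rural propensity
  from a Beta distribution and flags its ZIPs rural independently with
  that propensity. Point-mass overrides force a share of prefixes to be
  exactly fully urban (propensity 0) and fully rural (propensity 1), so
  the scale's endpoint strata are guaranteed non-empty at desk scale;
* a cohort: participants land in prefixes with probability proportional
  to prefix population and carry categorical demographics (optionally
  tilted by rurality) and an age;
* survey responses: for each of the 9 delayed-care and 14 affordability
  items, a participant answers affirmatively with probability
  logistic(alpha_item + beta * r), where r = percent_rural / 100. The
  shared slope beta is the single dial for the rurality effect: beta = 0
  is the exact null, beta > 0 makes outcome-coded participants come from
  more rural areas — the qualitative pattern the analysis is meant to
  detect.

All randomness flows from one integer seed through a single
``numpy.random.default_rng`` stream; a fixed seed gives byte-identical
output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ConfigError", "GeneratorConfig", "generate_zip_universe", "generate_cohort", "write_inputs"]

DELAYED_ITEMS = tuple(f"dc_{i:02d}" for i in range(1, 10))
AFFORDABILITY_ITEMS = tuple(f"af_{i:02d}" for i in range(1, 15))


class ConfigError(ValueError):
    pass


def _default_demographics() -> dict:
    # Level frequencies loosely follow the overall composition of a large
    # US research cohort; "rural_tilt" adds tilt*r to the first level's
    # weight (renormalized), emulating compositional differences between
    # fully-urban and fully-rural areas.
    return {
        "race": {
            "levels": ["White", "Black/African American", "Others or more than one"],
            "probs": [0.55, 0.20, 0.25],
            "rural_tilt": 0.35,
            "missing_rate": 0.012,
        },
        "ethnicity": {
            "levels": ["Non-Hispanic", "Hispanic", "Others"],
            "probs": [0.77, 0.20, 0.03],
            "rural_tilt": 0.15,
            "missing_rate": 0.012,
        },
        "sex_at_birth": {
            "levels": ["Female", "Male", "Others"],
            "probs": [0.61, 0.38, 0.01],
            "rural_tilt": 0.07,
            "missing_rate": 0.0,
        },
        "education": {
            "levels": [
                "College/Advanced Degree",
                "Less than College Graduate",
                "High School Graduate",
            ],
            "probs": [0.48, 0.33, 0.19],
            "rural_tilt": -0.07,
            "missing_rate": 0.025,
        },
    }


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic world; defaults define the study conditions.

    ``population_median``/``population_sigma`` parameterize the log-normal
    ZIP population (median ~8,000 persons, sigma 1.0 on the log scale).
    ``rural_beta_a``/``rural_beta_b`` shape the per-prefix rural
    propensity; ``frac_forced_urban``/``frac_forced_rural`` are the
    point-mass shares pinned at exactly 0 and 1. ``effect_beta`` is the
    log-odds increase in per-item affirmative probability per unit of
    rurality fraction r in [0, 1]; item intercepts are the baseline
    log-odds at r = 0.
    """

    seed: int = 42
    n_prefixes: int = 200
    zips_per_prefix: tuple[int, int] = (5, 30)
    population_median: float = 8000.0
    population_sigma: float = 1.0
    rural_beta_a: float = 0.4
    rural_beta_b: float = 0.6
    frac_forced_urban: float = 0.10
    frac_forced_rural: float = 0.05
    n_participants: int = 20000
    effect_beta: float = 1.0
    intercept_delayed: float = -1.2
    intercept_affordability: float = -1.0
    no_demographics_rate: float = 0.015
    demographics: dict = field(default_factory=_default_demographics)

    def validate(self) -> None:
        problems = []
        if self.n_prefixes <= 0:
            problems.append("n_prefixes must be positive")
        if self.n_prefixes > 999:
            problems.append("n_prefixes cannot exceed 999 distinct prefixes")
        lo, hi = self.zips_per_prefix
        if not (0 < lo <= hi):
            problems.append("zips_per_prefix must be a positive (low, high) range")
        if self.population_median <= 0 or self.population_sigma <= 0:
            problems.append("population model parameters must be positive")
        if self.rural_beta_a <= 0 or self.rural_beta_b <= 0:
            problems.append("Beta propensity parameters must be positive")
        if not (0 <= self.frac_forced_urban <= 1 and 0 <= self.frac_forced_rural <= 1):
            problems.append("forced fractions must lie in [0, 1]")
        if self.frac_forced_urban + self.frac_forced_rural > 1:
            problems.append("forced fractions sum above 1")
        if self.n_participants <= 0:
            problems.append("n_participants must be positive")
        if not 0 <= self.no_demographics_rate < 1:
            problems.append("no_demographics_rate must lie in [0, 1)")
        if problems:
            raise ConfigError("; ".join(problems))

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["zips_per_prefix"] = list(d["zips_per_prefix"])
        return json.dumps(d, indent=2, sort_keys=True)


def generate_zip_universe(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the (population table, rural-ZIP list) pair of input tables.

    Prefixes are sampled without replacement from 001-999 ("000" is
    reserved as the de-identification suppression code). The first
    ``frac_forced_urban`` share of sampled prefixes gets propensity
    exactly 0, the next ``frac_forced_rural`` share exactly 1, the rest
    Beta(a, b); each ZIP in a prefix is flagged rural independently with
    the prefix propensity.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    prefixes = rng.choice(np.arange(1, 1000), size=config.n_prefixes, replace=False)
    prefixes = np.sort(prefixes)

    n_urban = int(np.ceil(config.frac_forced_urban * config.n_prefixes))
    n_rural = int(np.ceil(config.frac_forced_rural * config.n_prefixes))
    propensity = rng.beta(
        config.rural_beta_a, config.rural_beta_b, size=config.n_prefixes
    )
    forced = rng.permutation(config.n_prefixes)
    propensity[forced[:n_urban]] = 0.0
    propensity[forced[n_urban : n_urban + n_rural]] = 1.0

    lo, hi = config.zips_per_prefix
    n_zips = rng.integers(lo, hi + 1, size=config.n_prefixes)

    rows = []
    rural_rows = []
    mu = np.log(config.population_median)
    for i, prefix in enumerate(prefixes):
        k = int(n_zips[i])
        suffixes = rng.choice(100, size=min(k, 100), replace=False)
        pops = np.maximum(
            1, rng.lognormal(mean=mu, sigma=config.population_sigma, size=len(suffixes))
        ).astype("int64")
        rural_flags = rng.random(len(suffixes)) < propensity[i]
        for suffix, pop, rural in zip(suffixes, pops, rural_flags):
            zip5 = f"{prefix:03d}{suffix:02d}"
            rows.append((zip5, int(pop)))
            if rural:
                rural_rows.append(zip5)

    population = pd.DataFrame(rows, columns=["zip5", "population"])
    rural = pd.DataFrame({"zip5": rural_rows})
    return population, rural


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(
    config: GeneratorConfig, scale
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the (participant table, survey response table) pair.

    ``scale`` is the RuralityScale built from this config's universe.
    Participants fall into prefixes with probability proportional to
    prefix population; every participant answers every generated item
    ("Yes"/"No"). The cohort stream is seeded with ``seed + 1`` so the
    universe and cohort draws are independent but both reproducible from
    the single configured seed.
    """
    config.validate()
    groups = scale.groups
    defined = groups.loc[
        (groups["total_population"] > 0) & groups["percent_rural"].notna()
    ]
    if defined.empty:
        raise ConfigError("scale has no defined-score prefixes")

    rng = np.random.default_rng(config.seed + 1)
    weights = defined["total_population"].to_numpy(dtype=float)
    weights /= weights.sum()
    idx = rng.choice(len(defined), size=config.n_participants, p=weights)
    zip3 = defined["prefix"].to_numpy()[idx]
    r = defined["percent_rural"].to_numpy()[idx] / 100.0

    n = config.n_participants
    participants = pd.DataFrame(
        {
            "participant_id": [f"P{i:06d}" for i in range(1, n + 1)],
            "zip3": zip3,
        }
    )
    for category, spec in config.demographics.items():
        levels = list(spec["levels"])
        base = np.asarray(spec["probs"], dtype=float)
        tilt = float(spec.get("rural_tilt", 0.0))
        probs = np.tile(base, (n, 1))
        probs[:, 0] = np.maximum(base[0] + tilt * r, 0.01)
        probs /= probs.sum(axis=1, keepdims=True)
        u = rng.random(n)
        cum = np.cumsum(probs, axis=1)
        choice = (u[:, None] > cum).sum(axis=1)
        values = np.array(levels, dtype=object)[choice]
        miss_rate = float(spec.get("missing_rate", 0.0))
        if miss_rate > 0:
            values[rng.random(n) < miss_rate] = None
        participants[category] = values
    age = np.clip(rng.normal(54.0, 17.0, size=n), 18, 99)
    participants["age"] = pd.array(age.astype("int64"), dtype="Int64")

    # a small share of participants provided no sociodemographics at all
    if config.no_demographics_rate > 0:
        none_mask = rng.random(n) < config.no_demographics_rate
        for category in config.demographics:
            participants.loc[none_mask, category] = None
        participants.loc[none_mask, "age"] = pd.NA

    items = [(item, config.intercept_delayed) for item in DELAYED_ITEMS] + [
        (item, config.intercept_affordability) for item in AFFORDABILITY_ITEMS
    ]
    frames = []
    pid = participants["participant_id"].to_numpy()
    for item, alpha in items:
        p_affirm = _logistic(alpha + config.effect_beta * r)
        affirm = rng.random(n) < p_affirm
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "item_id": item,
                    "response": np.where(affirm, "Yes", "No"),
                }
            )
        )
    responses = pd.concat(frames, ignore_index=True)
    responses = responses.sort_values(
        ["participant_id", "item_id"], kind="mergesort"
    ).reset_index(drop=True)
    return participants, responses


def write_inputs(config: GeneratorConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write the four CSV inputs plus a JSON config sidecar.

    Returns the paths keyed by role: population, rural_list, participants,
    responses, config.
    """
    from .geodata import ZipUniverse, apply_rural_designation
    from .scale import build_scale

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    population, rural = generate_zip_universe(config)
    universe = ZipUniverse(
        records=population.assign(is_rural=False),
        source_meta={"generator_seed": config.seed},
    )
    universe = apply_rural_designation(universe, rural["zip5"])
    scale = build_scale(universe)
    participants, responses = generate_cohort(config, scale)

    paths = {
        "population": out_dir / "zip_population.csv",
        "rural_list": out_dir / "rural_zips.csv",
        "participants": out_dir / "participants.csv",
        "responses": out_dir / "responses.csv",
        "config": out_dir / "generator_config.json",
    }
    population.to_csv(paths["population"], index=False)
    rural.to_csv(paths["rural_list"], index=False)
    participants.to_csv(paths["participants"], index=False)
    responses.to_csv(paths["responses"], index=False)
    paths["config"].write_text(config.to_json() + "\n")
    return paths
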