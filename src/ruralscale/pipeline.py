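"""End-to-end orchestration: ingest -> scale -> map -> code -> compare -> report.

A single :class:`RunConfig` drives either a real-input run (four CSV
paths plus optional item manifests) or a simulate-mode run (a
:class:`~ruralscale.simulate.GeneratorConfig`); exactly one mode is
active. Outputs are deterministic: identical config and seed give
byte-identical CSV/JSON artifacts.

Artifacts written to the output directory:

* ``scale.csv`` — prefix, total_population, rural_population,
  percent_rural (empty where undefined);
* ``participant_scores.csv`` — participant_id, percent_rural,
  missing_reason;
* ``coded_outcomes.csv`` — per-participant composite codes and counts;
* ``ks_delayed_care.json`` / ``ks_affordability.json`` — D, p, group
  sizes, location of the supremum gap;
* ``ecdf_delayed_care.csv`` / ``ecdf_affordability.csv`` — step-curve
  points (value, cum_prob, group);
* ``table_fully_urban.csv`` / ``table_fully_rural.csv`` — endpoint
  stratum descriptive tables;
* ``run_manifest.json`` — seed, row counts, exclusion counts by reason.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .coding import Domain, code_cohort, default_manifests, load_manifests
from .geodata import apply_rural_designation, read_rural_list, read_zip_population
from .scale import build_scale, map_participants
from .simulate import GeneratorConfig, write_inputs
from .stats import StatsError, compare_outcome_groups, stratum_table

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("ruralscale")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"[{stage}] {detail}")


@dataclass
class RunConfig:
    """Inputs and options for one pipeline run.

    Real-input mode: set the four path fields. Simulate mode: set
    ``generator`` (inputs are generated under ``out_dir/inputs``).
    """

    out_dir: str | Path = "results/run"
    population_path: str | Path | None = None
    rural_list_path: str | Path | None = None
    participants_path: str | Path | None = None
    responses_path: str | Path | None = None
    manifest_path: str | Path | None = None
    generator: GeneratorConfig | None = None
    min_answered: int = 1
    seed: int | None = None
    column_map: dict = field(default_factory=dict)

    def validate(self) -> None:
        real_paths = [
            self.population_path,
            self.rural_list_path,
            self.participants_path,
            self.responses_path,
        ]
        real = all(p is not None for p in real_paths)
        some_real = any(p is not None for p in real_paths)
        if self.generator is not None and some_real:
            raise PipelineError("config", "choose real-input mode OR simulate mode")
        if self.generator is None and not real:
            raise PipelineError(
                "config",
                "real-input mode needs all four input paths "
                "(population, rural list, participants, responses)",
            )


def _require(path: str | Path, stage: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise PipelineError(stage, f"missing input file: {p}")
    return p


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write all artifacts; returns the run manifest.

    Errors at any stage name the stage; partially written artifacts are
    removed so a failed run leaves no half-built output directory.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    try:
        return _run_stages(config, out_dir, written)
    except Exception:
        for path in written:
            if path.exists():
                path.unlink()
        raise


def _run_stages(config: RunConfig, out_dir: Path, written: list[Path]) -> dict:
    manifest: dict = {"version": __version__, "stages": {}}

    # --- stage: inputs -------------------------------------------------
    if config.generator is not None:
        gen = config.generator
        if config.seed is not None:
            gen = GeneratorConfig(**{**gen.__dict__, "seed": config.seed})
        log.info("simulate: generating inputs (seed=%d)", gen.seed)
        paths = write_inputs(gen, out_dir / "inputs")
        manifest["mode"] = "simulate"
        manifest["seed"] = gen.seed
    else:
        paths = {
            "population": _require(config.population_path, "ingest"),
            "rural_list": _require(config.rural_list_path, "ingest"),
            "participants": _require(config.participants_path, "ingest"),
            "responses": _require(config.responses_path, "ingest"),
        }
        manifest["mode"] = "real"
        manifest["seed"] = config.seed
    manifest["inputs"] = {k: str(v) for k, v in paths.items()}

    # --- stage: ingest -------------------------------------------------
    try:
        universe = read_zip_population(paths["population"], config.column_map)
        rural_list = read_rural_list(paths["rural_list"])
        universe = apply_rural_designation(universe, rural_list)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("ingest", str(exc)) from exc
    manifest["stages"]["ingest"] = dict(universe.source_meta)
    log.info(
        "ingest: %d ZIPs, total population %d (%d rural-tagged)",
        len(universe),
        universe.total_population,
        int(universe.records["is_rural"].sum()),
    )

    # --- stage: scale --------------------------------------------------
    try:
        scale = build_scale(universe)
    except Exception as exc:
        raise PipelineError("scale", str(exc)) from exc
    scale_csv = out_dir / "scale.csv"
    scale.to_frame().to_csv(scale_csv, index=False, float_format="%.10g")
    written.append(scale_csv)
    manifest["stages"]["scale"] = dict(scale.build_meta)

    # --- stage: map ----------------------------------------------------
    try:
        participants = pd.read_csv(paths["participants"], dtype={"zip3": str})
        scores, exclusions = map_participants(participants, scale)
    except Exception as exc:
        raise PipelineError("map", str(exc)) from exc
    scores_csv = out_dir / "participant_scores.csv"
    scores.to_csv(scores_csv, index=False, float_format="%.10g")
    written.append(scores_csv)
    manifest["stages"]["map"] = {"n_participants": len(scores), **exclusions}
    log.info("map: %d participants, %d scored", len(scores), exclusions["scored"])

    # --- stage: code ---------------------------------------------------
    try:
        manifests = (
            load_manifests(config.manifest_path)
            if config.manifest_path
            else default_manifests()
        )
        responses = pd.read_csv(paths["responses"], dtype=str)
        coded = code_cohort(responses, manifests, min_answered=config.min_answered)
    except Exception as exc:
        raise PipelineError("code", str(exc)) from exc
    coded_csv = out_dir / "coded_outcomes.csv"
    coded.to_csv(coded_csv, index=False)
    written.append(coded_csv)
    manifest["stages"]["code"] = {
        "n_coded": len(coded),
        "delayed_care_positive": int((coded["delayed_care"] == 1).sum()),
        "affordability_positive": int((coded["affordability"] == 1).sum()),
    }

    # --- stage: compare ------------------------------------------------
    ks_summaries = {}
    for domain in (Domain.DELAYED_CARE, Domain.AFFORDABILITY):
        col = "delayed_care" if domain is Domain.DELAYED_CARE else "affordability"
        try:
            curve0, curve1, ks, excl = compare_outcome_groups(scores, coded, col)
        except StatsError as exc:
            raise PipelineError("compare", f"{col}: {exc}") from exc
        ks_json = out_dir / f"ks_{col}.json"
        ks_json.write_text(json.dumps(ks.to_dict(), indent=2, sort_keys=True) + "\n")
        written.append(ks_json)
        ecdf_csv = out_dir / f"ecdf_{col}.csv"
        pd.concat(
            [
                curve0.to_frame().assign(group=0),
                curve1.to_frame().assign(group=1),
            ],
            ignore_index=True,
        ).to_csv(ecdf_csv, index=False, float_format="%.10g")
        written.append(ecdf_csv)
        ks_summaries[col] = {**ks.to_dict(), **excl}
        log.info("compare %s: D=%.4f p=%.3g", col, ks.d_statistic, ks.p_value)
    manifest["stages"]["compare"] = ks_summaries

    # --- stage: table --------------------------------------------------
    cohort = participants.merge(scores, on="participant_id")
    tables = {}
    for stratum, fname in (
        ("FULLY_URBAN", "table_fully_urban.csv"),
        ("FULLY_RURAL", "table_fully_rural.csv"),
    ):
        try:
            table = stratum_table(cohort, stratum, total_enrolled=len(cohort))
        except StatsError as exc:
            if exc.reason == "empty_stratum":
                log.warning("table: stratum %s empty, skipped", stratum)
                tables[stratum] = {"n_total": 0}
                continue
            raise PipelineError("table", str(exc)) from exc
        path = out_dir / fname
        table.to_frame().to_csv(path, index=False)
        written.append(path)
        tables[stratum] = {
            "n_total": table.n_total,
            "n_with_demographics": table.n_with_demographics,
        }
    manifest["stages"]["table"] = tables

    manifest_path = out_dir / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
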