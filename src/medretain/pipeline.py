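"""Pipeline orchestration: generate | simulate | psa | ceaf | report.

Each command writes CSV artifacts plus a ``manifest_<command>.json``
recording the seed, configuration, package version and SHA-256 hashes of
its inputs and outputs, so every result table is traceable to its inputs.
Identical configuration and seed give byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__, cea
from .config import RunConfig
from .errors import MissingArtifactError
from .params import load_bundle, save_bundle
from .population import EntryPlan
from .runmodel import RunSettings, evaluate_scenarios, results_frame
from .scenarios import enumerate_scenarios
from .synthetic import generate_default_params
from .uncertainty import PSADraws, run_psa
from .economics import valuation_thresholds
from .states import build_state_space

logger = logging.getLogger(__name__)

COMMANDS = ("generate", "simulate", "psa", "ceaf", "report")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(out_dir: Path, command: str, config: RunConfig,
                    inputs: list[Path], outputs: list[Path]) -> Path:
    manifest = {
        "command": command,
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "inputs": {str(p): _sha256(p) for p in inputs},
        "outputs": {str(p): _sha256(p) for p in outputs},
    }
    path = out_dir / f"manifest_{command}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"missing artifact {path}; run the {produced_by!r} command first"
        )
    return path


def _load_inputs(config: RunConfig, out_dir: Path):
    params_dir = Path(config.params_dir) if config.params_dir \
        else out_dir / "params"
    _require(params_dir / "params.yaml", "generate")
    bundle = load_bundle(params_dir)
    bundle.entry_plan = EntryPlan(config.first_cohort_size,
                                  config.cohort_growth, config.n_cohorts)
    bundle.offer_cycle = config.offer_cycle
    bundle.uptake_mode = config.uptake_mode
    bundle.intl_dollar_rate = config.intl_dollar_rate
    settings = RunSettings(config.horizon, config.discount_rate)
    return bundle, settings, params_dir


def _scenario_list(config: RunConfig):
    scenario_list = enumerate_scenarios(subgroup=config.subgroup,
                                        include_baseline=True)
    if config.scenario is not None:
        keep = {"baseline", config.scenario}
        scenario_list = [s for s in scenario_list if s.name in keep]
        if len(scenario_list) < 2 and config.scenario != "baseline":
            raise MissingArtifactError(
                f"unknown scenario {config.scenario!r}"
            )
    return scenario_list


def run_pipeline(config: RunConfig, command: str, out_dir: str | Path,
                 dump_traces: bool = False) -> dict[str, Path]:
    """Execute one pipeline command, returning the artifact paths."""
    if command not in COMMANDS:
        raise ValueError(f"unknown command {command!r}; expected {COMMANDS}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    if command == "generate":
        bundle = generate_default_params(config.seed)
        bundle.entry_plan = EntryPlan(config.first_cohort_size,
                                      config.cohort_growth, config.n_cohorts)
        bundle.offer_cycle = config.offer_cycle
        bundle.uptake_mode = config.uptake_mode
        bundle.intl_dollar_rate = config.intl_dollar_rate
        paths = save_bundle(bundle, out_dir / "params",
                            n_cycles=config.horizon + bundle.max_stock_age(),
                            n_cohorts=config.n_cohorts)
        artifacts = {k: Path(p) for k, p in paths.items()}
        _write_manifest(out_dir, command, config, [], list(artifacts.values()))
        return artifacts

    bundle, settings, params_dir = _load_inputs(config, out_dir)
    param_files = sorted(params_dir.glob("*"))

    if command == "simulate":
        scenario_list = _scenario_list(config)
        results = evaluate_scenarios(bundle, scenario_list, config.subgroup,
                                     settings, keep_traces=dump_traces)
        frame = results_frame(results)
        tables = {
            "summary": frame.reset_index(),
            "proportions": cea.proportions_of_baseline(frame).reset_index(),
            "cost_shares": frame.reset_index()[
                ["scenario"] + [c for c in frame.columns
                                if c.startswith("share_")]],
            "icers": cea.icer_table(frame),
        }
        base = results["baseline"]
        vt = valuation_thresholds(
            base.costs, base.effects,
            state_space=build_state_space(),
            cost_schedule=bundle.costs, rate=config.discount_rate,
            horizon=config.horizon, intl_dollar_rate=config.intl_dollar_rate,
        )
        tables["valuations"] = pd.DataFrame([{
            "per_doctor_year_mwk": vt.per_doctor_year,
            "per_specialist_year_mwk": vt.per_specialist_year,
            "per_doctor_year_intl_dollar":
                vt.in_dollars()["per_doctor_year"],
            "per_specialist_year_intl_dollar":
                vt.in_dollars()["per_specialist_year"],
        }])
        for name, table in tables.items():
            path = out_dir / f"{name}.csv"
            table.to_csv(path, index=False)
            artifacts[name] = path
        if dump_traces:
            trace_dir = out_dir / "traces"
            trace_dir.mkdir(exist_ok=True)
            for name, r in results.items():
                path = trace_dir / f"{name}.csv"
                r.trace.by_state().to_csv(path)
                artifacts[f"trace_{name}"] = path
        _write_manifest(out_dir, command, config, param_files,
                        list(artifacts.values()))
        return artifacts

    if command == "psa":
        draws = run_psa(bundle, n_draws=config.psa_draws, seed=config.seed,
                        subgroup=config.subgroup, settings=settings,
                        dispersion_policy=config.dispersion,
                        scenario_list=_scenario_list(config))
        path = out_dir / "psa_draws.csv"
        draws.to_frame().to_csv(path, index=False)
        artifacts["psa_draws"] = path
        means_path = out_dir / "psa_means.csv"
        draws.means().reset_index().to_csv(means_path, index=False)
        artifacts["psa_means"] = means_path
        _write_manifest(out_dir, command, config, param_files,
                        list(artifacts.values()))
        return artifacts

    if command == "ceaf":
        draws_path = _require(out_dir / "psa_draws.csv", "psa")
        draws = PSADraws.from_frame(pd.read_csv(draws_path),
                                    seed=config.seed,
                                    subgroup=config.subgroup)
        grid = cea.threshold_grid(config.threshold_max, config.threshold_step)
        means = draws.means()
        icers = cea.icer_table(means.reset_index().set_index("scenario"))
        icers_path = out_dir / "icers_psa.csv"
        icers.to_csv(icers_path, index=False)
        artifacts["icers_psa"] = icers_path
        for effect in cea.EFFECTS:
            frontier = cea.ceaf(draws, grid, effect)
            path = out_dir / f"ceaf_{effect}.csv"
            frontier.to_csv(path, index=False)
            artifacts[f"ceaf_{effect}"] = path
        _write_manifest(out_dir, command, config, [draws_path],
                        list(artifacts.values()))
        return artifacts

    # report
    needed = {
        "summary": out_dir / "summary.csv",
        "proportions": out_dir / "proportions.csv",
        "ceaf_doctor_years": out_dir / "ceaf_doctor_years.csv",
        "ceaf_specialist_years": out_dir / "ceaf_specialist_years.csv",
    }
    for key, path in needed.items():
        _require(path, "simulate" if "ceaf" not in key else "ceaf")
    lines = ["# Specialty-training policy report", ""]
    props = pd.read_csv(needed["proportions"])
    lines.append("## Effects as proportion of baseline (discounted)")
    lines.append(props.to_string(index=False))
    for effect in cea.EFFECTS:
        frontier = pd.read_csv(needed[f"ceaf_{effect}"])
        switches = cea.ceaf_switch_points(frontier)
        lines.append(f"\n## CEAF switch points ({effect})")
        lines.append(switches.to_string(index=False))
    path = out_dir / "report.md"
    path.write_text("\n".join(lines) + "\n")
    artifacts["report"] = path
    _write_manifest(out_dir, command, config, list(needed.values()), [path])
    return artifacts
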