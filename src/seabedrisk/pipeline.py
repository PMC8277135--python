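"""Three-stage workflow orchestration: expert maps -> combined network ->
Bayesian network -> scenario reports, with a reproducibility manifest.

Every defaulted choice (uniform policy, tie-breaks) is logged and recorded in
the manifest so a run can be audited and reproduced from config + seed +
input checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .bn_core import (
    CycleError,
    ModelError,
    Network,
    PROB_TOL,
    read_model_file,
)
from .causal_map import (
    degree_table,
    harmonize,
    merge_maps,
    read_concept_maps,
    read_synonym_table,
    summarize,
    to_adjacency,
    to_dot,
    to_graphml,
)
from .scenario_engine import compare_scenarios, read_scenario_file

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "validate_model_file"]


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    maps_path: Path
    synonyms_path: Path | None
    model_path: Path
    scenarios_path: Path
    output_dir: Path
    policy: str = "uniform"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("maps_path", "synonyms_path", "model_path", "scenarios_path", "output_dir"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(path: Path | None, stage: str) -> Path:
    if path is None or not Path(path).exists():
        raise PipelineError(stage, f"missing input file: {path}")
    return Path(path)


def validate_model_file(path: str | Path) -> list[str]:
    """Collect every structural violation in a model file; empty list = valid."""
    violations: list[str] = []
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except Exception as exc:  # unreadable file is a single fatal violation
        return [f"unreadable model file: {exc}"]
    if not isinstance(doc, dict):
        return ["model file is not a mapping"]

    kinds = {v.get("name"): v.get("kind", "random") for v in doc.get("variables", [])}
    cards = {v.get("name"): len(v.get("states", [])) for v in doc.get("variables", [])}
    for v in doc.get("variables", []):
        if len(v.get("states", [])) < 2:
            violations.append(f"variable {v.get('name')!r} has fewer than 2 states")

    seen_children = set()
    for c in doc.get("cpts", []):
        child = c.get("child")
        if child not in kinds:
            violations.append(f"CPT child {child!r} is not declared")
            continue
        if kinds[child] == "decision":
            violations.append(f"decision variable {child!r} carries a CPT")
        seen_children.add(child)
        parents = c.get("parents", [])
        for p in parents:
            if p not in kinds:
                violations.append(f"CPT for {child!r} references undeclared parent {p!r}")
        expected_rows = 1
        ok = True
        for p in parents:
            if p in cards:
                expected_rows *= cards[p]
            else:
                ok = False
        rows = c.get("rows", [])
        if ok and len(rows) != expected_rows:
            violations.append(
                f"CPT for {child!r} has {len(rows)} rows, expected {expected_rows}"
            )
        for row in rows:
            s = sum(row.get("p", []))
            if abs(s - 1.0) > PROB_TOL:
                violations.append(
                    f"CPT for {child!r}: row given {row.get('given')} sums to {s!r}"
                )
    for name, kind in kinds.items():
        if kind == "random" and name not in seen_children:
            violations.append(f"random variable {name!r} has no CPT")

    if not violations:
        try:
            read_model_file(path)
        except CycleError as exc:
            violations.append(str(exc))
        except ModelError as exc:
            violations.append(str(exc))
    return violations


def run_pipeline(config: PipelineConfig) -> dict:
    """Run merge -> summarize -> build/validate BN -> scenarios and write all
    artifacts plus a manifest to the output directory."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    defaulted: list[str] = []
    inputs: dict[str, str] = {}

    # stage 1: causal maps
    maps_path = _require(config.maps_path, "merge-maps")
    inputs["maps"] = _sha256(maps_path)
    try:
        maps = read_concept_maps(maps_path)
        if config.synonyms_path is not None:
            synonyms_path = _require(config.synonyms_path, "merge-maps")
            inputs["synonyms"] = _sha256(synonyms_path)
            synonyms = read_synonym_table(synonyms_path)
            maps = [harmonize(m, synonyms) for m in maps]
        else:
            defaulted.append("no synonym table: labels taken as already canonical")
        combined = merge_maps(maps)
        summary = summarize(combined)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("merge-maps", str(exc)) from exc

    to_graphml(combined, out / "combined.graphml")
    to_dot(combined, out / "combined.dot")
    to_adjacency(combined, "max_strength").to_csv(out / "adjacency.csv")
    degree_table(combined).to_csv(out / "degrees.csv", index=False)

    # stage 2: Bayesian network
    model_path = _require(config.model_path, "build-bn")
    inputs["model"] = _sha256(model_path)
    violations = validate_model_file(model_path)
    if violations:
        raise PipelineError("build-bn", "; ".join(violations))
    network = read_model_file(model_path)

    # stage 3: scenarios
    scenarios_path = _require(config.scenarios_path, "scenarios")
    inputs["scenarios"] = _sha256(scenarios_path)
    try:
        scenarios = read_scenario_file(scenarios_path)
        policy = None
        if config.policy == "uniform":
            from .bn_core import uniform_policy

            policy = uniform_policy(network)
            defaulted.append("unset decision variables resolved by uniform policy")
        table = compare_scenarios(network, scenarios, policy=policy)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("scenarios", str(exc)) from exc
    table.to_csv(out / "scenario_posteriors.csv", index=False)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "policy": config.policy,
        "inputs": inputs,
        "combined_map": {
            "n_nodes": summary["n_nodes"],
            "n_edges": summary["n_edges"],
            "per_category": summary["per_category"],
        },
        "network": {
            "n_variables": len(network.variables),
            "decision_variables": list(network.decision_variables),
        },
        "scenarios": [s.name for s in scenarios],
        "defaulted_decisions": defaulted,
        "artifacts": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
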