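"""Mining-scenario evaluation: posterior mortality per functional group,
scenario comparison, and stressor ranking.

A scenario is an assignment of states to the operator-controlled decision
variables (mining intensity, depth of extracted sediment, processing return
technique) plus optional evidence on random variables (e.g. contaminant
release observed significant).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .bn_core import (
    ModelError,
    Network,
    Posterior,
    most_probable_state,
    posterior,
    uniform_policy,
)
from .mortality import DEFAULT_SCHEME, MortalityClassScheme

logger = logging.getLogger(__name__)

__all__ = [
    "Scenario",
    "ScenarioResult",
    "StressorReport",
    "run_scenario",
    "compare_scenarios",
    "rank_stressors",
    "expected_mortality",
    "read_scenario_file",
    "write_scenario_file",
    "mortality_nodes",
]

TOTAL_PREFIX = "total mortality"
INDIRECT_PREFIX = "indirect mortality"
DIRECT_PREFIX = "direct mortality"


@dataclass(frozen=True)
class Scenario:
    """One mining operation: decision assignments plus optional evidence."""

    name: str
    decisions: Mapping[str, str] = field(default_factory=dict)
    evidence: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "decisions", dict(self.decisions))
        object.__setattr__(self, "evidence", dict(self.evidence))
        overlap = set(self.decisions) & set(self.evidence)
        if overlap:
            raise ModelError(f"scenario {self.name!r}: {sorted(overlap)} appear both as decision and evidence")

    def combined_evidence(self) -> dict[str, str]:
        return {**self.decisions, **self.evidence}

    def fingerprint(self) -> str:
        payload = json.dumps(
            {"decisions": dict(sorted(self.decisions.items())),
             "evidence": dict(sorted(self.evidence.items()))},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class ScenarioResult:
    scenario: Scenario
    posteriors: Mapping[tuple[str, str], Posterior]  # (group, kind) -> posterior
    fingerprint: str

    def most_probable(self, group: str, kind: str = "total") -> tuple[str, float, bool]:
        return most_probable_state(self.posteriors[(group, kind)])


@dataclass(frozen=True)
class StressorReport:
    target: str
    table: pd.DataFrame        # stressor, state, expected mortality, probabilities
    ranking: pd.DataFrame      # stressor, effect_size, tv_distance, descending
    sweep: pd.DataFrame | None = None


def mortality_nodes(network: Network) -> dict[tuple[str, str], str]:
    """Locate mortality nodes by naming convention:
    '<kind> mortality <group>' with kind in {total, indirect, direct}."""
    found: dict[tuple[str, str], str] = {}
    for name in network.variables:
        for kind, prefix in (("total", TOTAL_PREFIX), ("indirect", INDIRECT_PREFIX), ("direct", DIRECT_PREFIX)):
            if name.startswith(prefix + " "):
                found[(name[len(prefix) + 1 :], kind)] = name
    return found


def _validate_scenario(network: Network, scenario: Scenario) -> None:
    for var, state in scenario.combined_evidence().items():
        if var not in network.specs:
            raise ModelError(f"scenario {scenario.name!r} names undeclared variable {var!r}")
        network.specs[var].state_index(state)
    for var in scenario.decisions:
        if network.specs[var].node_kind != "decision":
            raise ModelError(f"scenario {scenario.name!r}: {var!r} is not a decision variable")


def run_scenario(
    network: Network,
    scenario: Scenario,
    policy: Mapping | None = None,
    kinds: Sequence[str] = ("total", "indirect"),
) -> ScenarioResult:
    """Posterior mortality distributions per functional group under a scenario.

    Decision variables not assigned by the scenario fall back to the supplied
    policy, or to a logged uniform default.
    """
    _validate_scenario(network, scenario)
    evidence = scenario.combined_evidence()
    unset = [d for d in network.decision_variables if d not in evidence]
    if unset and policy is None:
        policy = uniform_policy(network)
        logger.warning("scenario %r: decisions %s defaulted to uniform policy", scenario.name, unset)

    nodes = mortality_nodes(network)
    wanted = {(g, k): n for (g, k), n in nodes.items() if k in kinds}
    if not wanted:
        raise ModelError("network has no mortality nodes matching the naming convention")
    posteriors = {
        key: posterior(network, node, evidence=evidence, policy=policy)
        for key, node in sorted(wanted.items())
    }
    return ScenarioResult(scenario=scenario, posteriors=posteriors, fingerprint=scenario.fingerprint())


def compare_scenarios(
    network: Network,
    scenarios: Sequence[Scenario],
    policy: Mapping | None = None,
    kinds: Sequence[str] = ("total", "indirect"),
) -> pd.DataFrame:
    """Long-format table: one row per (scenario, group, kind, class)."""
    if not scenarios:
        raise ModelError("need at least one scenario")
    names = [s.name for s in scenarios]
    if len(set(names)) != len(names):
        raise ModelError(f"duplicate scenario names: {sorted(n for n in names if names.count(n) > 1)}")
    rows = []
    for scenario in scenarios:
        result = run_scenario(network, scenario, policy=policy, kinds=kinds)
        for (group, kind), post in result.posteriors.items():
            for state, prob in zip(post.states, post.probabilities):
                rows.append(
                    {
                        "scenario": scenario.name,
                        "group": group,
                        "kind": kind,
                        "class": state,
                        "probability": float(prob),
                        "fingerprint": result.fingerprint,
                    }
                )
    return pd.DataFrame(rows)


def expected_mortality(
    class_dist: Sequence[float],
    scheme: MortalityClassScheme = DEFAULT_SCHEME,
) -> float:
    """Class-midpoint expectation of a mortality class distribution, in percent."""
    p = np.asarray(class_dist, dtype=float)
    if p.size != scheme.n_classes:
        raise ModelError(f"expected {scheme.n_classes} class masses, got {p.size}")
    return float(np.dot(p, scheme.midpoints))


def rank_stressors(
    network: Network,
    target: str,
    stressors: Sequence[str],
    baseline: Scenario,
    policy: Mapping | None = None,
    scheme: MortalityClassScheme = DEFAULT_SCHEME,
    sweep: bool = False,
) -> StressorReport:
    """Rank stressors by the spread of expected target mortality across their
    states, holding the baseline scenario elsewhere.

    Effect size is the difference in class-midpoint expected mortality between
    the extreme (best/worst) states; the total-variation distance between the
    extreme-state posteriors is reported alongside.  Stressors that are not
    ancestors of the target get a warning and effect 0.
    """
    if target not in network.specs:
        raise ModelError(f"unknown target {target!r}")
    _validate_scenario(network, baseline)
    g = network.graph()
    ancestors = nx.ancestors(g, target)
    base_evidence = baseline.combined_evidence()
    unset = [d for d in network.decision_variables if d not in base_evidence]
    if unset and policy is None:
        policy = uniform_policy(network)

    table_rows = []
    rank_rows = []
    for stressor in stressors:
        if stressor not in network.specs:
            raise ModelError(f"unknown stressor {stressor!r}")
        if stressor not in ancestors:
            logger.warning("stressor %r is not an ancestor of %r; effect is 0", stressor, target)
        states = network.specs[stressor].states
        expectations = []
        dists = []
        for state in states:
            evidence = dict(base_evidence)
            evidence[stressor] = state
            post = posterior(network, target, evidence=evidence, policy=policy)
            e = expected_mortality(post.probabilities, scheme)
            expectations.append(e)
            dists.append(post.probabilities)
            table_rows.append(
                {"stressor": stressor, "state": state, "expected_mortality": e,
                 **{f"p({s})": float(p) for s, p in zip(post.states, post.probabilities)}}
            )
        lo, hi = int(np.argmin(expectations)), int(np.argmax(expectations))
        rank_rows.append(
            {
                "stressor": stressor,
                "effect_size": float(expectations[hi] - expectations[lo]),
                "tv_distance": float(0.5 * np.abs(dists[hi] - dists[lo]).sum()),
                "best_state": states[lo],
                "worst_state": states[hi],
            }
        )
    ranking = (
        pd.DataFrame(rank_rows)
        .sort_values(["effect_size", "stressor"], ascending=[False, True])
        .reset_index(drop=True)
    )

    sweep_df = None
    if sweep:
        import itertools

        state_lists = [network.specs[s].states for s in stressors]
        sweep_records = []
        for combo in itertools.product(*state_lists):
            evidence = dict(base_evidence)
            evidence.update(dict(zip(stressors, combo)))
            post = posterior(network, target, evidence=evidence, policy=policy)
            rec = dict(zip(stressors, combo))
            rec["expected_mortality"] = expected_mortality(post.probabilities, scheme)
            rec.update({f"p({s})": float(p) for s, p in zip(post.states, post.probabilities)})
            sweep_records.append(rec)
        sweep_df = pd.DataFrame(sweep_records)

    return StressorReport(
        target=target,
        table=pd.DataFrame(table_rows),
        ranking=ranking,
        sweep=sweep_df,
    )


# ---------------------------------------------------------------------------
# scenario file I/O

def read_scenario_file(path: str | Path) -> list[Scenario]:
    doc = yaml.safe_load(Path(path).read_text())
    return [
        Scenario(
            name=s["name"],
            decisions=s.get("decisions", {}),
            evidence=s.get("evidence", {}),
        )
        for s in doc.get("scenarios", [])
    ]


def write_scenario_file(scenarios: Sequence[Scenario], path: str | Path) -> None:
    doc = {
        "scenarios": [
            {"name": s.name, "decisions": dict(s.decisions), "evidence": dict(s.evidence)}
            for s in scenarios
        ]
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
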