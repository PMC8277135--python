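"""Synthetic generators: expert causal maps drawn from a hidden consensus
graph, the default 18-node mortality network with generated CPTs, and full
factorial scenario suites.  Everything is reproducible from a seed so the
whole pipeline is testable without external downloads.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import fixtures
from .bn_core import CPT, Network, VariableSpec, build_network, write_model_file
from .causal_map import CombinedNetwork, ConceptMap, Link
from .cpt_elicitation import InfluenceRanking, ParentInfluence, initialize_cpt, random_cpt
from .mortality import (
    DEFAULT_SCHEME,
    build_total_mortality_cpt,
    direct_mortality_from_intensity,
    grid_to_class,
)
from .scenario_engine import Scenario, write_scenario_file

__all__ = [
    "SyntheticConfig",
    "generate_expert_maps",
    "generate_network",
    "generate_scenarios",
    "default_variable_specs",
    "FUNCTIONAL_GROUPS",
    "INTENSITY_STATES",
    "make_fixture_workspace",
]

FUNCTIONAL_GROUPS = ("infauna", "mobile epifauna", "sessile epifauna")
INTENSITY_STATES = ("50% removed", "75% removed", "100% removed")
_INTENSITY_PERCENT = {"50% removed": 50, "75% removed": 75, "100% removed": 100}
DEPTH_STATES = ("<10 cm", "11-30 cm", ">30 cm")
RETURN_STATES = ("at the surface", "at the bottom")
LEVEL3 = ("low", "medium", "high")


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    n_experts: int = 11
    map_size_range: tuple[int, int] = (8, 24)
    link_inclusion: float = 0.7
    noise_rate: float = 0.0
    strength_probs: tuple[float, float, float] = (0.3, 0.4, 0.3)
    missing_strength_rate: float = 0.4
    cpt_concentration: float = 1.0
    monotone: bool = True
    direct_dispersion: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.map_size_range
        if not 2 <= lo <= hi:
            raise ValueError(f"bad map size range {self.map_size_range}")
        for p in (self.link_inclusion, self.noise_rate, self.missing_strength_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.strength_probs) - 1.0) > 1e-9:
            raise ValueError("strength_probs must sum to 1")


# ---------------------------------------------------------------------------
# expert causal maps from a hidden consensus graph

def generate_expert_maps(
    config: SyntheticConfig,
    truth: CombinedNetwork | None = None,
) -> list[ConceptMap]:
    """Draw per-expert maps as grown connected subgraphs of a hidden consensus
    network (default: the packaged combined fixture) plus optional noise links.

    The connecting edge used at each growth step is always included, so every
    sampled node appears in at least one link and the map size equals the
    sampled target.
    """
    if truth is None:
        truth = fixtures.load_combined()
    rng = np.random.default_rng(config.seed)
    directed = set(truth.edges)
    neighbors: dict[str, set[str]] = {n: set() for n in truth.nodes}
    for s, t in directed:
        neighbors[s].add(t)
        neighbors[t].add(s)

    lo, hi = config.map_size_range
    if hi > len(truth.nodes):
        raise ValueError("map size range exceeds the hidden network's node count")
    all_nodes = sorted(truth.nodes)
    maps = []
    for e in range(config.n_experts):
        target = int(rng.integers(lo, hi + 1))
        start = all_nodes[int(rng.integers(len(all_nodes)))]
        chosen = [start]
        chosen_set = {start}
        links: set[tuple[str, str]] = set()
        while len(chosen) < target:
            frontier = sorted(
                {(u, v) for u in chosen for v in neighbors[u] if v not in chosen_set}
            )
            if not frontier:  # isolated pocket; hop to a fresh node (truth is connected)
                rest = [n for n in all_nodes if n not in chosen_set]
                chosen.append(rest[int(rng.integers(len(rest)))])
                chosen_set.add(chosen[-1])
                continue
            u, v = frontier[int(rng.integers(len(frontier)))]
            chosen.append(v)
            chosen_set.add(v)
            links.add((u, v) if (u, v) in directed else (v, u))
        # induced truth edges beyond the growth tree, thinned by link_inclusion
        for s, t in sorted(directed):
            if s in chosen_set and t in chosen_set and (s, t) not in links:
                if rng.random() < config.link_inclusion:
                    links.add((s, t))
        # noise links absent from the hidden truth
        n_noise = int(round(config.noise_rate * len(links)))
        attempts = 0
        while n_noise > 0 and attempts < 100 * n_noise:
            attempts += 1
            s, t = rng.choice(chosen, size=2, replace=False)
            if s != t and (s, t) not in directed and (t, s) not in directed and (s, t) not in links:
                links.add((s, t))
                n_noise -= 1
        strength_of = {}
        for link in sorted(links):
            if rng.random() < config.missing_strength_rate:
                strength_of[link] = None
            else:
                strength_of[link] = int(rng.choice([1, 2, 3], p=config.strength_probs))
        maps.append(
            ConceptMap(
                expert_id=f"SYN{e + 1:02d}",
                nodes=frozenset(chosen_set),
                links=frozenset(Link(s, t, strength_of[(s, t)]) for s, t in links),
            )
        )
    return maps


# ---------------------------------------------------------------------------
# the 18-node quantitative network

def default_variable_specs() -> list[VariableSpec]:
    """Default structure: 3 decision + 6 random process variables + 3 mortality
    nodes (direct, indirect, total) per functional group = 18 variables."""
    scheme = DEFAULT_SCHEME
    specs = [
        VariableSpec("mining intensity", INTENSITY_STATES, "decision", "extraction technique"),
        VariableSpec("depth of extracted sediment", DEPTH_STATES, "decision", "extraction technique"),
        VariableSpec("processing return technique", RETURN_STATES, "decision", "extraction technique"),
        VariableSpec("volume of extraction", LEVEL3, "random", "extraction technique"),
        VariableSpec("sediment type", ("soft", "hard", "rocks"), "random", "environmental condition"),
        VariableSpec("contaminants in sediment", LEVEL3, "random", "environmental condition"),
        VariableSpec("suspended sediment", LEVEL3, "random", "environmental change"),
        VariableSpec("sediment deposition", LEVEL3, "random", "environmental change"),
        VariableSpec("contaminant release", ("low", "significant"), "random", "environmental change"),
    ]
    for group in FUNCTIONAL_GROUPS:
        for kind in ("direct", "indirect", "total"):
            specs.append(
                VariableSpec(
                    f"{kind} mortality {group}", scheme.labels, "random", "affected functional group"
                )
            )
    return specs


def _direct_mortality_cpt(child: str, dispersion: int) -> CPT:
    rows = [
        grid_to_class(direct_mortality_from_intensity(_INTENSITY_PERCENT[s], dispersion))
        for s in INTENSITY_STATES
    ]
    return CPT(child=child, parents=("mining intensity",), table=np.array(rows))


#: per-group weights for the pressure -> indirect-mortality rankings
#: (suspended sediment, sediment deposition, contaminant release); mobile
#: fauna can partly escape, so physical pressures weigh less for them
_INDIRECT_WEIGHTS = {
    "sessile epifauna": (1.0, 1.0, 1.2),
    "infauna": (0.7, 1.0, 1.2),
    "mobile epifauna": (0.5, 0.5, 1.2),
}


def _monotone_cpts(specs: dict[str, VariableSpec], dispersion: int) -> list[CPT]:
    cpts: list[CPT] = [
        CPT("sediment type", (), np.array([0.5, 0.3, 0.2])),
        CPT("contaminants in sediment", (), np.array([0.4, 0.4, 0.2])),
    ]
    cpts.append(
        initialize_cpt(
            specs["volume of extraction"],
            [specs["mining intensity"], specs["depth of extracted sediment"]],
            InfluenceRanking(
                "volume of extraction",
                {
                    "mining intensity": ParentInfluence(weight=1.0, direction=1),
                    "depth of extracted sediment": ParentInfluence(weight=1.0, direction=1),
                },
                spread=0.8,
            ),
        )
    )
    return_offsets = {"at the surface": -0.25, "at the bottom": 0.25}
    for child, spread in (("suspended sediment", 0.9), ("sediment deposition", 0.9)):
        cpts.append(
            initialize_cpt(
                specs[child],
                [specs["volume of extraction"], specs["sediment type"], specs["processing return technique"]],
                InfluenceRanking(
                    child,
                    {
                        "volume of extraction": ParentInfluence(weight=1.0, direction=1),
                        # softer sediment disperses more readily
                        "sediment type": ParentInfluence(weight=0.5, direction=-1),
                        "processing return technique": ParentInfluence(weight=0.5, offsets=return_offsets),
                    },
                    spread=spread,
                ),
            )
        )
    cpts.append(
        initialize_cpt(
            specs["contaminant release"],
            [specs["contaminants in sediment"], specs["suspended sediment"]],
            InfluenceRanking(
                "contaminant release",
                {
                    "contaminants in sediment": ParentInfluence(weight=1.0, direction=1),
                    "suspended sediment": ParentInfluence(weight=0.6, direction=1),
                },
                spread=0.8,
            ),
        )
    )
    for group in FUNCTIONAL_GROUPS:
        cpts.append(_direct_mortality_cpt(f"direct mortality {group}", dispersion))
        w_ss, w_sd, w_cr = _INDIRECT_WEIGHTS[group]
        cpts.append(
            initialize_cpt(
                specs[f"indirect mortality {group}"],
                [specs["suspended sediment"], specs["sediment deposition"], specs["contaminant release"]],
                InfluenceRanking(
                    f"indirect mortality {group}",
                    {
                        "suspended sediment": ParentInfluence(weight=w_ss, direction=1),
                        "sediment deposition": ParentInfluence(weight=w_sd, direction=1),
                        "contaminant release": ParentInfluence(weight=w_cr, direction=1),
                    },
                    spread=1.0,
                ),
            )
        )
        cpts.append(
            build_total_mortality_cpt(
                f"total mortality {group}",
                specs[f"direct mortality {group}"],
                specs[f"indirect mortality {group}"],
            )
        )
    return cpts


def _random_cpts(specs: dict[str, VariableSpec], config: SyntheticConfig, rng: np.random.Generator) -> list[CPT]:
    parents_of = {
        "sediment type": (),
        "contaminants in sediment": (),
        "volume of extraction": ("mining intensity", "depth of extracted sediment"),
        "suspended sediment": ("volume of extraction", "sediment type", "processing return technique"),
        "sediment deposition": ("volume of extraction", "sediment type", "processing return technique"),
        "contaminant release": ("contaminants in sediment", "suspended sediment"),
    }
    for group in FUNCTIONAL_GROUPS:
        parents_of[f"indirect mortality {group}"] = (
            "suspended sediment", "sediment deposition", "contaminant release",
        )
    cpts = []
    for child, parents in parents_of.items():
        cpts.append(
            random_cpt(
                specs[child],
                [specs[p] for p in parents],
                rng,
                concentration=config.cpt_concentration,
                monotone=False,
            )
        )
    for group in FUNCTIONAL_GROUPS:
        cpts.append(_direct_mortality_cpt(f"direct mortality {group}", config.direct_dispersion))
        cpts.append(
            build_total_mortality_cpt(
                f"total mortality {group}",
                specs[f"direct mortality {group}"],
                specs[f"indirect mortality {group}"],
            )
        )
    return cpts


def generate_network(config: SyntheticConfig) -> Network:
    """The default 18-node network with generated CPTs.

    With ``monotone`` the process and indirect-mortality CPTs come from
    positive-direction influence rankings (higher pressure states push
    mortality upward); otherwise they are seeded Dirichlet draws.  Direct
    mortality is always proportional to mining intensity and total mortality
    is always the deterministic grid combination.
    """
    spec_list = default_variable_specs()
    specs = {s.name: s for s in spec_list}
    if config.monotone:
        cpts = _monotone_cpts(specs, config.direct_dispersion)
    else:
        rng = np.random.default_rng(config.seed)
        cpts = _random_cpts(specs, config, rng)
    return build_network(spec_list, cpts)


def generate_scenarios(
    network: Network,
    fixed: dict[str, str] | None = None,
) -> list[Scenario]:
    """Full factorial suite over the decision variables (18 scenarios with the
    default network); ``fixed`` pins chosen decisions and shrinks the grid."""
    fixed = dict(fixed or {})
    free = [d for d in sorted(network.decision_variables) if d not in fixed]
    for var, state in fixed.items():
        network.specs[var].state_index(state)
    scenarios = []
    for i, combo in enumerate(itertools.product(*(network.specs[d].states for d in free)), start=1):
        decisions = dict(fixed)
        decisions.update(dict(zip(free, combo)))
        scenarios.append(Scenario(name=f"S{i:02d}", decisions=decisions))
    return scenarios


def make_fixture_workspace(directory: str | Path, config: SyntheticConfig) -> dict[str, Path]:
    """Materialize a complete test workspace: synthetic expert maps, the
    packaged synonym table, a generated model file, and a scenario suite."""
    from .causal_map import write_concept_maps

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "maps": directory / "expert_maps.csv",
        "synonyms": directory / "synonyms.csv",
        "model": directory / "model.yaml",
        "scenarios": directory / "scenarios.yaml",
    }
    write_concept_maps(generate_expert_maps(config), paths["maps"])
    paths["synonyms"].write_text(fixtures.fixture_path("synonyms.csv").read_text())
    network = generate_network(config)
    write_model_file(network, paths["model"])
    write_scenario_file(generate_scenarios(network), paths["scenarios"])
    return paths
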