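"""Discrete Bayesian network with decision and random nodes, exact inference.

The network couples operator-controlled decision variables (no prior) with
expert-elicited random variables carrying conditional probability tables.
Queries are answered exactly by variable elimination; decision variables must
be fixed by evidence or covered by an explicit policy.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "VariableSpec",
    "CPT",
    "Network",
    "Posterior",
    "ModelError",
    "CycleError",
    "ContradictoryEvidenceError",
    "build_network",
    "joint_probability",
    "posterior",
    "most_probable_state",
    "read_model_file",
    "write_model_file",
    "read_cpt_table",
    "write_cpt_table",
    "posterior_table",
]

PROB_TOL = 1e-9

VARIABLE_CATEGORIES = (
    "environmental condition",
    "extraction technique",
    "environmental change",
    "affected functional group",
)


class ModelError(ValueError):
    """A structural defect in the network definition."""


class CycleError(ModelError):
    """The implied graph is not acyclic."""


class ContradictoryEvidenceError(ValueError):
    """Evidence has zero marginal likelihood under the model."""


@dataclass(frozen=True)
class VariableSpec:
    """A discrete variable: ordered states, decision/random role, category tag."""

    name: str
    states: tuple[str, ...]
    node_kind: str = "random"
    category: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        if len(self.states) < 2:
            raise ModelError(f"variable {self.name!r} needs >=2 states")
        if len(set(self.states)) != len(self.states):
            raise ModelError(f"variable {self.name!r} has duplicate state labels")
        if self.node_kind not in ("random", "decision"):
            raise ModelError(f"variable {self.name!r}: node_kind must be 'random' or 'decision'")

    @property
    def cardinality(self) -> int:
        return len(self.states)

    def state_index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise ModelError(f"{state!r} is not a state of {self.name!r} (states: {self.states})") from None


@dataclass(frozen=True)
class CPT:
    """Conditional probability table: one distribution over the child's states
    for every full combination of parent states.

    ``table`` has one axis per parent (in ``parents`` order) and a final axis
    over child states.
    """

    child: str
    parents: tuple[str, ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "parents", tuple(self.parents))
        t = np.asarray(self.table, dtype=float)
        if t.ndim != len(self.parents) + 1:
            raise ModelError(
                f"CPT for {self.child!r}: table has {t.ndim} axes, expected {len(self.parents) + 1}"
            )
        object.__setattr__(self, "table", t)

    def validate(self, tol: float = PROB_TOL) -> None:
        if (self.table < 0).any():
            raise ModelError(f"CPT for {self.child!r} has negative entries")
        sums = np.atleast_1d(self.table.sum(axis=-1))
        bad = np.argwhere(np.abs(sums - 1.0) > tol)
        if bad.size:
            idx = tuple(int(i) for i in bad[0])
            raise ModelError(
                f"CPT for {self.child!r}: row at parent index {idx} sums to {sums[idx]!r}, not 1"
            )

    def row(self, parent_states: Sequence[int]) -> np.ndarray:
        return self.table[tuple(parent_states)]

    def renormalized(self) -> "CPT":
        sums = self.table.sum(axis=-1, keepdims=True)
        if (sums <= 0).any():
            raise ModelError(f"CPT for {self.child!r}: cannot renormalize an all-zero row")
        logger.warning("renormalizing CPT rows for %r on explicit request", self.child)
        return replace(self, table=self.table / sums)


@dataclass(frozen=True)
class Posterior:
    """Exact posterior of one variable given evidence and a decision policy."""

    variable: str
    states: tuple[str, ...]
    probabilities: np.ndarray
    evidence: tuple[tuple[str, str], ...]
    policy_note: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if abs(p.sum() - 1.0) > PROB_TOL:
            raise ValueError(f"posterior for {self.variable!r} sums to {p.sum()!r}")
        object.__setattr__(self, "probabilities", p)
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "evidence", tuple(self.evidence))

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.states, self.probabilities.tolist()))


@dataclass(frozen=True)
class Network:
    """Validated discrete BN: variable specs plus one CPT per random variable."""

    specs: Mapping[str, VariableSpec]
    cpts: Mapping[str, CPT]

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.specs)

    @property
    def decision_variables(self) -> tuple[str, ...]:
        return tuple(n for n, s in self.specs.items() if s.node_kind == "decision")

    @property
    def random_variables(self) -> tuple[str, ...]:
        return tuple(n for n, s in self.specs.items() if s.node_kind == "random")

    def parents(self, name: str) -> tuple[str, ...]:
        cpt = self.cpts.get(name)
        return cpt.parents if cpt is not None else ()

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.specs)
        for cpt in self.cpts.values():
            for p in cpt.parents:
                g.add_edge(p, cpt.child)
        return g


def build_network(specs: Iterable[VariableSpec], cpts: Iterable[CPT]) -> Network:
    """Assemble and fully validate a network (acyclicity, CPT coverage, row sums)."""
    spec_map = {s.name: s for s in specs}
    cpt_map: dict[str, CPT] = {}
    for cpt in cpts:
        if cpt.child not in spec_map:
            raise ModelError(f"CPT child {cpt.child!r} is not a declared variable")
        if cpt.child in cpt_map:
            raise ModelError(f"duplicate CPT for {cpt.child!r}")
        cpt_map[cpt.child] = cpt

    for name, cpt in cpt_map.items():
        spec = spec_map[name]
        if spec.node_kind == "decision":
            raise ModelError(f"decision variable {name!r} must not carry a CPT")
        for p in cpt.parents:
            if p not in spec_map:
                raise ModelError(f"CPT for {name!r} references undeclared parent {p!r}")
        expected = tuple(spec_map[p].cardinality for p in cpt.parents) + (spec.cardinality,)
        if cpt.table.shape != expected:
            raise ModelError(
                f"CPT for {name!r}: table shape {cpt.table.shape} does not match "
                f"parent/child cardinalities {expected} (missing or extra rows)"
            )
        cpt.validate()

    for name, spec in spec_map.items():
        if spec.node_kind == "random" and name not in cpt_map:
            raise ModelError(f"random variable {name!r} has no CPT")

    net = Network(specs=spec_map, cpts=cpt_map)
    g = net.graph()
    try:
        cycle = nx.find_cycle(g, orientation="original")
    except nx.NetworkXNoCycle:
        pass
    else:
        path = " -> ".join(e[0] for e in cycle) + " -> " + cycle[-1][1]
        raise CycleError(f"network contains a cycle: {path}")
    return net


# ---------------------------------------------------------------------------
# policies

Policy = Mapping[str, "str | Sequence[float]"]


def _policy_vector(spec: VariableSpec, choice: "str | Sequence[float]") -> np.ndarray:
    if isinstance(choice, str):
        vec = np.zeros(spec.cardinality)
        vec[spec.state_index(choice)] = 1.0
        return vec
    vec = np.asarray(choice, dtype=float)
    if vec.shape != (spec.cardinality,) or (vec < 0).any() or abs(vec.sum() - 1.0) > PROB_TOL:
        raise ModelError(f"invalid policy distribution for {spec.name!r}: {choice!r}")
    return vec


def _resolve_decisions(
    network: Network, evidence: Mapping[str, str], policy: Policy | None
) -> tuple[dict[str, np.ndarray], str]:
    """Every decision node must be evidenced or covered by the policy."""
    policy = dict(policy or {})
    vectors: dict[str, np.ndarray] = {}
    notes: list[str] = []
    for name in network.decision_variables:
        spec = network.specs[name]
        if name in evidence:
            continue
        if name in policy:
            vectors[name] = _policy_vector(spec, policy[name])
            notes.append(f"policy({name})")
        else:
            raise ModelError(
                f"decision variable {name!r} is neither evidenced nor covered by a policy"
            )
    return vectors, "; ".join(notes)


def uniform_policy(network: Network) -> dict[str, np.ndarray]:
    """Uniform distribution over every decision variable (logged default)."""
    logger.warning(
        "defaulting to a uniform policy over decision variables %s",
        list(network.decision_variables),
    )
    return {
        n: np.full(network.specs[n].cardinality, 1.0 / network.specs[n].cardinality)
        for n in network.decision_variables
    }


# ---------------------------------------------------------------------------
# exact inference

@dataclass
class _Factor:
    variables: tuple[str, ...]
    values: np.ndarray


def _expand(f: _Factor, union: Sequence[str], cards: Mapping[str, int]) -> np.ndarray:
    """Broadcast a factor's array into the axis order of `union`."""
    order = [f.variables.index(v) for v in union if v in f.variables]
    arr = np.transpose(f.values, order)
    shape = [cards[v] if v in f.variables else 1 for v in union]
    return arr.reshape(shape)


def _multiply(factors: Sequence[_Factor], cards: Mapping[str, int]) -> _Factor:
    union: list[str] = []
    for f in factors:
        for v in f.variables:
            if v not in union:
                union.append(v)
    values = np.ones([cards[v] for v in union])
    for f in factors:
        values = values * _expand(f, union, cards)
    return _Factor(tuple(union), values)


def _sum_out(f: _Factor, var: str) -> _Factor:
    ax = f.variables.index(var)
    return _Factor(
        tuple(v for v in f.variables if v != var),
        f.values.sum(axis=ax),
    )


def _network_factors(
    network: Network,
    evidence: Mapping[str, str],
    policy_vectors: Mapping[str, np.ndarray],
) -> list[_Factor]:
    factors: list[_Factor] = []
    for name in network.random_variables:
        cpt = network.cpts[name]
        factors.append(_Factor(cpt.parents + (name,), cpt.table))
    for name, vec in policy_vectors.items():
        factors.append(_Factor((name,), np.asarray(vec, dtype=float)))
    for name, state in evidence.items():
        spec = network.specs[name]
        ind = np.zeros(spec.cardinality)
        ind[spec.state_index(state)] = 1.0
        factors.append(_Factor((name,), ind))
    return factors


def _elimination_order(network: Network, keep: set[str], order: Sequence[str] | None) -> list[str]:
    if order is not None:
        missing = set(network.variables) - keep - set(order)
        if missing:
            raise ModelError(f"elimination order omits variables: {sorted(missing)}")
        return [v for v in order if v not in keep]
    # min-degree greedy on the moralized graph; networks here are small
    g = nx.moral_graph(network.graph())
    out: list[str] = []
    remaining = set(network.variables) - keep
    while remaining:
        v = min(remaining, key=lambda n: (g.degree(n), n))
        nbrs = [u for u in g.neighbors(v) if u != v]
        g.add_edges_from((a, b) for a in nbrs for b in nbrs if a != b)
        g.remove_node(v)
        remaining.discard(v)
        out.append(v)
    return out


def _validate_evidence(network: Network, evidence: Mapping[str, str]) -> None:
    for name, state in evidence.items():
        if name not in network.specs:
            raise ModelError(f"evidence names undeclared variable {name!r}")
        network.specs[name].state_index(state)


def joint_probability(
    network: Network,
    assignment: Mapping[str, str],
    policy: Policy | None = None,
) -> float:
    """Chain-rule probability of one full state assignment.

    Decision variables take the mass the policy gives their assigned state;
    without a policy entry the assignment itself is treated as the decision
    (mass 1).
    """
    missing = set(network.variables) - set(assignment)
    if missing:
        raise ModelError(f"assignment does not cover variables: {sorted(missing)}")
    _validate_evidence(network, assignment)
    policy = dict(policy or {})
    prob = 1.0
    for name in network.variables:
        spec = network.specs[name]
        idx = spec.state_index(assignment[name])
        if spec.node_kind == "decision":
            if name in policy:
                prob *= float(_policy_vector(spec, policy[name])[idx])
        else:
            cpt = network.cpts[name]
            parent_idx = tuple(
                network.specs[p].state_index(assignment[p]) for p in cpt.parents
            )
            prob *= float(cpt.table[parent_idx + (idx,)])
    return prob


def posterior(
    network: Network,
    query: str,
    evidence: Mapping[str, str] | None = None,
    policy: Policy | None = None,
    elimination_order: Sequence[str] | None = None,
) -> Posterior:
    """Exact posterior of `query` given evidence, by variable elimination."""
    evidence = dict(evidence or {})
    if query not in network.specs:
        raise ModelError(f"unknown query variable {query!r}")
    _validate_evidence(network, evidence)
    policy_vectors, note = _resolve_decisions(network, evidence, policy)

    cards = {n: s.cardinality for n, s in network.specs.items()}
    factors = _network_factors(network, evidence, policy_vectors)
    for var in _elimination_order(network, {query}, elimination_order):
        involved = [f for f in factors if var in f.variables]
        rest = [f for f in factors if var not in f.variables]
        if involved:
            rest.append(_sum_out(_multiply(involved, cards), var))
        factors = rest
    final = _multiply(factors, cards)
    if final.variables != (query,):
        ax = final.variables.index(query)
        values = final.values.sum(axis=tuple(i for i in range(final.values.ndim) if i != ax))
    else:
        values = final.values
    mass = values.sum()
    if mass <= PROB_TOL:
        raise ContradictoryEvidenceError(
            f"evidence {evidence!r} has zero marginal likelihood"
        )
    return Posterior(
        variable=query,
        states=network.specs[query].states,
        probabilities=values / mass,
        evidence=tuple(sorted(evidence.items())),
        policy_note=note,
    )


def most_probable_state(post: Posterior) -> tuple[str, float, bool]:
    """Argmax state of a posterior; ties break toward the earlier-ordered state.

    Returns ``(state, probability, tied)``.
    """
    p = post.probabilities
    best = int(np.argmax(p))
    tied = bool(np.sum(np.isclose(p, p[best], rtol=0.0, atol=PROB_TOL)) > 1)
    if tied:
        logger.info("posterior for %r has tied modes; reporting the earlier-ordered state", post.variable)
    return post.states[best], float(p[best]), tied


# ---------------------------------------------------------------------------
# model file I/O (YAML, deterministic layout, bit-exact round trip)

def _cpt_to_rows(network_specs: Mapping[str, VariableSpec], cpt: CPT) -> list[dict]:
    parent_states = [network_specs[p].states for p in cpt.parents]
    rows = []
    for combo in itertools.product(*(range(len(s)) for s in parent_states)):
        rows.append(
            {
                "given": [parent_states[i][j] for i, j in enumerate(combo)],
                "p": [float(x) for x in cpt.table[combo]],
            }
        )
    return rows


def write_model_file(network: Network, path: str | Path) -> None:
    doc = {
        "variables": [
            {
                "name": s.name,
                "category": s.category,
                "kind": s.node_kind,
                "states": list(s.states),
            }
            for s in network.specs.values()
        ],
        "cpts": [
            {
                "child": cpt.child,
                "parents": list(cpt.parents),
                "rows": _cpt_to_rows(network.specs, cpt),
            }
            for cpt in network.cpts.values()
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False, default_flow_style=None))


def read_model_file(path: str | Path) -> Network:
    doc = yaml.safe_load(Path(path).read_text())
    specs = [
        VariableSpec(
            name=v["name"],
            states=tuple(v["states"]),
            node_kind=v.get("kind", "random"),
            category=v.get("category", ""),
        )
        for v in doc.get("variables", [])
    ]
    spec_map = {s.name: s for s in specs}
    cpts = []
    for c in doc.get("cpts", []):
        child = c["child"]
        parents = tuple(c.get("parents", []))
        if child not in spec_map:
            raise ModelError(f"CPT child {child!r} is not a declared variable")
        for p in parents:
            if p not in spec_map:
                raise ModelError(f"CPT for {child!r} references undeclared parent {p!r}")
        cards = tuple(spec_map[p].cardinality for p in parents)
        table = np.zeros(cards + (spec_map[child].cardinality,))
        seen = np.zeros(cards, dtype=bool) if cards else np.zeros((), dtype=bool)
        for row in c["rows"]:
            combo = tuple(
                spec_map[p].state_index(s) for p, s in zip(parents, row.get("given", []))
            )
            table[combo] = np.asarray(row["p"], dtype=float)
            seen[combo] = True
        if not seen.all():
            first = tuple(int(i) for i in np.argwhere(~np.atleast_1d(seen))[0])
            raise ModelError(f"CPT for {child!r} is missing the row for parent index {first}")
        cpts.append(CPT(child=child, parents=parents, table=table))
    return build_network(specs, cpts)


def read_cpt_table(
    path: str | Path,
    child: str,
    specs: Mapping[str, VariableSpec],
    sep: str = ",",
) -> CPT:
    """Import a CPT stored as a delimited table: one column per parent name,
    one column per child state, one row per parent combination."""
    df = pd.read_csv(path, sep=sep)
    child_spec = specs[child]
    parents = tuple(c for c in df.columns if c not in child_spec.states)
    for p in parents:
        if p not in specs:
            raise ModelError(f"CPT table column {p!r} is neither a parent variable nor a child state")
    missing_states = [s for s in child_spec.states if s not in df.columns]
    if missing_states:
        raise ModelError(f"CPT table for {child!r} lacks state columns {missing_states}")
    cards = tuple(specs[p].cardinality for p in parents)
    table = np.zeros(cards + (child_spec.cardinality,))
    seen = np.zeros(cards, dtype=bool) if cards else np.zeros((), dtype=bool)
    for _, row in df.iterrows():
        combo = tuple(specs[p].state_index(str(row[p])) for p in parents)
        table[combo] = [float(row[s]) for s in child_spec.states]
        seen[combo] = True
    if not seen.all():
        first = tuple(int(i) for i in np.argwhere(~np.atleast_1d(seen))[0])
        raise ModelError(f"CPT table for {child!r} is missing the row for parent index {first}")
    return CPT(child=child, parents=parents, table=table)


def write_cpt_table(
    cpt: CPT, specs: Mapping[str, VariableSpec], path: str | Path, sep: str = ","
) -> None:
    child_spec = specs[cpt.child]
    parent_states = [specs[p].states for p in cpt.parents]
    records = []
    for combo in itertools.product(*(range(len(s)) for s in parent_states)):
        rec = {p: parent_states[i][j] for i, (p, j) in enumerate(zip(cpt.parents, combo))}
        rec.update(dict(zip(child_spec.states, cpt.table[combo].tolist())))
        records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, sep=sep, index=False)


def posterior_table(posteriors: Sequence[Posterior]) -> pd.DataFrame:
    """Long-format table of posteriors (variable, state, probability, evidence)."""
    rows = []
    for post in posteriors:
        fingerprint = ";".join(f"{k}={v}" for k, v in post.evidence)
        for state, prob in zip(post.states, post.probabilities):
            rows.append(
                {
                    "variable": post.variable,
                    "state": state,
                    "probability": float(prob),
                    "evidence": fingerprint,
                }
            )
    return pd.DataFrame(rows, columns=["variable", "state", "probability", "evidence"])
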