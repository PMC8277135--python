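"""Expert causal maps: reading, label harmonization, and merging.

Each expert contributes a directed graph of cause-effect beliefs with
optional 1-3 link strengths.  Labels are harmonized through a synonym table
(e.g. "polychaetes" -> "mobile infauna") and the harmonized maps are merged
into one combined network that keeps every nonredundant variable and
connection together with per-expert provenance.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Link",
    "ConceptMap",
    "SynonymTable",
    "CombinedNetwork",
    "MapFormatError",
    "read_concept_maps",
    "write_concept_maps",
    "read_synonym_table",
    "harmonize",
    "merge_maps",
    "to_adjacency",
    "from_adjacency",
    "summarize",
    "degree_table",
    "to_graphml",
    "to_dot",
]

VALID_STRENGTHS = (1, 2, 3)


class MapFormatError(ValueError):
    """A malformed causal-map record."""


@dataclass(frozen=True)
class Link:
    source: str
    target: str
    strength: int | None = None

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise MapFormatError(f"self-loop {self.source!r} -> {self.target!r}")
        if self.strength is not None and self.strength not in VALID_STRENGTHS:
            raise MapFormatError(
                f"link {self.source!r} -> {self.target!r}: strength {self.strength!r} not in 1-3"
            )


@dataclass(frozen=True)
class ConceptMap:
    """One expert's directed causal graph with optional link strengths."""

    expert_id: str
    nodes: frozenset[str]
    links: frozenset[Link]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        object.__setattr__(self, "links", frozenset(self.links))
        endpoints = {l.source for l in self.links} | {l.target for l in self.links}
        if not endpoints <= self.nodes:
            raise MapFormatError(
                f"map {self.expert_id!r}: link endpoints {sorted(endpoints - self.nodes)} "
                "missing from the node set"
            )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True)
class SynonymTable:
    """Mapping raw label -> canonical label, closed after one application."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        mapping = dict(self.mapping)
        for raw, canonical in mapping.items():
            if canonical in mapping and mapping[canonical] != canonical:
                raise MapFormatError(
                    f"synonym table is not closed: canonical {canonical!r} "
                    f"(for {raw!r}) is itself mapped to {mapping[canonical]!r}"
                )
        object.__setattr__(self, "mapping", mapping)

    def canonical(self, label: str) -> str:
        return self.mapping.get(label, label)

    @classmethod
    def empty(cls) -> "SynonymTable":
        return cls(mapping={})


@dataclass(frozen=True)
class CombinedNetwork:
    """Union of harmonized expert maps with per-edge provenance.

    ``edges`` maps (source, target) to the list of (expert_id, strength)
    records that support it.  ``categories`` optionally tags nodes
    (pressure / environmental condition / operational factor / biological
    component); it is fixture metadata, never inferred.
    """

    nodes: frozenset[str]
    edges: Mapping[tuple[str, str], tuple[tuple[str, int | None], ...]]
    categories: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        edges = {k: tuple(v) for k, v in self.edges.items()}
        for (s, t), records in edges.items():
            if not records:
                raise MapFormatError(f"edge {s!r} -> {t!r} carries no expert record")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "categories", dict(self.categories))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def support_count(self, source: str, target: str) -> int:
        return len(self.edges[(source, target)])

    def max_strength(self, source: str, target: str) -> int | None:
        strengths = [s for _, s in self.edges[(source, target)] if s is not None]
        return max(strengths) if strengths else None

    def to_nx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for n in sorted(self.nodes):
            g.add_node(n, category=self.categories.get(n, ""))
        for (s, t), records in sorted(self.edges.items()):
            ms = self.max_strength(s, t)
            g.add_edge(
                s,
                t,
                support=self.support_count(s, t),
                max_strength=0 if ms is None else ms,
                experts=";".join(e for e, _ in records),
            )
        return g


# ---------------------------------------------------------------------------
# reading / writing

def _parse_rows(rows: Iterable[Sequence[str]], where: str) -> list[ConceptMap]:
    by_expert: dict[str, list[Link]] = {}
    order: list[str] = []
    for lineno, row in enumerate(rows, start=1):
        row = [c.strip() for c in row]
        if not row or not any(row) or row[0].startswith("#"):
            continue
        if row[0] == "expert_id":  # header
            continue
        if len(row) not in (3, 4):
            raise MapFormatError(f"{where}:{lineno}: expected expert_id,source,target[,strength]")
        expert, source, target = row[0], row[1], row[2]
        strength: int | None = None
        if len(row) == 4 and row[3]:
            try:
                strength = int(row[3])
            except ValueError:
                raise MapFormatError(f"{where}:{lineno}: strength {row[3]!r} is not an integer") from None
        try:
            link = Link(source, target, strength)
        except MapFormatError as exc:
            raise MapFormatError(f"{where}:{lineno}: {exc}") from None
        if expert not in by_expert:
            by_expert[expert] = []
            order.append(expert)
        by_expert[expert].append(link)
    return [
        ConceptMap(
            expert_id=e,
            nodes=frozenset({l.source for l in by_expert[e]} | {l.target for l in by_expert[e]}),
            links=frozenset(by_expert[e]),
        )
        for e in order
    ]


def read_concept_maps(source: str | Path | io.TextIOBase) -> list[ConceptMap]:
    """Parse an edge-list file with records ``expert_id,source,target[,strength]``.

    Returns one ConceptMap per expert in first-appearance order.  Self-loops
    and strengths outside 1-3 are rejected with the record location.
    """
    if isinstance(source, (str, Path)):
        where = str(source)
        with open(source, newline="") as fh:
            return _parse_rows(csv.reader(fh), where)
    return _parse_rows(csv.reader(source), "<stream>")


def write_concept_maps(maps: Sequence[ConceptMap], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["expert_id", "source", "target", "strength"])
        for cmap in maps:
            for link in sorted(cmap.links, key=lambda l: (l.source, l.target)):
                writer.writerow(
                    [cmap.expert_id, link.source, link.target,
                     "" if link.strength is None else link.strength]
                )


def read_synonym_table(source: str | Path | io.TextIOBase) -> SynonymTable:
    """Two-column delimited text: raw label, canonical label."""
    if isinstance(source, (str, Path)):
        with open(source, newline="") as fh:
            rows = list(csv.reader(fh))
    else:
        rows = list(csv.reader(source))
    mapping = {}
    for row in rows:
        row = [c.strip() for c in row]
        if not row or not any(row) or row[0].startswith("#") or row[0] == "raw":
            continue
        if len(row) != 2:
            raise MapFormatError(f"synonym record must have two columns: {row!r}")
        mapping[row[0]] = row[1]
    return SynonymTable(mapping=mapping)


# ---------------------------------------------------------------------------
# harmonization and merging

def harmonize(cmap: ConceptMap, synonyms: SynonymTable) -> ConceptMap:
    """Replace labels by their canonical forms.

    Links made parallel by the relabeling collapse to one link keeping the
    MAXIMUM strength (absent strengths never beat a numeric one); collapsed
    self-loops are dropped and logged.
    """
    nodes = frozenset(synonyms.canonical(n) for n in cmap.nodes)
    best: dict[tuple[str, str], int | None] = {}
    for link in cmap.links:
        s, t = synonyms.canonical(link.source), synonyms.canonical(link.target)
        if s == t:
            logger.warning(
                "map %s: dropping self-loop %r -> %r created by harmonization of %r -> %r",
                cmap.expert_id, s, t, link.source, link.target,
            )
            continue
        key = (s, t)
        if key not in best:
            best[key] = link.strength
        else:
            old = best[key]
            if old is None or (link.strength is not None and link.strength > old):
                best[key] = link.strength
    links = frozenset(Link(s, t, strength) for (s, t), strength in best.items())
    return ConceptMap(expert_id=cmap.expert_id, nodes=nodes, links=links)


def merge_maps(
    maps: Sequence[ConceptMap],
    categories: Mapping[str, str] | None = None,
) -> CombinedNetwork:
    """Union of already-harmonized maps; every edge keeps each contributing
    expert's strength record and the count of supporting experts."""
    if not maps:
        raise MapFormatError("cannot merge an empty list of maps")
    nodes: set[str] = set()
    edges: dict[tuple[str, str], list[tuple[str, int | None]]] = {}
    for cmap in sorted(maps, key=lambda m: m.expert_id):
        nodes |= cmap.nodes
        for link in sorted(cmap.links, key=lambda l: (l.source, l.target)):
            edges.setdefault((link.source, link.target), []).append(
                (cmap.expert_id, link.strength)
            )
    return CombinedNetwork(
        nodes=frozenset(nodes),
        edges={k: tuple(v) for k, v in edges.items()},
        categories=categories or {},
    )


# ---------------------------------------------------------------------------
# adjacency, summaries, exports

WEIGHT_RULES = ("none", "support_count", "max_strength")


def to_adjacency(network: CombinedNetwork, weight_rule: str = "none") -> pd.DataFrame:
    """Square adjacency matrix, rows/columns in lexicographic label order.

    Weight rules: ``none`` (1 for every edge), ``support_count``,
    ``max_strength`` (edges whose strengths were all unelicited weigh 1).
    """
    if weight_rule not in WEIGHT_RULES:
        raise MapFormatError(f"unknown weight rule {weight_rule!r}; choose from {WEIGHT_RULES}")
    labels = sorted(network.nodes)
    mat = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for (s, t) in network.edges:
        if weight_rule == "support_count":
            w = network.support_count(s, t)
        elif weight_rule == "max_strength":
            ms = network.max_strength(s, t)
            w = 1 if ms is None else ms
        else:
            w = 1
        mat.loc[s, t] = w
    return mat


def from_adjacency(matrix: pd.DataFrame, expert_id: str = "adjacency") -> CombinedNetwork:
    """Rebuild the topology of a combined network from an adjacency matrix.

    Provenance cannot be recovered; every nonzero entry becomes an edge with
    a single placeholder record.
    """
    if list(matrix.index) != list(matrix.columns):
        raise MapFormatError("adjacency matrix must have identical row and column labels")
    edges = {}
    arr = matrix.to_numpy()
    labels = list(matrix.index)
    for i, j in zip(*np.nonzero(arr)):
        edges[(labels[i], labels[j])] = ((expert_id, None),)
    return CombinedNetwork(nodes=frozenset(labels), edges=edges)


def degree_table(network: CombinedNetwork) -> pd.DataFrame:
    labels = sorted(network.nodes)
    out_deg = {n: 0 for n in labels}
    in_deg = {n: 0 for n in labels}
    for s, t in network.edges:
        out_deg[s] += 1
        in_deg[t] += 1
    return pd.DataFrame(
        {
            "node": labels,
            "category": [network.categories.get(n, "") for n in labels],
            "in_degree": [in_deg[n] for n in labels],
            "out_degree": [out_deg[n] for n in labels],
        }
    )


def summarize(network: CombinedNetwork) -> dict:
    """Deterministic counts report: nodes, edges, per-category node counts,
    and the in/out-degree table."""
    per_category: dict[str, int] = {}
    for n in network.nodes:
        cat = network.categories.get(n, "(uncategorized)")
        per_category[cat] = per_category.get(cat, 0) + 1
    return {
        "n_nodes": network.n_nodes,
        "n_edges": network.n_edges,
        "per_category": dict(sorted(per_category.items())),
        "degree_table": degree_table(network),
    }


def to_graphml(network: CombinedNetwork, path: str | Path) -> None:
    nx.write_graphml(network.to_nx(), str(path))


def to_dot(network: CombinedNetwork, path: str | Path) -> None:
    """Minimal hand-rolled DOT export (edge attrs: support count, max strength)."""
    lines = ["digraph combined {"]
    for n in sorted(network.nodes):
        cat = network.categories.get(n, "")
        lines.append(f'  "{n}" [category="{cat}"];')
    for (s, t) in sorted(network.edges):
        ms = network.max_strength(s, t)
        lines.append(
            f'  "{s}" -> "{t}" [support={network.support_count(s, t)}, '
            f'max_strength={0 if ms is None else ms}];'
        )
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
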