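"""Loaders for the packaged causal-map fixture.

The package ships a plain-text encoding of the eleven individual expert
causal maps, the synonym table used to harmonize them, and the node category
tags of the combined network.  Harmonizing and merging these maps yields the
combined causal network (53 variables, 96 connections).
"""

from __future__ import annotations

from importlib import resources

from .causal_map import (
    CombinedNetwork,
    ConceptMap,
    SynonymTable,
    harmonize,
    merge_maps,
    read_concept_maps,
    read_synonym_table,
)

__all__ = [
    "load_expert_maps",
    "load_synonyms",
    "load_categories",
    "load_combined",
    "fixture_path",
]


def fixture_path(name: str):
    return resources.files("seabedrisk") / "data" / name


def load_expert_maps() -> list[ConceptMap]:
    with resources.as_file(fixture_path("expert_maps.csv")) as p:
        return read_concept_maps(p)


def load_synonyms() -> SynonymTable:
    with resources.as_file(fixture_path("synonyms.csv")) as p:
        return read_synonym_table(p)


def load_categories() -> dict[str, str]:
    text = fixture_path("node_categories.csv").read_text()
    out = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("node,"):
            continue
        node, category = line.split(",", 1)
        out[node] = category
    return out


def load_combined() -> CombinedNetwork:
    """Harmonize and merge the packaged expert maps into the combined network."""
    synonyms = load_synonyms()
    maps = [harmonize(m, synonyms) for m in load_expert_maps()]
    return merge_maps(maps, categories=load_categories())
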