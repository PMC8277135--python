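"""Generate the packaged causal-map fixture CSVs.

Builds the canonical 53-node / 96-edge combined network design, splits it
into 11 expert edge lists (node counts within 8-24), injects raw synonym
labels, and writes src/seabedrisk/data/{expert_maps,synonyms,node_categories}.csv.
Run from the repo root:  python scratch/gen_fixture.py
"""

import csv
from pathlib import Path

OPERATIONAL = [
    "mining intensity", "depth of extracted sediment", "processing return technique",
    "volume of extraction", "mining tool operation", "vessel operations",
    "duration of extraction",
]
PRESSURES = [
    "nodule removal", "modification of seafloor substrate", "modification of seafloor topography",
    "suspended sediment in water column", "suspended sediment near seafloor",
    "sediment deposition", "release of nutrients", "contaminant release",
    "underwater noise", "loss of hard substrate",
]
ENVIRONMENT = [
    "sediment type", "contaminants in sediment", "water depth", "near-bottom currents",
    "stratification", "oxygen conditions", "sediment grain size", "organic content of sediment",
    "pore water composition", "salinity", "temperature", "nutrient concentration in sediment",
]
BIOLOGICAL = [
    "sessile epifauna", "mobile epifauna", "mobile infauna", "sessile infauna",
    "filter feeders", "deposit feeders", "demersal fish", "pelagic fish",
    "fish early life stages", "macrophytes", "marine mammals", "seabirds",
    "zooplankton", "phytoplankton", "microbial communities", "meiofauna",
    "food web structure", "benthic primary production", "reproductive success",
    "recovery potential", "habitat availability", "benthic biodiversity",
    "demersal fish distribution", "ecosystem functioning",
]

O = {i + 1: n for i, n in enumerate(OPERATIONAL)}
P = {i + 1: n for i, n in enumerate(PRESSURES)}
E = {i + 1: n for i, n in enumerate(ENVIRONMENT)}
B = {i + 1: n for i, n in enumerate(BIOLOGICAL)}

# 96 directed canonical edges, index 1..96
EDGES = [
    (O[1], O[4]), (O[2], O[4]), (O[7], O[4]), (O[4], P[4]), (O[4], P[5]),          # 1-5
    (O[4], P[6]), (O[3], P[4]), (O[3], P[5]), (O[3], P[6]), (O[5], P[9]),          # 6-10
    (O[6], P[9]), (O[5], P[5]), (O[1], P[1]), (P[1], P[10]), (O[2], P[2]),         # 11-15
    (O[4], P[2]), (O[4], P[3]), (E[1], P[4]), (E[1], P[5]), (E[1], P[6]),          # 16-20
    (E[7], P[4]), (E[7], P[5]), (E[2], P[8]), (P[5], P[8]), (E[12], P[7]),         # 21-25
    (P[5], P[7]), (E[8], P[7]), (E[9], P[8]), (E[4], P[4]), (E[4], P[5]),          # 26-30
    (E[4], P[6]), (E[5], P[4]), (E[3], P[4]), (E[6], P[8]), (E[10], E[5]),         # 31-35
    (E[11], E[5]), (E[3], E[5]), (P[1], B[1]), (P[10], B[1]), (P[10], B[21]),      # 36-40
    (P[2], B[3]), (P[2], B[4]), (P[2], B[16]), (P[2], B[15]), (P[2], B[6]),        # 41-45
    (P[3], B[21]), (P[4], B[13]), (P[4], B[14]), (P[4], B[9]), (P[4], B[8]),       # 46-50
    (P[5], B[5]), (P[5], B[1]), (P[5], B[2]), (P[5], B[3]), (P[6], B[1]),          # 51-55
    (P[6], B[4]), (P[6], B[16]), (P[6], B[10]), (P[6], B[18]), (P[7], B[14]),      # 56-60
    (P[7], B[18]), (P[8], B[1]), (P[8], B[2]), (P[8], B[3]), (P[8], B[19]),        # 61-65
    (P[8], B[9]), (P[8], B[16]), (P[9], B[11]), (P[9], B[7]), (P[9], B[8]),        # 66-70
    (P[9], B[12]), (P[1], B[21]), (B[1], B[17]), (B[2], B[17]), (B[3], B[17]),     # 71-75
    (B[6], B[17]), (B[17], B[7]), (B[17], B[11]), (B[3], B[7]), (B[2], B[7]),      # 76-80
    (B[21], B[20]), (B[19], B[20]), (B[15], B[18]), (B[14], B[13]), (B[13], B[8]), # 81-85
    (B[9], B[8]), (B[7], B[23]), (B[21], B[23]), (B[1], B[22]), (B[3], B[22]),     # 86-90
    (B[22], B[24]), (B[18], B[24]), (B[17], B[24]), (B[20], B[22]), (B[10], B[18]),# 91-95
    (E[6], B[4]),                                                                  # 96
]

# per-expert canonical edge indices (1-based); E01-E03 geologists, rest ecologists
ASSIGNMENTS = {
    "E01": list(range(1, 19)),
    "E02": list(range(13, 38)),
    "E03": list(range(1, 13)) + list(range(29, 35)),
    "E04": list(range(38, 58)),
    "E05": list(range(51, 73)),
    "E06": list(range(73, 97)),
    "E07": list(range(38, 51)) + list(range(62, 68)),
    "E08": list(range(55, 62)) + [83, 84, 85, 95],
    "E09": list(range(62, 72)) + [79, 80, 81, 82],
    "E10": list(range(73, 79)) + list(range(89, 95)),
    "E11": list(range(47, 55)) + [84, 85, 86],
}

SYNONYMS = {
    "worms": "mobile infauna",
    "polychaetes": "mobile infauna",
    "annelids": "mobile infauna",
    "turbidity near the seabed": "suspended sediment near seafloor",
    "smothering by settling sediment": "sediment deposition",
    "release of toxic substances": "contaminant release",
    "bottom fauna biodiversity": "benthic biodiversity",
}

# raw-label substitutions applied when writing an expert's records
RAW_LABELS = {
    "E02": {"contaminant release": "release of toxic substances"},
    "E04": {"mobile infauna": "polychaetes"},
    "E05": {"suspended sediment near seafloor": "turbidity near the seabed"},
    "E06": {"mobile infauna": "worms", "benthic biodiversity": "bottom fauna biodiversity"},
    "E07": {"mobile infauna": "annelids"},
    "E08": {"sediment deposition": "smothering by settling sediment"},
}

# extra raw records that collapse onto an existing edge during harmonization
EXTRA_RAW = [
    ("E04", "modification of seafloor substrate", "worms", 1),  # dup of edge 41
]


def strength_for(edge_idx: int, expert_rank: int):
    if (edge_idx * 7 + expert_rank * 3) % 10 < 6:
        return (edge_idx + expert_rank) % 3 + 1
    return None


def main() -> None:
    assert len(set(EDGES)) == 96, f"duplicate edges: {len(set(EDGES))}"
    nodes = {n for e in EDGES for n in e}
    all_labels = set(OPERATIONAL + PRESSURES + ENVIRONMENT + BIOLOGICAL)
    assert nodes == all_labels and len(nodes) == 53, (len(nodes), sorted(all_labels - nodes))
    covered = sorted({i for idxs in ASSIGNMENTS.values() for i in idxs})
    assert covered == list(range(1, 97)), f"uncovered edges: {set(range(1,97)) - set(covered)}"

    # weak connectivity of the canonical graph (synthetic generator relies on it)
    import networkx as nx
    g = nx.DiGraph(EDGES)
    assert nx.is_weakly_connected(g), "canonical graph must be weakly connected"

    rows = []
    for rank, (expert, idxs) in enumerate(sorted(ASSIGNMENTS.items())):
        subs = RAW_LABELS.get(expert, {})
        node_set = set()
        for i in idxs:
            s, t = EDGES[i - 1]
            node_set.update((s, t))
            rows.append((expert, subs.get(s, s), subs.get(t, t), strength_for(i, rank)))
        n = len(node_set)
        assert 8 <= n <= 24, f"{expert}: {n} nodes outside 8-24"
        print(f"{expert}: {len(idxs)} links, {n} canonical nodes")
    for expert, s, t, strength in EXTRA_RAW:
        rows.append((expert, s, t, strength))

    data_dir = Path(__file__).resolve().parent.parent / "src" / "seabedrisk" / "data"
    data_dir.mkdir(parents=True, exist_ok=True)

    with open(data_dir / "expert_maps.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["expert_id", "source", "target", "strength"])
        for expert, s, t, strength in rows:
            w.writerow([expert, s, t, "" if strength is None else strength])

    with open(data_dir / "synonyms.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["raw", "canonical"])
        for raw, canonical in sorted(SYNONYMS.items()):
            w.writerow([raw, canonical])

    with open(data_dir / "node_categories.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["node", "category"])
        for label in sorted(OPERATIONAL):
            w.writerow([label, "operational factor"])
        for label in sorted(PRESSURES):
            w.writerow([label, "pressure"])
        for label in sorted(ENVIRONMENT):
            w.writerow([label, "environmental condition"])
        for label in sorted(BIOLOGICAL):
            w.writerow([label, "biological component"])

    print(f"wrote fixture to {data_dir}")


if __name__ == "__main__":
    main()
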