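# seabedrisk

Probabilistic environmental risk assessment of seabed mineral extraction:
merge expert causal maps into a combined causal network, build a discrete
Bayesian network of mining pressures and benthic-fauna mortality, and query
posterior mortality distributions under alternative mining scenarios.

## What it does

1. **Causal-map aggregation** (`seabedrisk.causal_map`) — read per-expert
   directed edge lists with optional 1–3 link strengths, harmonize labels
   through a synonym table (e.g. *polychaetes* → *mobile infauna*), and merge
   the maps into one combined network with per-expert provenance. Exports:
   GraphML, DOT, adjacency matrix, degree/category summaries. The packaged
   11-map fixture merges to 53 variables and 96 connections.
2. **Bayesian network core** (`seabedrisk.bn_core`) — discrete networks with
   decision (operator-controlled) and random nodes, full validation
   (acyclicity, CPT coverage, row sums within 1e-9), exact posteriors by
   variable elimination, YAML model files with bit-exact round trips, and a
   delimited CPT-table importer for externally published tables.
3. **CPT elicitation** (`seabedrisk.cpt_elicitation`) — initialize CPTs from
   ranked parent influences (direction + magnitude, per-state offsets for
   nominal parents), adjust rows verbatim with an audit log, and generate
   seeded Dirichlet CPTs (optionally monotone by first-order stochastic
   dominance) for testing.
4. **Mortality combination** (`seabedrisk.mortality`) — total mortality
   `total = direct + indirect × (1 − direct)` computed by numerical
   approximation on the 1% grid, mapped to the five mortality classes
   (0–10/11–30/31–60/61–80/81–100%); direct mortality proportional to the
   mined share; a deterministic 25-row total-mortality CPT builder.
5. **Scenario engine** (`seabedrisk.scenario_engine`) — evaluate mining
   scenarios (decision assignments + optional evidence), compare scenarios in
   long-format tables, and rank stressors by their effect on expected
   mortality (class-midpoint metric, with total-variation distance).
6. **Synthetic data** (`seabedrisk.synthetic_data`) — seeded generators for
   expert maps (drawn from a hidden consensus network), the default 18-node
   quantitative model, and full-factorial scenario suites, so every stage is
   testable offline.

## CLI

```sh
# merge the packaged fixture maps (or your own edge lists)
seabedrisk merge-maps path/to/expert_maps.csv --synonyms path/to/synonyms.csv --out-dir out/

# materialize a complete synthetic workspace (maps, model, scenarios)
seabedrisk make-fixtures workspace/ --seed 1

# validate a model file, run a scenario, compare scenario suites
seabedrisk validate-model workspace/model.yaml
seabedrisk run-scenario workspace/model.yaml \
    --set "mining intensity=75% removed" \
    --set "depth of extracted sediment=11-30 cm"
seabedrisk compare-scenarios workspace/model.yaml workspace/scenarios.yaml --out posteriors.csv

# stressor ranking
seabedrisk rank-stressors workspace/model.yaml \
    --target "total mortality infauna" \
    --stressor "suspended sediment" --stressor "contaminant release"

# the whole three-step pipeline with a reproducibility manifest
seabedrisk run-pipeline --maps workspace/expert_maps.csv \
    --synonyms workspace/synonyms.csv --model workspace/model.yaml \
    --scenarios workspace/scenarios.yaml --out-dir out/
```

Every defaulted choice (uniform decision policy, tie-breaks) is logged and
recorded in the run manifest.

## Data fixture

`src/seabedrisk/data/` ships a constructed plain-text encoding of the eleven
expert causal maps (edge lists with synonym variants and partial strengths),
the synonym table, and node category tags; `scripts/build_fixture.py`
regenerates it deterministically.
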