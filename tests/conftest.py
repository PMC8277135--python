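import itertools

import numpy as np
import pytest

from seabedrisk.bn_core import CPT, VariableSpec, build_network


def random_network(rng, n_nodes=None, max_states=3, n_decisions=0, edge_prob=0.5):
    """Seeded random DAG with Dirichlet CPTs, for oracle cross-checks."""
    if n_nodes is None:
        n_nodes = int(rng.integers(3, 9))
    names = [f"v{i}" for i in range(n_nodes)]
    cards = rng.integers(2, max_states + 1, size=n_nodes)
    decision_idx = set(rng.choice(n_nodes, size=n_decisions, replace=False).tolist()) if n_decisions else set()
    specs = [
        VariableSpec(
            names[i],
            tuple(f"s{j}" for j in range(cards[i])),
            "decision" if i in decision_idx else "random",
        )
        for i in range(n_nodes)
    ]
    cpts = []
    for i in range(n_nodes):
        if i in decision_idx:
            continue
        parents = tuple(
            names[j] for j in range(i) if rng.random() < edge_prob
        )
        shape = tuple(int(cards[int(p[1:])]) for p in parents)
        table = rng.dirichlet(np.ones(int(cards[i])), size=shape or None)
        if not parents:
            table = np.asarray(table).reshape(int(cards[i]))
        cpts.append(CPT(child=names[i], parents=parents, table=np.asarray(table)))
    return build_network(specs, cpts)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def chain_network():
    """Hand-specified 3-node chain a -> b -> c with binary states."""
    a = VariableSpec("a", ("a0", "a1"))
    b = VariableSpec("b", ("b0", "b1"))
    c = VariableSpec("c", ("c0", "c1"))
    cpts = [
        CPT("a", (), np.array([0.3, 0.7])),
        CPT("b", ("a",), np.array([[0.9, 0.1], [0.2, 0.8]])),
        CPT("c", ("b",), np.array([[0.6, 0.4], [0.25, 0.75]])),
    ]
    return build_network([a, b, c], cpts)


@pytest.fixture(scope="session")
def mini_mortality_network():
    """Small network following the mortality naming convention, enumerable."""
    from seabedrisk.mortality import DEFAULT_SCHEME, build_total_mortality_cpt
    from seabedrisk.synthetic_data import INTENSITY_STATES

    rng = np.random.default_rng(7)
    intensity = VariableSpec("mining intensity", INTENSITY_STATES, "decision")
    suspended = VariableSpec("suspended sediment", ("low", "medium", "high"))
    direct = VariableSpec("direct mortality benthos", DEFAULT_SCHEME.labels)
    indirect = VariableSpec("indirect mortality benthos", DEFAULT_SCHEME.labels)
    total = VariableSpec("total mortality benthos", DEFAULT_SCHEME.labels)
    cpts = [
        CPT("suspended sediment", ("mining intensity",), rng.dirichlet(np.ones(3), size=3)),
        CPT("direct mortality benthos", ("mining intensity",), rng.dirichlet(np.ones(5), size=3)),
        CPT("indirect mortality benthos", ("suspended sediment",), rng.dirichlet(np.ones(5), size=3)),
        build_total_mortality_cpt("total mortality benthos", direct, indirect),
    ]
    return build_network([intensity, suspended, direct, indirect, total], cpts)
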