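import itertools

import numpy as np
import pytest

from seabedrisk.bn_core import (
    CPT,
    ContradictoryEvidenceError,
    CycleError,
    ModelError,
    Posterior,
    VariableSpec,
    build_network,
    joint_probability,
    most_probable_state,
    posterior,
    read_cpt_table,
    read_model_file,
    uniform_policy,
    write_cpt_table,
    write_model_file,
)

from _oracles import enumerate_posterior
from conftest import random_network


class TestBuildNetwork:
    def test_two_node_chain(self):
        a = VariableSpec("a", ("0", "1"))
        b = VariableSpec("b", ("0", "1"))
        net = build_network(
            [a, b],
            [CPT("a", (), np.array([0.5, 0.5])), CPT("b", ("a",), np.full((2, 2), 0.5))],
        )
        assert set(net.variables) == {"a", "b"}
        assert net.parents("b") == ("a",)

    def test_cycle_rejected(self):
        a = VariableSpec("a", ("0", "1"))
        b = VariableSpec("b", ("0", "1"))
        with pytest.raises(CycleError, match="cycle"):
            build_network(
                [a, b],
                [
                    CPT("a", ("b",), np.full((2, 2), 0.5)),
                    CPT("b", ("a",), np.full((2, 2), 0.5)),
                ],
            )

    def test_decision_with_cpt_rejected(self):
        d = VariableSpec("d", ("0", "1"), "decision")
        with pytest.raises(ModelError, match="decision"):
            build_network([d], [CPT("d", (), np.array([0.5, 0.5]))])

    def test_random_without_cpt_rejected(self):
        with pytest.raises(ModelError, match="no CPT"):
            build_network([VariableSpec("a", ("0", "1"))], [])

    def test_missing_rows_rejected(self):
        a = VariableSpec("a", ("0", "1", "2"))
        b = VariableSpec("b", ("0", "1"))
        with pytest.raises(ModelError, match="shape"):
            build_network(
                [a, b],
                [
                    CPT("a", (), np.full(3, 1 / 3)),
                    CPT("b", ("a",), np.full((2, 2), 0.5)),  # needs 3 rows
                ],
            )

    def test_unnormalized_row_rejected(self):
        with pytest.raises(ModelError, match="sums to"):
            build_network(
                [VariableSpec("a", ("0", "1"))],
                [CPT("a", (), np.array([0.5, 0.6]))],
            )

    def test_18_variable_network(self):
        from seabedrisk.synthetic_data import SyntheticConfig, generate_network

        net = generate_network(SyntheticConfig(seed=0))
        assert len(net.variables) == 18


class TestJointProbability:
    def test_two_uniform_roots(self):
        specs = [VariableSpec("a", ("0", "1")), VariableSpec("b", ("0", "1"))]
        cpts = [CPT("a", (), np.array([0.5, 0.5])), CPT("b", (), np.array([0.5, 0.5]))]
        net = build_network(specs, cpts)
        for sa, sb in itertools.product("01", repeat=2):
            assert joint_probability(net, {"a": sa, "b": sb}) == pytest.approx(0.25)

    def test_sums_to_one(self, chain_network):
        total = sum(
            joint_probability(chain_network, {"a": f"a{i}", "b": f"b{j}", "c": f"c{k}"})
            for i, j, k in itertools.product(range(2), repeat=3)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_hand_multiplied_chain(self, chain_network):
        # p(a1) * p(b0|a1) * p(c1|b0) = 0.7 * 0.2 * 0.4
        p = joint_probability(chain_network, {"a": "a1", "b": "b0", "c": "c1"})
        assert p == pytest.approx(0.7 * 0.2 * 0.4, abs=1e-15)

    def test_incomplete_assignment_rejected(self, chain_network):
        with pytest.raises(ModelError, match="cover"):
            joint_probability(chain_network, {"a": "a0"})

    def test_decision_policy_mass(self):
        d = VariableSpec("d", ("0", "1"), "decision")
        x = VariableSpec("x", ("0", "1"))
        net = build_network([d, x], [CPT("x", ("d",), np.array([[0.9, 0.1], [0.3, 0.7]]))])
        p = joint_probability(net, {"d": "1", "x": "0"}, policy={"d": [0.25, 0.75]})
        assert p == pytest.approx(0.75 * 0.3)


class TestPosterior:
    def test_root_prior(self, chain_network):
        post = posterior(chain_network, "a")
        assert np.allclose(post.probabilities, [0.3, 0.7], atol=1e-12)

    def test_query_equals_evidence(self, chain_network):
        post = posterior(chain_network, "b", evidence={"b": "b1"})
        assert np.allclose(post.probabilities, [0.0, 1.0])

    def test_conditioning_on_all_parents_gives_cpt_row(self, chain_network):
        post = posterior(chain_network, "c", evidence={"b": "b0"})
        assert np.allclose(post.probabilities, [0.6, 0.4], atol=1e-12)

    def test_matches_enumeration_oracle_seeded(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            net = random_network(rng, n_nodes=6)
            names = list(net.variables)
            ev_var = names[int(rng.integers(len(names)))]
            ev_state = net.specs[ev_var].states[0]
            q = names[int(rng.integers(len(names)))]
            try:
                expected = enumerate_posterior(net, q, {ev_var: ev_state})
            except ZeroDivisionError:
                continue
            got = posterior(net, q, evidence={ev_var: ev_state})
            assert np.max(np.abs(got.probabilities - np.array(expected))) < 1e-9

    def test_elimination_order_invariance(self, rng):
        net = random_network(rng, n_nodes=7)
        names = [v for v in net.variables if v != "v0"]
        base = posterior(net, "v0")
        for _ in range(5):
            order = [names[i] for i in rng.permutation(len(names))]
            alt = posterior(net, "v0", elimination_order=order)
            assert np.allclose(base.probabilities, alt.probabilities, atol=1e-12)

    def test_disconnected_node_changes_nothing(self, chain_network):
        specs = list(chain_network.specs.values()) + [VariableSpec("iso", ("0", "1"))]
        cpts = list(chain_network.cpts.values()) + [CPT("iso", (), np.array([0.4, 0.6]))]
        bigger = build_network(specs, cpts)
        for q in ("a", "b", "c"):
            assert np.allclose(
                posterior(chain_network, q, evidence={"c": "c1"}).probabilities,
                posterior(bigger, q, evidence={"c": "c1"}).probabilities,
                atol=1e-12,
            )

    def test_contradictory_evidence(self):
        a = VariableSpec("a", ("0", "1"))
        net = build_network([a], [CPT("a", (), np.array([1.0, 0.0]))])
        with pytest.raises(ContradictoryEvidenceError):
            posterior(net, "a", evidence={"a": "1"})

    def test_decision_requires_policy_or_evidence(self):
        d = VariableSpec("d", ("0", "1"), "decision")
        x = VariableSpec("x", ("0", "1"))
        net = build_network([d, x], [CPT("x", ("d",), np.array([[0.9, 0.1], [0.3, 0.7]]))])
        with pytest.raises(ModelError, match="policy"):
            posterior(net, "x")
        post = posterior(net, "x", policy=uniform_policy(net))
        assert np.allclose(post.probabilities, [0.6, 0.4], atol=1e-12)

    def test_posterior_sums_to_one_property(self, rng):
        for _ in range(10):
            net = random_network(rng)
            post = posterior(net, "v0")
            assert abs(post.probabilities.sum() - 1.0) < 1e-9


class TestMostProbableState:
    def test_simple_argmax(self):
        post = Posterior("x", ("s1", "s2", "s3"), np.array([0.1, 0.6, 0.3]), ())
        assert most_probable_state(post) == ("s2", 0.6, False)

    def test_tie_breaks_low(self):
        post = Posterior("x", ("s1", "s2"), np.array([0.5, 0.5]), ())
        state, prob, tied = most_probable_state(post)
        assert state == "s1" and prob == 0.5 and tied


class TestModelFileIO:
    def test_bit_exact_roundtrip(self, tmp_path, chain_network):
        p1, p2 = tmp_path / "m1.yaml", tmp_path / "m2.yaml"
        write_model_file(chain_network, p1)
        net2 = read_model_file(p1)
        write_model_file(net2, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert list(net2.variables) == list(chain_network.variables)
        for name, cpt in chain_network.cpts.items():
            assert np.array_equal(net2.cpts[name].table, cpt.table)

    def test_synthetic_roundtrip_bit_exact(self, tmp_path):
        from seabedrisk.synthetic_data import SyntheticConfig, generate_network

        net = generate_network(SyntheticConfig(seed=3))
        p1, p2 = tmp_path / "m1.yaml", tmp_path / "m2.yaml"
        write_model_file(net, p1)
        write_model_file(read_model_file(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_row_in_file_rejected(self, tmp_path):
        path = tmp_path / "m.yaml"
        path.write_text(
            "variables:\n"
            "- {name: a, kind: random, states: ['0', '1']}\n"
            "- {name: b, kind: random, states: ['0', '1']}\n"
            "cpts:\n"
            "- child: a\n  parents: []\n  rows:\n  - {given: [], p: [0.5, 0.5]}\n"
            "- child: b\n  parents: [a]\n  rows:\n  - {given: ['0'], p: [0.5, 0.5]}\n"
        )
        with pytest.raises(ModelError, match="missing"):
            read_model_file(path)


class TestCptTableIO:
    def test_roundtrip(self, tmp_path, chain_network):
        specs = chain_network.specs
        path = tmp_path / "cpt.csv"
        write_cpt_table(chain_network.cpts["b"], specs, path)
        cpt = read_cpt_table(path, "b", specs)
        assert cpt.parents == ("a",)
        assert np.allclose(cpt.table, chain_network.cpts["b"].table)

    def test_missing_combination_rejected(self, tmp_path, chain_network):
        path = tmp_path / "cpt.csv"
        path.write_text("a,b0,b1\na0,0.9,0.1\n")
        with pytest.raises(ModelError, match="missing"):
            read_cpt_table(path, "b", chain_network.specs)
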