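"""CPT estimation, exact inference vs enumeration, neighborhoods, exports."""

import numpy as np
import pytest

from venomnet.mdl import DiscreteDataset
from venomnet.network import (
    DegenerateEvidenceError,
    NetworkModel,
    arc_influence,
    connectivity_stats,
    first_degree_associates,
    fit_cpts,
    infer_posterior,
    to_dot,
    to_graphml,
    cpts_to_json,
)

from helpers import posterior_by_enumeration, random_network


def binary_ds(columns: dict[str, list[int]]) -> DiscreteDataset:
    names = list(columns)
    codes = np.array(list(zip(*columns.values())), dtype=np.int64)
    return DiscreteDataset(names, codes, [2] * len(names))


def fixture_model(arcs: list[tuple[str, str]], nodes: list[str]) -> NetworkModel:
    parents: dict[str, tuple[str, ...]] = {v: () for v in nodes}
    for p, c in arcs:
        parents[c] = parents[c] + (p,)
    cpts = {}
    for v in nodes:
        q = 2 ** len(parents[v])
        cpts[v] = np.full((q, 2), 0.5)
    return NetworkModel(tuple(nodes), {v: 2 for v in nodes}, parents, cpts)


class TestFitCPTs:
    def test_laplace_hand_example(self):
        ds = binary_ds({"x": [1, 1, 1, 0]})
        m = fit_cpts({"x": ()}, ds, alpha=1)
        assert m.cpts["x"][0, 1] == pytest.approx(4 / 6)

    def test_unseen_parent_config_uniform(self):
        ds = binary_ds({"x": [0, 0], "y": [1, 0]})
        m = fit_cpts({"x": (), "y": ("x",)}, ds, alpha=0)
        assert m.cpts["y"][1].tolist() == [0.5, 0.5]  # x = 1 never observed

    def test_alpha_zero_gives_ml_frequencies(self):
        ds = binary_ds({"x": [1, 1, 1, 0]})
        m = fit_cpts({"x": ()}, ds, alpha=0)
        assert m.cpts["x"][0, 1] == pytest.approx(0.75)

    def test_rows_sum_to_one(self, rng):
        cols = {v: rng.integers(0, 2, size=40).tolist() for v in "abc"}
        m = fit_cpts({"a": (), "b": ("a",), "c": ("a", "b")}, binary_ds(cols))
        for v in "abc":
            assert np.allclose(m.cpts[v].sum(axis=1), 1.0, atol=1e-12)


class TestInference:
    def test_single_edge_posterior_is_cpt_row(self, rng):
        x = rng.integers(0, 2, size=100).tolist()
        y = rng.integers(0, 2, size=100).tolist()
        m = fit_cpts({"x": (), "y": ("x",)}, binary_ds({"x": x, "y": y}))
        post = infer_posterior(m, {"x": 1}, "y")
        assert post == pytest.approx(m.cpts["y"][1], abs=1e-12)

    def test_no_evidence_marginal_matches_enumeration(self, rng):
        for _ in range(20):
            m = random_network(rng)
            q = m.nodes[0]
            got = infer_posterior(m, {}, q)
            want = posterior_by_enumeration(m, {}, q)
            assert got == pytest.approx(want, abs=1e-9)

    def test_posterior_matches_enumeration_with_evidence(self, rng):
        for _ in range(30):
            m = random_network(rng)
            ev_nodes = [v for v in m.nodes[1:]][: int(rng.integers(0, len(m.nodes)))]
            evidence = {v: int(rng.integers(0, m.cards[v])) for v in ev_nodes}
            got = infer_posterior(m, evidence, m.nodes[0])
            want = posterior_by_enumeration(m, evidence, m.nodes[0])
            assert got == pytest.approx(want, abs=1e-9)
            assert got.sum() == pytest.approx(1.0, abs=1e-9)

    def test_explaining_away_in_v_structure(self):
        # C = noisy OR of A, B; observing A = 1 explains C = 1, lowering P(B = 1)
        nodes = ["a", "b", "c"]
        parents = {"a": (), "b": (), "c": ("a", "b")}
        cpt_c = np.array(
            [[0.95, 0.05], [0.1, 0.9], [0.1, 0.9], [0.02, 0.98]]
        )  # rows: (a,b) = 00,01,10,11
        cpts = {"a": np.array([[0.5, 0.5]]), "b": np.array([[0.5, 0.5]]), "c": cpt_c}
        m = NetworkModel(tuple(nodes), {v: 2 for v in nodes}, parents, cpts)
        p_b_given_c = infer_posterior(m, {"c": 1}, "b")[1]
        p_b_given_c_a = infer_posterior(m, {"c": 1, "a": 1}, "b")[1]
        assert p_b_given_c_a < p_b_given_c
        # cross-check both against brute-force enumeration
        assert p_b_given_c == pytest.approx(
            posterior_by_enumeration(m, {"c": 1}, "b")[1], abs=1e-12
        )

    def test_zero_probability_evidence_raises(self):
        nodes = ["x", "y"]
        cpts = {"x": np.array([[1.0, 0.0]]), "y": np.array([[1.0, 0.0], [0.5, 0.5]])}
        m = NetworkModel(tuple(nodes), {v: 2 for v in nodes}, {"x": (), "y": ("x",)}, cpts)
        with pytest.raises(DegenerateEvidenceError):
            infer_posterior(m, {"x": 1}, "y")

    def test_query_in_evidence_rejected(self, rng):
        m = random_network(rng, n_nodes=3)
        with pytest.raises(ValueError):
            infer_posterior(m, {m.nodes[0]: 0}, m.nodes[0])


class TestNeighborhoods:
    def test_adjacency_definition(self):
        m = fixture_model([("x", "r"), ("r", "y"), ("z", "x")], ["x", "y", "z", "r"])
        assert first_degree_associates(m, "r") == {"x", "y"}

    def test_isolated_target_empty(self):
        m = fixture_model([], ["a", "b"])
        assert first_degree_associates(m, "a") == set()

    def test_characteristic_post_antivenom_topology(self):
        """Fixture with a characteristic post-antivenom associate set for recovery."""
        nodes = ["age", "antihistamines", "WBC", "HGF", "CCL5", "VEGF", "R"]
        arcs = [
            ("age", "R"),
            ("antihistamines", "R"),
            ("R", "HGF"),
            ("R", "CCL5"),
            ("R", "VEGF"),
            ("WBC", "R"),
        ]
        m = fixture_model(arcs, nodes)
        assert first_degree_associates(m, "R") == {
            "age", "antihistamines", "WBC", "HGF", "CCL5", "VEGF",
        }
        stats = connectivity_stats(m, outcome="R")
        assert stats.outcome_degree == 6
        assert stats.n_arcs == 6

    def test_unknown_target_rejected(self):
        m = fixture_model([], ["a"])
        with pytest.raises(KeyError):
            first_degree_associates(m, "nope")


class TestConnectivity:
    def test_empty_graph_counts(self):
        m = fixture_model([], list("abcde"))
        s = connectivity_stats(m)
        assert s.n_nodes == 5 and s.n_arcs == 0
        assert all(d == 0 for d in s.degree.values())

    def test_handshake_identity(self, rng):
        for _ in range(10):
            m = random_network(rng)
            s = connectivity_stats(m)
            assert sum(s.degree.values()) == 2 * s.n_arcs


class TestArcInfluenceAndExport:
    def test_influence_positive_for_strong_arc(self, rng):
        x = rng.integers(0, 2, size=300)
        y = np.where(rng.uniform(size=300) < 0.05, 1 - x, x)
        ds = binary_ds({"x": x.tolist(), "y": y.tolist()})
        m = fit_cpts({"x": (), "y": ("x",)}, ds)
        infl = arc_influence(m, ds)
        assert infl[("x", "y")] > 0

    def test_exports_roundtrip(self, tmp_path, rng):
        import json
        import networkx as nx

        m = fixture_model([("a", "b"), ("b", "c")], ["a", "b", "c"])
        to_graphml(m, tmp_path / "m.graphml")
        g = nx.read_graphml(tmp_path / "m.graphml")
        assert set(g.edges) == {("a", "b"), ("b", "c")}
        to_dot(m, tmp_path / "m.dot")
        assert '"a" -> "b";' in (tmp_path / "m.dot").read_text()
        cpts_to_json(m, tmp_path / "m.json")
        payload = json.loads((tmp_path / "m.json").read_text())
        assert payload["nodes"]["b"]["parents"] == ["a"]
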