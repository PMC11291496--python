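import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from permamicro import conet, datagen
from permamicro.conet import (
    CorrelationMatrix,
    ModulePartition,
    build_network,
    keystone_fraction,
    modules_and_relative_modularity,
    node_roles,
    prepare_matrix,
    rmt_threshold,
    topology,
)
from permamicro.core_io import CountTable, ValidationError, min_depth, rarefy_table


def corr_from(values: np.ndarray) -> CorrelationMatrix:
    ids = [f"f{i}" for i in range(values.shape[0])]
    return CorrelationMatrix(ids, values)


class TestPrepareMatrix:
    def test_prevalence_filter_drops_absent_feature(self):
        counts = np.array([[5, 5, 5, 5], [3, 0, 3, 3], [2, 3, 2, 4], [9, 1, 4, 2]])
        t = CountTable(["a", "b", "c", "d"], ["s1", "s2", "s3", "s4"], counts)
        c = prepare_matrix(t, ["s1", "s2", "s3", "s4"])
        assert "b" not in c.feature_ids
        assert {"a", "c", "d"} <= set(c.feature_ids)

    def test_proportional_features_perfectly_correlated(self):
        rng = np.random.default_rng(0)
        base = rng.integers(10, 100, size=6)
        counts = np.vstack([base, base * 3, rng.integers(10, 100, size=6)])
        t = CountTable(["a", "b", "c"], [f"s{i}" for i in range(6)], counts)
        c = prepare_matrix(t, list(t.sample_ids))
        i, j = c.feature_ids.index("a"), c.feature_ids.index("b")
        assert c.r[i, j] == pytest.approx(1.0, abs=1e-12)

    def test_matches_two_pass_oracle(self):
        # independent two-pass covariance/correlation implementation
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 500, size=(5, 10))
        t = CountTable([f"f{i}" for i in range(5)], [f"s{j}" for j in range(10)], counts)
        c = prepare_matrix(t, list(t.sample_ids))
        rel = counts / counts.sum(axis=0, keepdims=True)
        x = np.log10(rel)
        n = x.shape[1]
        means = x.sum(axis=1) / n
        oracle = np.empty((5, 5))
        for i in range(5):
            for j in range(5):
                di, dj = x[i] - means[i], x[j] - means[j]
                oracle[i, j] = (di * dj).sum() / np.sqrt((di**2).sum() * (dj**2).sum())
        np.testing.assert_allclose(c.r, oracle, atol=1e-12)

    def test_too_few_samples_rejected(self, small_table):
        with pytest.raises(ValidationError):
            prepare_matrix(small_table, ["s1", "s2"])


class TestThresholdAndNetwork:
    def test_near_identity_already_poisson_at_smin(self):
        rng = np.random.default_rng(2)
        r = np.eye(40) + rng.uniform(-0.1, 0.1, size=(40, 40))
        r = np.clip((r + r.T) / 2, -1, 1)
        np.fill_diagonal(r, 1.0)
        assert rmt_threshold(corr_from(r)) == pytest.approx(0.3)

    def test_dense_goe_like_matrix_is_wigner_at_low_threshold(self):
        # correlation matrix of modest samples: spacings repel, not Poisson
        rng = np.random.default_rng(3)
        x = rng.normal(size=(200, 60))
        r = np.corrcoef(x)
        b = np.where(np.abs(r) >= 0.05, r, 0.0)
        np.fill_diagonal(b, 1.0)
        eigs = np.linalg.eigvalsh(b)
        from permamicro import rmt

        label, p_poisson, _ = rmt.classify_spacings(rmt.unfolded_spacings(eigs))
        assert label == "wigner"
        assert p_poisson < 0.05

    def test_complete_graph_counts(self):
        r = np.ones((4, 4))
        g = build_network(corr_from(r), 0.9)
        topo = topology(g)
        assert topo["n_links"] == 6
        assert topo["avgK"] == pytest.approx(3.0)

    def test_edges_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(30, 12))
        c = corr_from(np.corrcoef(x))
        prev = None
        for s in (0.3, 0.5, 0.7):
            edges = set(map(frozenset, build_network(c, s).edges()))
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_avgk_identity_on_generated_networks(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(30, 12))
        c = corr_from(np.corrcoef(x))
        for s in (0.4, 0.6):
            topo = topology(build_network(c, s))
            assert topo["avgK"] == pytest.approx(2 * topo["n_links"] / topo["n_nodes"])

    def test_triangle_plus_pendant_clustering(self):
        r = np.zeros((4, 4))
        for i, j in ((0, 1), (0, 2), (1, 2), (2, 3)):
            r[i, j] = r[j, i] = 0.95
        np.fill_diagonal(r, 1.0)
        topo = topology(build_network(corr_from(r), 0.9))
        assert topo["avg_clustering"] == pytest.approx((1 + 1 + 1 / 3 + 0) / 4)

    def test_empty_network_errors(self):
        r = np.eye(5)
        with pytest.raises(ValidationError):
            build_network(corr_from(r), 0.5)


def two_cliques(k=6):
    g = nx.Graph()
    a = [f"a{i}" for i in range(k)]
    b = [f"b{i}" for i in range(k)]
    g.add_edges_from(itertools.combinations(a, 2))
    g.add_edges_from(itertools.combinations(b, 2))
    return g, a, b


class TestModules:
    def test_two_cliques_modularity_half(self):
        g, a, b = two_cliques()
        part = modules_and_relative_modularity(g, n_null=10, seed=0)
        assert part.modularity == pytest.approx(0.5)
        assert len(set(part.membership.values())) == 2
        assert {part.membership[x] for x in a} != {part.membership[x] for x in b}

    def test_null_rewiring_preserves_degrees(self):
        g = nx.gnm_random_graph(30, 60, seed=1)
        h = g.copy()
        nx.double_edge_swap(h, nswap=600, max_tries=20000, seed=2)
        assert sorted(d for _, d in h.degree()) == sorted(d for _, d in g.degree())

    def test_planted_partition_recovery(self):
        g = nx.planted_partition_graph(4, 15, 0.9, 0.05, seed=7)
        part = modules_and_relative_modularity(g, n_null=10, seed=0)
        truth = [g.nodes[v]["block"] for v in sorted(g.nodes())]
        found = [part.membership[v] for v in sorted(g.nodes())]
        assert adjusted_rand_score(truth, found) > 0.9

    def test_relative_modularity_positive_for_modular_graph(self):
        g, _, _ = two_cliques()
        g.add_edge("a0", "b0")  # keep it swappable
        part = modules_and_relative_modularity(g, n_null=20, seed=3)
        assert part.relative_modularity > 0
        assert len(part.null_modularities) == 20


class TestNodeRoles:
    def test_all_links_inside_module_pi_zero(self):
        g, a, b = two_cliques()
        part = ModulePartition({**{x: 0 for x in a}, **{x: 1 for x in b}}, 0.5, 0.0)
        roles = {r.node: r for r in node_roles(g, part)}
        assert roles["a0"].pi == 0.0

    def test_even_split_pi_half(self):
        g = nx.Graph()
        g.add_edges_from([("x", "a0"), ("x", "b0"), ("a0", "a1"), ("b0", "b1")])
        part = ModulePartition({"x": 0, "a0": 0, "a1": 0, "b0": 1, "b1": 1}, 0.0, 0.0)
        roles = {r.node: r for r in node_roles(g, part)}
        assert roles["x"].pi == pytest.approx(0.5)

    def test_bridged_cliques_hand_computation(self):
        # bridge node linked to 3 members of each 6-clique, assigned to module A
        g, a, b = two_cliques()
        for v in a[:3] + b[:3]:
            g.add_edge("bridge", v)
        membership = {**{x: 0 for x in a}, **{x: 1 for x in b}, "bridge": 0}
        roles = {r.node: r for r in node_roles(g, ModulePartition(membership, 0.0, 0.0))}
        # hand calculation: module A has within-degrees [6,6,6,5,5,5,3]
        k_within = np.array([6, 6, 6, 5, 5, 5, 3])
        zi_expected = (3 - k_within.mean()) / k_within.std()
        assert roles["bridge"].zi == pytest.approx(zi_expected)
        assert roles["bridge"].pi == pytest.approx(1 - 2 * 0.5**2)
        # Pi = 0.5 sits below the 0.62 connector cut-off, so the bridge is
        # peripheral under the standard role taxonomy
        assert roles["bridge"].role == "peripheral"

    def test_zi_standardized_within_modules(self):
        g = nx.gnm_random_graph(40, 120, seed=9)
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes()})
        part = modules_and_relative_modularity(g, n_null=10, seed=0)
        roles = node_roles(g, part)
        df = pd.DataFrame([vars(r) for r in roles])
        df["module"] = df.node.map(part.membership)
        for _, grp in df.groupby("module"):
            if len(grp) > 1 and grp.zi.std() > 0:
                assert grp.zi.mean() == pytest.approx(0.0, abs=1e-9)
                assert grp.zi.to_numpy().std() == pytest.approx(1.0, abs=1e-9)

    def test_keystone_fraction(self):
        roles = [
            conet.NodeRole("a", 0, 0, "peripheral"),
            conet.NodeRole("b", 3, 0, "module_hub"),
            conet.NodeRole("c", 0, 0.7, "connector"),
            conet.NodeRole("d", 0, 0, "peripheral"),
        ]
        assert keystone_fraction(roles) == 0.5


class TestEigengenes:
    def test_rank_one_module(self):
        # identical member profiles: eigengene is the standardized profile
        profile = np.array([10, 40, 20, 80, 30, 60])
        counts = np.vstack([profile, profile * 2, profile * 4, [7, 7, 7, 7, 7, 7]])
        t = CountTable(["m1", "m2", "m3", "x"], [f"s{i}" for i in range(6)], counts)
        g = nx.Graph()
        g.add_nodes_from(["m1", "m2", "m3"])
        part = ModulePartition({"m1": 0, "m2": 0, "m3": 0}, 0.0, 0.0)
        env = pd.DataFrame({"cov": np.arange(6.0)}, index=[f"s{i}" for i in range(6)])
        out = conet.module_eigengenes(g, part, t, env)
        # exact up to the half-count pseudocount perturbation
        assert out.explained_var.iloc[0] == pytest.approx(1.0, abs=1e-3)

    def test_sign_invariance_of_correlation_magnitude(self):
        rng = np.random.default_rng(11)
        counts = rng.integers(1, 200, size=(5, 8))
        t = CountTable([f"m{i}" for i in range(5)], [f"s{j}" for j in range(8)], counts)
        g = nx.Graph()
        g.add_nodes_from(t.feature_ids)
        part = ModulePartition({f: 0 for f in t.feature_ids}, 0.0, 0.0)
        env = pd.DataFrame({"cov": rng.normal(size=8)}, index=t.sample_ids)
        out = conet.module_eigengenes(g, part, t, env)
        # orientation rule pins the sign: recomputation is identical
        out2 = conet.module_eigengenes(g, part, t, env)
        assert out.r.iloc[0] == out2.r.iloc[0]
        assert abs(out.r.iloc[0]) <= 1.0

    def test_temperature_module_tracked(self):
        # the generator's first prokaryotic module follows soil temperature
        cfg = datagen.GeneratorConfig(seed=5)
        experiment, truth = datagen.generate_experiment(cfg)
        members = [f for f, mod in truth.module_membership.items() if mod == "pASV_mod0"]
        g = nx.Graph()
        g.add_nodes_from(members)
        part = ModulePartition({f: 0 for f in members}, 0.0, 0.0)
        env = pd.DataFrame({m.sample_id: m.env for m in experiment.metadata}).T
        out = conet.module_eigengenes(g, part, experiment.asv_prok, env)
        row = out[out.covariate == "soil_temperature"].iloc[0]
        assert abs(row.r) > 0.8


class TestPlantedModuleRecovery:
    def test_threshold_separates_planted_from_background(self):
        # frozen seed-3 run: planted within-module edges survive the RMT
        # threshold far above the background pair rate in both arms
        cfg = datagen.GeneratorConfig(seed=3)
        experiment, truth = datagen.generate_experiment(cfg)
        table = rarefy_table(experiment.asv_prok, min_depth(experiment.asv_prok), 1)
        member = truth.module_membership
        rates = {}
        for trt in ("control", "warming"):
            ids_t = [m.sample_id for m in experiment.metadata if m.treatment == trt]
            c = prepare_matrix(table, ids_t)
            g = build_network(c, rmt_threshold(c))
            within = bg = wr = br = 0
            for i, j in itertools.combinations(range(len(c.feature_ids)), 2):
                fi, fj = c.feature_ids[i], c.feature_ids[j]
                has = g.has_edge(fi, fj)
                if member.get(fi) is not None and member.get(fi) == member.get(fj):
                    within += 1
                    wr += has
                else:
                    bg += 1
                    br += has
            rates[trt] = (wr / within, br / bg)
        # recorded values: control ~(0.77, 0.034), warming ~(0.96, 0.069)
        assert rates["control"][0] > 0.7 and rates["control"][1] < 0.05
        assert rates["warming"][0] > 0.9 and rates["warming"][1] < 0.10
        # the warming boost makes warming modules denser
        assert rates["warming"][0] > rates["control"][0]
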