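"""Network construction, modules, Zi-Pi roles and keystone comparison."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from rhizonet import network as net
from rhizonet import synth, diversity

from conftest import brute_spearman


def _table(rows, samples=None, otus=None):
    rows = np.atleast_2d(rows)
    return pd.DataFrame(rows,
                        index=samples or [f"s{i}" for i in range(len(rows))],
                        columns=otus or [f"o{j}" for j in range(rows.shape[1])])


class TestPrevalenceFilter:
    def test_strict_boundary_at_half(self):
        # 23/44 kept, 22/44 dropped
        col_23 = [1] * 23 + [0] * 21
        col_22 = [1] * 22 + [0] * 22
        t = _table(np.column_stack([col_23, col_22, [1] * 44]),
                   otus=["kept", "dropped", "always"])
        out = net.prevalence_filter(t, 0.5)
        assert list(out.columns) == ["kept", "always"]

    def test_all_present_unchanged(self):
        t = _table([[1, 2], [3, 4], [5, 6]])
        pd.testing.assert_frame_equal(net.prevalence_filter(t, 0.5), t)

    def test_nothing_surviving_reports_max(self):
        t = _table([[1, 0], [0, 1], [0, 0], [0, 0]])
        with pytest.raises(ValueError, match="0.25"):
            net.prevalence_filter(t, 0.5)


class TestCorrelationEdges:
    def test_perfect_positive_and_negative(self):
        x = np.arange(10.0)
        t = _table(np.column_stack([x, 2 * x + 1, 9 - x]), otus=["a", "b", "c"])
        edges = net.correlation_edges(t, rho_min=0.6, p_max=0.05)
        pairs = {frozenset((r.otu_a, r.otu_b)): r.rho for r in edges.itertuples()}
        assert pairs[frozenset(("a", "b"))] == pytest.approx(1.0)
        assert pairs[frozenset(("a", "c"))] == pytest.approx(-1.0)

    def test_matches_brute_force_rank_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            x = rng.integers(0, 5, size=8).astype(float)
            y = rng.integers(0, 5, size=8).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            t = _table(np.column_stack([x, y]))
            edges = net.correlation_edges(t, rho_min=-1.0, p_max=1.1)
            assert edges["rho"].iloc[0] == pytest.approx(
                brute_spearman(x, y), abs=1e-12)

    def test_zero_variance_excluded_with_warning(self):
        rng = np.random.default_rng(2)
        t = _table(np.column_stack([rng.normal(size=8), np.full(8, 3.0)]))
        with pytest.warns(UserWarning, match="zero-variance"):
            edges = net.correlation_edges(t, rho_min=0.0, p_max=1.1)
        assert len(edges) == 0

    def test_planted_pairs_recovered_exactly(self):
        # two perfectly correlated pairs among independent noise: the
        # thresholded edge set is exactly the planted pairs, signs correct
        rng = np.random.default_rng(5)
        n = 30
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        noise = rng.normal(size=(n, 6))
        t = _table(np.column_stack([x, 3 * x + 1, z, -2 * z, noise]),
                   otus=["p1", "p2", "n1", "n2"] + [f"x{i}" for i in range(6)])
        edges = net.correlation_edges(t, rho_min=0.6, p_max=0.05)
        found = {frozenset((r.otu_a, r.otu_b)): r.rho for r in edges.itertuples()}
        assert set(found) == {frozenset(("p1", "p2")), frozenset(("n1", "n2"))}
        assert found[frozenset(("p1", "p2"))] > 0
        assert found[frozenset(("n1", "n2"))] < 0

    def test_edge_set_monotone_in_rho_min(self):
        rng = np.random.default_rng(7)
        t = _table(rng.integers(0, 40, size=(12, 10)))
        loose = net.correlation_edges(t, rho_min=0.3, p_max=0.5)
        tight = net.correlation_edges(t, rho_min=0.6, p_max=0.5)
        as_set = lambda e: {frozenset((r.otu_a, r.otu_b)) for r in e.itertuples()}
        assert as_set(tight) <= as_set(loose)

    def test_invariant_to_sample_permutation_and_monotone_transform(self):
        rng = np.random.default_rng(11)
        t = _table(rng.integers(0, 40, size=(12, 6)))
        base = net.correlation_edges(t, rho_min=0.3, p_max=0.5)
        shuffled = t.iloc[rng.permutation(12)]
        transformed = np.log1p(shuffled)
        other = net.correlation_edges(transformed, rho_min=0.3, p_max=0.5)
        key = lambda e: sorted((tuple(sorted((r.otu_a, r.otu_b))), round(r.rho, 9))
                               for r in e.itertuples())
        assert key(base) == key(other)


class TestDetectModules:
    def test_two_disjoint_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        modules, q = net.detect_modules(g, seed=0)
        assert q == pytest.approx(0.5, abs=1e-12)
        parts = {frozenset(n for n in g if modules[n] == m)
                 for m in set(modules.values())}
        assert parts == {frozenset(range(5)), frozenset(range(5, 10))}

    def test_single_clique(self):
        g = nx.complete_graph(4)
        modules, q = net.detect_modules(g, seed=0)
        assert len(set(modules.values())) == 1
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_edgeless_graph(self):
        g = nx.empty_graph(5)
        modules, q = net.detect_modules(g, seed=0)
        assert len(set(modules.values())) == 5
        assert q == 0.0

    def test_q_matches_networkx(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            g = nx.gnp_random_graph(20, 0.2, seed=int(rng.integers(1e6)))
            if g.number_of_edges() == 0:
                continue
            modules, q = net.detect_modules(g, seed=1)
            comms = {}
            for node, m in modules.items():
                comms.setdefault(m, set()).add(node)
            assert q == pytest.approx(
                nx.community.modularity(g, comms.values()), abs=1e-12)

    def test_planted_three_block_recovery(self):
        from sklearn.metrics import adjusted_rand_score
        sizes = [20, 20, 20]
        labels = np.repeat([0, 1, 2], 20)
        ok = 0
        for seed in range(20):
            g = nx.stochastic_block_model(
                sizes, [[0.6, 0.02, 0.02], [0.02, 0.6, 0.02], [0.02, 0.02, 0.6]],
                seed=seed)
            modules, _ = net.detect_modules(g, seed=seed)
            found = [modules[i] for i in range(60)]
            ok += adjusted_rand_score(labels, found) >= 0.9
        assert ok == 20


class TestZiPi:
    def test_all_links_internal_gives_pi_zero(self):
        g = nx.complete_graph(4)
        modules = {n: 0 for n in g}
        roles = net.zi_pi(g, modules)
        assert (roles["pi"] == 0).all()

    def test_even_split_gives_pi_half(self):
        g = nx.star_graph(4)  # hub 0 with leaves 1-4
        modules = {0: 0, 1: 0, 2: 0, 3: 1, 4: 1}
        roles = net.zi_pi(g, modules)
        assert roles.loc[0, "pi"] == pytest.approx(0.5)

    def test_constant_within_degree_gives_zi_zero(self):
        g = nx.cycle_graph(4)
        modules = {n: 0 for n in g}
        roles = net.zi_pi(g, modules)
        assert (roles["zi"] == 0).all()

    def test_brute_force_recount_on_random_graphs(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(5, 31))
            g = nx.gnp_random_graph(n, 0.25, seed=int(rng.integers(1e6)))
            modules = {node: int(rng.integers(0, 4)) for node in g}
            roles = net.zi_pi(g, modules)
            for node in g:
                k = g.degree(node)
                per_mod = {}
                for nbr in g.neighbors(node):
                    per_mod[modules[nbr]] = per_mod.get(modules[nbr], 0) + 1
                pi = 1 - sum((c / k) ** 2 for c in per_mod.values()) if k else 0.0
                mates = [j for j in g if modules[j] == modules[node]]
                kin = [sum(1 for nb in g.neighbors(j)
                           if modules[nb] == modules[node]) for j in mates]
                sd = np.std(kin)
                zi = ((kin[mates.index(node)] - np.mean(kin)) / sd) if sd > 0 else 0.0
                assert roles.loc[node, "pi"] == pytest.approx(pi, abs=1e-12)
                assert roles.loc[node, "zi"] == pytest.approx(zi, abs=1e-12)

    def test_roles_partition_and_boundaries(self):
        cases = [(-1.0, 0.0, "peripheral"), (2.5, 0.62, "peripheral"),
                 (2.0, 0.7, "connector"), (3.0, 0.5, "provincial_hub"),
                 (3.0, 0.7, "kinless_hub"), (2.5, 0.9, "connector"),
                 (4.0, 0.62, "provincial_hub")]
        for zi, pi, expected in cases:
            assert net.classify_role(zi, pi) == expected


class TestKeystones:
    @staticmethod
    def _roles(df_rows):
        return pd.DataFrame(df_rows, columns=["otu", "zi", "pi", "role"]).set_index("otu")

    def test_all_peripheral_gives_empty_set(self, small_taxonomy):
        roles = self._roles([["OTU_1", 0.1, 0.0, "peripheral"],
                             ["OTU_2", -1.0, 0.2, "peripheral"]])
        table = _table([[10, 20], [5, 5]], otus=["OTU_1", "OTU_2"])
        report = net.keystone_taxa(roles, small_taxonomy, table)
        assert len(report.table) == 0
        assert report.share == 0.0

    def test_share_is_read_fraction(self, small_taxonomy):
        roles = self._roles([["OTU_1", 3.0, 0.1, "provincial_hub"],
                             ["OTU_2", 0.0, 0.0, "peripheral"]])
        table = _table([[10, 30], [20, 40]], otus=["OTU_1", "OTU_2"])
        report = net.keystone_taxa(roles, small_taxonomy, table)
        assert report.share == pytest.approx(30 / 100)
        assert report.table.loc["OTU_1", "genus"] == "Dioszegia"

    def test_planted_hub_recovered_as_keystone(self):
        # well-powered design: the planted high-fidelity hubs of two blocks
        # should surface as non-peripheral nodes of the thresholded network
        recovered = 0
        for seed in range(10):
            otus = [f"OTU_{i + 1:04d}" for i in range(150)]
            mods = tuple(
                synth.PlantedModule(members=tuple(otus[k:k + 31]),
                                    loading=1.1, hub=otus[k])
                for k in (0, 31))
            cfg = synth.SynthConfig(seed=seed, n_sites=40, n_otus=150, modules=mods)
            counts, tax, meta, truth = synth.generate(cfg)
            rare = diversity.rarefy(counts, seed=0)
            sub = rare.loc[meta.loc[rare.index, "group"] == "AP"]
            graph = net.build_network(net.prevalence_filter(sub, 0.5), tax)
            modules, _ = net.detect_modules(graph, seed=0)
            roles = net.zi_pi(graph, modules)
            hubs = [h for h in truth.hubs if h in roles.index]
            recovered += any(roles.loc[h, "role"] != "peripheral" for h in hubs)
        assert recovered >= 8


class TestCompareKeystones:
    def test_identical_abundances_not_flagged(self, small_taxonomy):
        roles = pd.DataFrame([["OTU_1", 3.0, 0.1, "provincial_hub"]],
                             columns=["otu", "zi", "pi", "role"]).set_index("otu")
        table = _table(np.tile([10, 20], (6, 1)), otus=["OTU_1", "OTU_2"])
        meta = pd.DataFrame({"group": ["AP"] * 3 + ["N"] * 3}, index=table.index)
        rep = net.KeystoneReport("AP", roles.assign(genus="g"), 0.3)
        out = net.compare_keystones(rep, net.KeystoneReport("N", roles.iloc[:0], 0.0),
                                    table, meta)
        assert not out["significant"].any()

    def test_bh_adjustment_monotone(self, survey):
        counts, tax, meta, _ = survey
        rel_cols = counts.columns[:6]
        roles = pd.DataFrame(
            [[o, 3.0, 0.1, "provincial_hub"] for o in rel_cols],
            columns=["otu", "zi", "pi", "role"]).set_index("otu")
        rep = net.KeystoneReport("AP", roles, 0.1)
        out = net.compare_keystones(rep, net.KeystoneReport("N", roles.iloc[:0], 0.0),
                                    counts, meta)
        assert (out["p_adj"] >= out["p"] - 1e-15).all()

    def test_planted_enriched_keystone_flagged(self, survey):
        counts, tax, meta, truth = survey
        marker = truth.biomarkers[0]          # 8-fold enriched OTU
        roles = pd.DataFrame([[marker.otu, 3.0, 0.1, "provincial_hub"]],
                             columns=["otu", "zi", "pi", "role"]).set_index("otu")
        rep = net.KeystoneReport("AP", roles, 0.1)
        out = net.compare_keystones(rep, net.KeystoneReport("N", roles.iloc[:0], 0.0),
                                    counts, meta)
        assert out.loc[marker.otu, "significant"]
        assert out.loc[marker.otu, "higher_in"] == marker.group


class TestTopologySummary:
    def test_path_graph_hand_values(self):
        g = nx.path_graph(3)
        topo = net.topology_summary(g)
        assert topo.average_degree == pytest.approx(4 / 3)
        assert topo.average_clustering == 0.0
        assert topo.average_path_length == pytest.approx(4 / 3)

    def test_triangle(self):
        g = nx.complete_graph(3)
        topo = net.topology_summary(g)
        assert topo.average_clustering == pytest.approx(1.0)
        assert topo.average_path_length == pytest.approx(1.0)
        assert topo.edge_count == 3

    def test_average_degree_formula(self):
        g = nx.path_graph(4)  # 4 nodes, 3 edges
        topo = net.topology_summary(g)
        assert topo.average_degree == pytest.approx(1.5)

    def test_positive_negative_fractions_sum_to_one(self, survey):
        counts, tax, meta, _ = survey
        rare = diversity.rarefy(counts, seed=0)
        sub = rare.loc[meta.loc[rare.index, "group"] == "AP"]
        graph = net.build_network(net.prevalence_filter(sub, 0.5), tax)
        topo = net.topology_summary(graph)
        neg = sum(1 for *_, d in graph.edges(data=True) if d["rho"] < 0)
        assert topo.positive_edge_fraction + neg / topo.edge_count == pytest.approx(1.0)

    def test_empty_graph_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            topo = net.topology_summary(nx.Graph())
        assert topo.node_count == 0
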