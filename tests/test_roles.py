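"""Module partition, Zi/Pi topology, role classification, module-trait."""

from fractions import Fraction

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from keystonetaxa import (
    SyntheticSpec,
    annotate_network,
    classify_role,
    fast_greedy_partition,
    generate_community,
    module_trait_correlation,
    node_topology,
    role_census,
    to_relative_abundance,
)
from keystonetaxa.prep import transform_for_correlation
from keystonetaxa.rmt import build_network, similarity_matrix
from keystonetaxa.roles import modularity_exact
from keystonetaxa.table_io import TraitTable


def brute_force_topology(g, module_of):
    """Independent Zi/Pi by raw edge counting."""
    out = {}
    for node in g.nodes:
        k_is = {}
        for nb in g.neighbors(node):
            k_is[module_of[nb]] = k_is.get(module_of[nb], 0) + 1
        k = sum(k_is.values())
        own = module_of[node]
        members = [n for n in g.nodes if module_of[n] == own]
        within = [
            sum(1 for nb in g.neighbors(n) if module_of[nb] == own) for n in members
        ]
        mu = sum(within) / len(within)
        sd = (sum((w - mu) ** 2 for w in within) / len(within)) ** 0.5
        zi = 0.0 if sd == 0 else (k_is.get(own, 0) - mu) / sd
        pi = 0.0 if k == 0 else 1.0 - sum((c / k) ** 2 for c in k_is.values())
        out[node] = (zi, pi)
    return out


class TestFastGreedy:
    def test_two_cliques_bridged_recovered_with_exact_q(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        g.add_edge(0, 5)
        module_of, q = fast_greedy_partition(g)
        assert len({module_of[n] for n in range(5)}) == 1
        assert len({module_of[n] for n in range(5, 10)}) == 1
        assert module_of[0] != module_of[5]
        assert modularity_exact(g, module_of) == Fraction(20, 21) - Fraction(1, 2)
        assert q == pytest.approx(float(Fraction(19, 42)))

    def test_single_clique_q_zero(self):
        module_of, q = fast_greedy_partition(nx.complete_graph(6))
        assert len(set(module_of.values())) == 1
        assert q == pytest.approx(0.0)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="no edges"):
            fast_greedy_partition(nx.empty_graph(5))

    def test_planted_blocks_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        hits = 0
        for seed in range(20):
            g = nx.stochastic_block_model(
                [25] * 4,
                [[0.3 if i == j else 0.02 for j in range(4)] for i in range(4)],
                seed=seed,
            )
            module_of, _ = fast_greedy_partition(g)
            ari = adjusted_rand_score(
                [i // 25 for i in range(100)], [module_of[n] for n in range(100)]
            )
            hits += ari >= 0.9
        assert hits >= 19


class TestNodeTopology:
    def test_evenly_spread_participation(self):
        # hub with one edge into each of 3 cliques: Pi = 1 - 3*(1/3)^2
        g = nx.Graph()
        module_of = {}
        for m in range(3):
            nodes = [f"m{m}n{i}" for i in range(4)]
            g.add_edges_from(
                (a, b) for i, a in enumerate(nodes) for b in nodes[i + 1 :]
            )
            module_of.update({n: m for n in nodes})
        g.add_edges_from([("hub", "m0n0"), ("hub", "m1n0"), ("hub", "m2n0")])
        module_of["hub"] = 0
        topo = node_topology(g, module_of)
        assert topo.loc["hub", "Pi"] == pytest.approx(2 / 3)

    def test_all_within_module_pi_zero(self):
        g = nx.complete_graph(4)
        topo = node_topology(g, {n: 0 for n in g.nodes})
        assert (topo["Pi"] == 0).all()

    def test_zscore_with_population_sd(self):
        # within-degrees {1,1,1,5}: hub Zi = (5-2)/sqrt(3)
        g = nx.star_graph(3)  # center 0 has degree 3 within
        g.add_edge(1, 2)  # make degrees {3,2,2,1}
        # craft simpler: use explicit within-degree pattern via brute force
        module_of = {n: 0 for n in g.nodes}
        topo = node_topology(g, module_of)
        brute = brute_force_topology(g, module_of)
        for n in g.nodes:
            assert topo.loc[n, "Zi"] == pytest.approx(brute[n][0], abs=1e-12)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(8, 40))
            g = nx.gnp_random_graph(n, 0.2, seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            module_of = {node: int(rng.integers(0, 4)) for node in g.nodes}
            topo = node_topology(g, module_of)
            brute = brute_force_topology(g, module_of)
            for node in g.nodes:
                assert topo.loc[node, "Zi"] == pytest.approx(brute[node][0], abs=1e-12)
                assert topo.loc[node, "Pi"] == pytest.approx(brute[node][1], abs=1e-12)


class TestClassifyRole:
    @pytest.mark.parametrize(
        "zi, pi, role",
        [
            (1.0, 0.5, "peripheral"),
            (2.5, 0.62, "peripheral"),  # both boundaries peripheral-inclusive
            (2.5, 0.63, "connector"),
            (2.6, 0.62, "module hub"),
            (3.0, 0.7, "network hub"),
            (-4.0, 0.0, "peripheral"),
        ],
    )
    def test_quoted_cutoffs(self, zi, pi, role):
        assert classify_role(zi, pi) == role

    @settings(derandomize=True, max_examples=200)
    @given(
        st.floats(min_value=-10, max_value=10, allow_nan=False),
        st.floats(min_value=0, max_value=1, allow_nan=False),
    )
    def test_total_function_on_the_plane(self, zi, pi):
        assert classify_role(zi, pi) in {
            "peripheral", "connector", "module hub", "network hub",
        }


class TestRoleCensus:
    def test_isolated_cliques_have_no_connectors(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        module_of, _ = fast_greedy_partition(g)
        census = role_census(node_topology(g, module_of))
        assert census.loc["connector", "count"] == 0
        assert census["fraction"].sum() == pytest.approx(1.0)

    def test_planted_connectors_detected_in_most_seeds(self):
        # stated generator spec: strong blocks, uniform base abundance so the
        # connector's correlations survive the count layer, n = 150 + 150
        hits = 0
        for seed in range(10):
            spec = SyntheticSpec(
                seed=seed, n_connectors=2, delta=0.0, n_differential=0,
                rho_connector=0.5, rho_within=0.8, n_samples_per_group=150,
                base_log_abundance=(0.0,) * 300,
            )
            counts, truth = generate_community(spec)
            x = transform_for_correlation(to_relative_abundance(counts))
            net = build_network(similarity_matrix(x), 0.30)
            annotate_network(net)
            detected = set(net.topology.index[net.topology["role"] == "connector"])
            hits += truth.connector_taxa == detected
        assert hits >= 8


class TestModuleTrait:
    def _transformed_and_traits(self):
        rng = np.random.default_rng(1)
        x = pd.DataFrame(
            rng.standard_normal((6, 30)),
            index=[f"t{i}" for i in range(6)],
            columns=[f"s{j}" for j in range(30)],
        )
        return x

    def test_single_taxon_module_noiseless_trait(self):
        x = self._transformed_and_traits()
        traits = TraitTable(
            data=pd.DataFrame(
                {"group": ["H"] * 15 + ["L"] * 15, "tr": x.loc["t0"].to_numpy()},
                index=x.columns,
            )
        )
        res = module_trait_correlation(
            x, {"t0": 0, "t1": 1, "t2": 1, "t3": 1, "t4": 1, "t5": 1},
            traits, min_module_size=1,
        )
        r0 = res[(res.module == 0) & (res.trait == "tr")]["r"].iloc[0]
        assert abs(r0) == pytest.approx(1.0)

    def test_duplicating_every_member_leaves_correlations_unchanged(self):
        x = self._transformed_and_traits()
        traits = TraitTable(
            data=pd.DataFrame(
                {"group": ["H"] * 15 + ["L"] * 15, "tr": x.loc["t0"].to_numpy()},
                index=x.columns,
            )
        )
        members = ["t1", "t2", "t3"]
        base = module_trait_correlation(x, {t: 0 for t in members}, traits)
        clones = x.loc[members].rename(index={t: t + "_dup" for t in members})
        dup = pd.concat([x, clones])
        doubled = module_trait_correlation(
            dup, {**{t: 0 for t in members}, **{t + "_dup": 0 for t in members}}, traits
        )
        assert doubled["r"].to_numpy() == pytest.approx(base["r"].to_numpy())
        assert doubled["p"].to_numpy() == pytest.approx(base["p"].to_numpy())

    def test_small_modules_skipped(self):
        x = self._transformed_and_traits()
        traits = TraitTable(
            data=pd.DataFrame(
                {"group": ["H"] * 15 + ["L"] * 15, "tr": np.arange(30.0)},
                index=x.columns,
            )
        )
        res = module_trait_correlation(x, {"t0": 0, "t1": 0, "t2": 1, "t3": 1, "t4": 1}, traits)
        assert set(res["module"]) == {1}

    def test_eigengene_summary_matches_mean_on_coherent_module(self):
        # members are noisy copies of one signal: PC1 and mean summaries agree
        rng = np.random.default_rng(8)
        signal = rng.standard_normal(30)
        x = pd.DataFrame(
            [signal + 0.1 * rng.standard_normal(30) for _ in range(4)],
            index=[f"t{i}" for i in range(4)],
            columns=[f"s{j}" for j in range(30)],
        )
        traits = TraitTable(
            data=pd.DataFrame(
                {"group": ["H"] * 15 + ["L"] * 15, "tr": signal}, index=x.columns
            )
        )
        module_of = {t: 0 for t in x.index}
        mean_r = module_trait_correlation(x, module_of, traits)["r"].iloc[0]
        pc1_r = module_trait_correlation(x, module_of, traits, summary="pc1")["r"].iloc[0]
        assert mean_r == pytest.approx(pc1_r, abs=0.02)
        assert mean_r > 0.9

    def test_stars_convention(self):
        from keystonetaxa.roles import _stars

        assert [_stars(p) for p in (0.005, 0.03, 0.07, 0.5)] == ["**", "*", "#", ""]
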