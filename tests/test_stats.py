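"""Statistical screens against independent brute-force oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from keystonetaxa import (
    SyntheticSpec,
    anosim,
    bh_adjust,
    bray_curtis,
    differential_screen,
    generate_dataset,
    pcoa,
    rank_sum_test,
    spearman,
    to_relative_abundance,
    trait_screen,
    welch_t_test,
)
from keystonetaxa.prep import RelativeAbundanceTable
from keystonetaxa.stats import cooccurrence_network


def brute_force_rank_sum_p(x, y):
    """Exact two-sided p by enumerating every assignment of ranks."""
    pooled = np.concatenate([x, y])
    n = len(pooled)
    ranks = pd.Series(pooled).rank().to_numpy()
    obs = ranks[: len(x)].sum()
    mean = len(x) * (n + 1) / 2
    count = total = 0
    for idx in combinations(range(n), len(x)):
        s = ranks[list(idx)].sum()
        total += 1
        if abs(s - mean) >= abs(obs - mean) - 1e-12:
            count += 1
    return count / total


class TestRankSum:
    def test_extreme_arrangement_exact_p(self):
        # [1,2,3] vs [4,5,6]: 2 of the 20 rank splits are as extreme
        _, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)
        assert p == pytest.approx(brute_force_rank_sum_p([1, 2, 3], [4, 5, 6]))

    def test_matches_enumeration_on_random_small_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            x = rng.permutation(20)[: rng.integers(2, 5)].astype(float)
            y = rng.permutation(np.arange(20, 40))[: rng.integers(2, 5)].astype(float)
            _, p = rank_sum_test(x, y)
            assert p == pytest.approx(brute_force_rank_sum_p(x, y), abs=1e-12)

    def test_identical_groups_p_one(self):
        _, p = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.99

    def test_label_swap_symmetry(self):
        x, y = [1.2, 3.4, 2.2, 9.9], [0.5, 4.4, 7.7]
        assert rank_sum_test(x, y)[1] == pytest.approx(rank_sum_test(y, x)[1])


class TestWelch:
    def test_identical_groups(self):
        t, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_closed_form_value(self):
        # means 2.5 vs 3.5, each sample var 5/3 -> se^2 = (5/3)/4 * 2 = 5/6
        t, _ = welch_t_test([1, 2, 3, 4], [2, 3, 4, 5])
        assert t == pytest.approx(-1 / np.sqrt(5 / 6), abs=1e-9)

    def test_sign_flip_flips_t_keeps_p(self):
        x, y = [1.0, 4.0, 2.0], [3.0, 5.0, 9.0]
        t1, p1 = welch_t_test(x, y)
        t2, p2 = welch_t_test([-v for v in x], [-v for v in y])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)


class TestSpearman:
    def test_monotone_identity_and_reversal(self):
        x = [1.0, 2.0, 3.0, 5.0]
        assert spearman(x, x)[0] == pytest.approx(1.0)
        assert spearman(x, x[::-1])[0] == pytest.approx(-1.0)

    def test_rank_formula_example(self):
        rho, _ = spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8)


class TestBH:
    def test_hand_stepped_example(self):
        q = bh_adjust([0.01, 0.04, 0.03, 0.005])
        assert q == pytest.approx([0.02, 0.04, 0.04, 0.02])

    def test_equal_ps_unchanged_and_single_p_identity(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])
        assert bh_adjust([0.07]) == pytest.approx([0.07])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=20),
        st.data(),
    )
    def test_shrinking_any_p_never_loses_discoveries(self, ps, data):
        q_before = bh_adjust(ps)
        i = data.draw(st.integers(min_value=0, max_value=len(ps) - 1))
        shrunk = list(ps)
        shrunk[i] = shrunk[i] / 2
        q_after = bh_adjust(shrunk)
        for alpha in (0.01, 0.05, 0.1):
            assert (q_after <= alpha).sum() >= (q_before <= alpha).sum()


class TestScreens:
    def test_planted_taxa_lead_q_ordering(self):
        spec = SyntheticSpec(seed=4, delta=1.5, n_differential=6)
        counts, traits, truth = generate_dataset(spec)
        res = differential_screen(to_relative_abundance(counts), traits)
        top = set(res.nsmallest(6, "q")["taxon"])
        assert len(top & set(truth.differential_taxa)) >= 4

    def test_enrichment_direction_matches_planted_sign(self):
        spec = SyntheticSpec(seed=9, delta=1.5, n_differential=4)
        counts, traits, truth = generate_dataset(spec)
        res = differential_screen(to_relative_abundance(counts), traits).set_index("taxon")
        for taxon, delta in truth.differential_taxa.items():
            if taxon in res.index and res.loc[taxon, "q"] < 0.05:
                assert res.loc[taxon, "enriched_in"] == ("H" if delta > 0 else "L")

    def test_trait_screen_missing_values_pairwise(self, small_dataset):
        counts, traits, _ = small_dataset
        data = traits.data.copy()
        data.iloc[0, data.columns.get_loc("ADG")] = np.nan
        from keystonetaxa.table_io import TraitTable

        res = trait_screen(
            to_relative_abundance(counts), TraitTable(data=data), trait_names=["ADG"]
        )
        assert (res["n"] == len(data) - 1).all()

    def test_cooccurrence_planted_pair_is_the_dominant_edge(self):
        # one near-duplicated taxon pair among independent taxa: the planted
        # edge has |rho| ~ 1; every other (compositional-closure) edge is weak
        rng = np.random.default_rng(2)
        n = 120
        base = rng.standard_normal(n)
        mat = np.vstack([base + 0.05 * rng.standard_normal(n)] * 2 +
                        [rng.standard_normal(n) for _ in range(8)])
        props = np.exp(mat) / np.exp(mat).sum(axis=0)
        rel = RelativeAbundanceTable(
            proportions=pd.DataFrame(props, index=[f"t{i}" for i in range(10)])
        )
        edges = cooccurrence_network(rel, floor=0.0, alpha=0.05)
        pairs = set(map(tuple, edges[["source", "target"]].to_numpy()))
        assert ("t0", "t1") in pairs
        others = edges[~((edges.source == "t0") & (edges.target == "t1"))]
        assert edges.set_index(["source", "target"]).loc[("t0", "t1"), "rho"] > 0.95
        assert (others["rho"].abs() < 0.4).all()

    def test_cooccurrence_degree_equals_edge_count(self):
        from keystonetaxa.stats import network_degrees

        rng = np.random.default_rng(3)
        mat = np.exp(rng.standard_normal((8, 60)))
        rel = RelativeAbundanceTable(
            proportions=pd.DataFrame(mat / mat.sum(axis=0), index=[f"t{i}" for i in range(8)])
        )
        edges = cooccurrence_network(rel, floor=0.0, alpha=0.5)
        deg = network_degrees(edges)
        for t in deg.index:
            assert deg[t] == ((edges.source == t) | (edges.target == t)).sum()


class TestBrayCurtis:
    def test_identical_disjoint_and_formula(self):
        rel = RelativeAbundanceTable(
            proportions=pd.DataFrame(
                {
                    "u": [0.5, 0.5, 0.0],
                    "v": [0.0, 0.5, 0.5],
                    "w": [0.5, 0.5, 0.0],
                    "x": [0.0, 0.0, 1.0],
                },
                index=list("abc"),
            )
        )
        d = bray_curtis(rel)
        assert d.loc["u", "w"] == pytest.approx(0.0)
        assert d.loc["w", "x"] == pytest.approx(1.0)  # disjoint support
        assert d.loc["u", "v"] == pytest.approx(0.5)  # [1,1,0] vs [0,1,1]


class TestPcoa:
    def test_euclidean_distances_reconstructed(self):
        rng = np.random.default_rng(3)
        pts = rng.standard_normal((8, 3))
        from scipy.spatial.distance import pdist, squareform

        d = pd.DataFrame(squareform(pdist(pts)))
        res = pcoa(d)
        back = squareform(pdist(res.coordinates.to_numpy()))
        assert np.allclose(back, d.to_numpy(), atol=1e-9)

    def test_equidistant_triple_gives_equal_eigenvalues(self):
        d = pd.DataFrame(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float))
        res = pcoa(d)
        pos = res.eigenvalues[res.eigenvalues > 1e-12]
        assert pos[0] == pytest.approx(pos[1])

    def test_agrees_with_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(4)
        pts = rng.standard_normal((10, 4))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(pts))
        ours = pcoa(pd.DataFrame(d))
        theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d), method="eigh")
        assert np.allclose(
            np.abs(ours.coordinates.to_numpy()[:, :3]),
            np.abs(theirs.samples.to_numpy()[:, :3]),
            atol=1e-8,
        )


class TestAnosim:
    def test_perfect_separation_r_one(self):
        rng = np.random.default_rng(5)
        pts = np.vstack([rng.normal(0, 0.01, (5, 2)), rng.normal(50, 0.01, (5, 2))])
        from scipy.spatial.distance import pdist, squareform

        d = pd.DataFrame(squareform(pdist(pts)))
        res = anosim(d, np.array(["a"] * 5 + ["b"] * 5), seed=0)
        assert res.R == pytest.approx(1.0)
        assert res.p >= 1 / 1000

    def test_agrees_with_scikit_bio_statistic(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(6)
        pts = rng.standard_normal((12, 4))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(pts))
        labels = np.array(["a"] * 6 + ["b"] * 6)
        ours = anosim(pd.DataFrame(d), labels, n_perm=99, seed=0)
        theirs = skbio.stats.distance.anosim(
            skbio.DistanceMatrix(d), labels, permutations=0
        )
        assert ours.R == pytest.approx(theirs["test statistic"], abs=1e-12)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(7)
        from scipy.spatial.distance import pdist, squareform

        d = pd.DataFrame(squareform(pdist(rng.standard_normal((10, 3)))))
        labels = np.array(["a"] * 5 + ["b"] * 5)
        assert anosim(d, labels, seed=42).p == anosim(d, labels, seed=42).p
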