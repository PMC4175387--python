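import itertools

import numpy as np
import pytest
from scipy import stats

from genenetval import (
    DEFAULT_THRESHOLDS,
    GeneNetwork,
    build_kgn,
    functional_assignment,
    noise_study,
    random_network,
    roc_study,
    sample_size,
)
from genenetval.evaluation import perturb_network, roc_from_scores


def path_network(k: int, prefix: str = "G") -> GeneNetwork:
    genes = [f"{prefix}{i}" for i in range(k)]
    return GeneNetwork(genes, zip(genes, genes[1:]), label=f"path{k}")


class TestRandomNetwork:
    def test_size_conserved(self):
        tpl = GeneNetwork("ABCDE", [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")])
        null = random_network(tpl, "pure_random", seed=4)
        assert null.genes == tpl.genes
        assert null.n_edges == tpl.n_edges

    def test_deterministic(self):
        tpl = path_network(10)
        assert random_network(tpl, "pure_random", 7) == random_network(
            tpl, "pure_random", 7
        )
        assert random_network(tpl, "scale_free", 7) == random_network(
            tpl, "scale_free", 7
        )

    def test_scale_free_same_genes_similar_size(self):
        tpl = path_network(30)
        null = random_network(tpl, "scale_free", seed=1)
        assert null.genes == tpl.genes
        # BA with m=1 over 30 nodes gives 29 edges vs the template's 29
        assert abs(null.n_edges - tpl.n_edges) <= tpl.n_edges * 0.2

    def test_too_many_edges_rejected(self):
        tpl = GeneNetwork("AB", [("A", "B")])
        tpl.edges.add(("A", "C"))  # force inconsistency artificially
        tpl.genes.add("C")
        tpl.edges.add(("B", "C"))
        tpl.edges.add(("A", "D"))
        with pytest.raises(ValueError):
            random_network(tpl, "pure_random", 0)

    def test_uniform_over_edge_sets(self):
        """Each 2-edge outcome over 4 genes appears ~uniformly (chi-square)."""
        tpl = GeneNetwork("ABCD", [("A", "B"), ("C", "D")])
        pairs = list(itertools.combinations(sorted(tpl.genes), 2))
        outcomes = list(itertools.combinations(pairs, 2))  # C(6,2) = 15
        index = {frozenset(o): i for i, o in enumerate(outcomes)}
        counts = np.zeros(len(outcomes))
        for seed in range(1500):
            null = random_network(tpl, "pure_random", seed=seed)
            counts[index[frozenset(null.edges)]] += 1
        assert stats.chisquare(counts).pvalue > 1e-3


class TestSampleSize:
    def test_classic_385(self):
        assert sample_size(0.95, 0.05, 0.5) == 385

    def test_99_percent(self):
        # z = 2.5758...: ceil(z^2 * 0.25 / 0.0025) = 664
        assert sample_size(0.99, 0.05, 0.5) == 664

    @pytest.mark.parametrize(
        "conf,margin,p", [(0.95, 0.05, 0.0), (0.0, 0.05, 0.5), (0.95, 1.5, 0.5)]
    )
    def test_out_of_range_rejected(self, conf, margin, p):
        with pytest.raises(ValueError):
            sample_size(conf, margin, p)


class TestRoc:
    def test_default_grid_has_101_thresholds(self):
        assert len(DEFAULT_THRESHOLDS) == 101
        assert DEFAULT_THRESHOLDS[0] == 0.0
        assert DEFAULT_THRESHOLDS[-1] == 1.0
        assert DEFAULT_THRESHOLDS[1] == pytest.approx(0.01)

    def test_perfect_separation(self):
        """Real validity 1, null validity small but positive: AUC = 1."""
        gold = path_network(12)
        real = gold.copy()
        null = GeneNetwork(gold.genes,
                           [("G0", "G1"), ("G0", "G11"), ("G1", "G10"),
                            ("G2", "G9"), ("G3", "G8")])
        res = roc_study(real, [gold], [null], n=2)
        assert res.auc == pytest.approx(1.0)
        # at threshold 0 every evaluation fires: the (1,1) point is achieved
        assert (1.0, 1.0) in res.points

    def test_identical_real_and_null_gives_half(self):
        gold = path_network(8)
        res = roc_study(gold.copy(), [gold], [gold.copy()], n=2)
        assert res.auc == pytest.approx(0.5)
        for c in res.confusion:
            assert c.tpr == pytest.approx(c.fpr)

    def test_confusion_counts_hand_example(self):
        """4-threshold toy sweep reproduces hand-computed confusion counts."""
        # one real network scoring V = (0.9, 0.6) on two pathways and one
        # null scoring (0.2, 0.05): thresholds 0, 0.3, 0.5, 1
        res = roc_from_scores([0.9, 0.6], [0.2, 0.05], thresholds=[0, 0.3, 0.5, 1])
        by_t = {c.threshold: c for c in res.confusion}
        assert (by_t[0].tp, by_t[0].fp, by_t[0].tn, by_t[0].fn) == (2, 2, 0, 0)
        assert (by_t[0.3].tp, by_t[0.3].fp) == (2, 0)
        assert (by_t[0.5].tp, by_t[0.5].fp) == (2, 0)
        assert (by_t[1].tp, by_t[1].fp, by_t[1].tn, by_t[1].fn) == (0, 0, 2, 2)
        for c in res.confusion:
            assert c.total == 4

    def test_strict_inequality_at_threshold(self):
        res = roc_from_scores([0.5], [0.5], thresholds=[0.5])
        assert res.confusion[0].tp == 0 and res.confusion[0].fp == 0

    def test_auc_matches_sklearn_on_random_scores(self):
        """Trapezoidal AUC equals sklearn's on a dense common grid."""
        from sklearn.metrics import auc as sk_auc

        rng = np.random.default_rng(0)
        for _ in range(20):
            pos = rng.uniform(0, 1, 30)
            neg = rng.uniform(0, 1, 30)
            res = roc_from_scores(pos, neg)
            fpr = [p[0] for p in res.points]
            tpr = [p[1] for p in res.points]
            assert res.auc == pytest.approx(sk_auc(fpr, tpr), abs=1e-9)

    def test_empty_pathways_rejected(self):
        gold = path_network(5)
        with pytest.raises(ValueError):
            roc_study(gold, [], [gold], n=1)

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            roc_from_scores([1.0], [0.0], thresholds=[-0.1, 0.5])


class TestNoise:
    def test_zero_perturbation_is_noop(self):
        net = path_network(5)
        rng = np.random.default_rng(0)
        assert perturb_network(net, 0.0, rng) == net

    def test_perturbation_preserves_size(self):
        net = path_network(20)
        rng = np.random.default_rng(3)
        noisy = perturb_network(net, 0.3, rng)
        assert noisy.n_edges == net.n_edges
        assert noisy.genes >= {g for e in noisy.edges for g in e}
        removed = net.edges - noisy.edges
        assert len(removed) == round(0.3 * net.n_edges)

    def test_tiny_network_noop_iteration(self):
        """round(k * 0.1 * ||E||) = 0 leaves validity untouched."""
        net = GeneNetwork("ABC", [("A", "B")])
        profile = noise_study(net, net, n=1, iterations=1, replicates=3, seed=0)
        # k=1: round(0.1 * 1) = 0 edges perturbed
        assert profile.records[0].mean_validity == pytest.approx(1.0)

    def test_deterministic(self):
        net = path_network(12)
        a = noise_study(net, net, n=2, replicates=5, seed=9).mean_series()
        b = noise_study(net, net, n=2, replicates=5, seed=9).mean_series()
        assert a == b

    def test_full_replacement_capped(self):
        net = path_network(10)
        profile = noise_study(net, net, n=1, iterations=12, replicates=2, seed=1)
        assert profile.records[-1].noise_fraction == pytest.approx(1.0)

    def test_degradation_trend(self):
        """Mean validity decreases as the noise fraction grows (self-match)."""
        rng = np.random.default_rng(5)
        genes = [f"G{i}" for i in range(15)]
        net = GeneNetwork(genes, label="dense")
        for i in range(15):
            for j in range(i + 1, 15):
                if rng.random() < 0.25:
                    net.add_edge(genes[i], genes[j])
        profile = noise_study(net, net, n=2, replicates=50, seed=11)
        means = profile.mean_series()
        rho, _ = stats.spearmanr(range(1, 11), means)
        assert rho < -0.8
        assert means[-1] < means[0]


class TestKgnAndAssignment:
    def test_single_pathway_identity(self):
        net = path_network(6)
        assert build_kgn([net]) == net

    def test_disjoint_union(self):
        a = path_network(4, "A")
        b = path_network(4, "B")
        kgn = build_kgn([a, b])
        assert kgn.n_edges == a.n_edges + b.n_edges
        assert kgn.genes == a.genes | b.genes

    def test_shared_edge_counted_once(self):
        a = GeneNetwork(edges=[("X", "Y"), ("Y", "Z")])
        b = GeneNetwork(edges=[("X", "Y"), ("W", "X")])
        assert build_kgn([a, b]).n_edges == 3
        assert build_kgn([a, b]).edges == a.edges | b.edges

    def test_idempotent_and_order_independent(self):
        a, b = path_network(5, "A"), path_network(3, "B")
        assert build_kgn([a, b]) == build_kgn([b, a]) == build_kgn([a, b, a])

    def test_matching_pathway_ranks_first(self):
        target = path_network(6, "T")
        other = path_network(6, "X")
        ranking = functional_assignment(target.copy(), [other, target], n=1)
        assert ranking[0][0] == target.label
        assert ranking[0][1].validity == pytest.approx(1.0)
        assert ranking[1][1].validity is None  # gene-disjoint: undefined, last

    def test_level1_pathway_beats_level2_pathway(self):
        """Direct hits weigh 1, two-step hits only 1/2."""
        g_i = GeneNetwork(edges=[("A", "B"), ("B", "C")])
        direct = GeneNetwork(edges=[("A", "B"), ("B", "C")], label="direct")
        indirect = GeneNetwork(
            edges=[("A", "M"), ("M", "B"), ("B", "N"), ("N", "C")], label="indirect"
        )
        ranking = functional_assignment(g_i, [indirect, direct], n=2)
        assert [lbl for lbl, _ in ranking] == ["direct", "indirect"]
        assert ranking[0][1].validity == pytest.approx(1.0)
        assert ranking[1][1].validity == pytest.approx(0.5)

    def test_overlapping_pathways_both_rank_high(self):
        """Related processes sharing edges both score well (cell-cycle/meiosis)."""
        shared = [("A", "B"), ("B", "C"), ("C", "D")]
        p1 = GeneNetwork(edges=shared + [("D", "E")], label="cycle")
        p2 = GeneNetwork(edges=shared + [("D", "F")], label="meiosis")
        g_i = GeneNetwork(edges=shared)
        ranking = functional_assignment(g_i, [p1, p2], n=2)
        assert all(res.validity == pytest.approx(1.0) for _, res in ranking)
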