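"""Neuronal gene classification, cluster distributions, EASE enrichment, BH."""

import itertools

import numpy as np
import pytest
from scipy.stats import fisher_exact, hypergeom

from tssmeta import clustering as clu
from tssmeta import genesets as gs


def assignment_of(labels: dict[str, int]) -> clu.ClusterAssignment:
    k = max(labels.values())
    return clu.ClusterAssignment(
        labels=labels, centroids=np.empty((k, 0)), mean_occupancy=np.full(k, np.nan)
    )


class TestClassifyNeuronal:
    @pytest.mark.parametrize(
        "term, branch, included",
        [
            ("synaptic vesicle", "biological_process", True),
            ("Synapse organization", "molecular_function", True),
            ("neuron projection", "cellular_component", True),
            ("neurogenesis", "biological_process", False),
            ("metabolic process", "biological_process", False),
        ],
    )
    def test_matching_rule(self, term, branch, included):
        anns = [gs.TermAnnotation("G1", term, branch)]
        assert (("G1" in gs.classify_neuronal(anns)) is included)

    def test_intersection_with_gene_universe(self):
        anns = [
            gs.TermAnnotation("G1", "synapse", "cellular_component"),
            gs.TermAnnotation("G2", "synapse", "cellular_component"),
        ]
        assert gs.classify_neuronal(anns, genes=["G1"]) == {"G1"}

    def test_unknown_branch_rejected(self):
        with pytest.raises(ValueError):
            gs.TermAnnotation("G1", "synapse", "bp")


class TestClusterDistribution:
    def test_percentages_match_label_counts(self):
        labels = {f"G{i}": lab for i, lab in enumerate([1] + [2] * 2 + [3] * 3 + [4] * 4)}
        dist = gs.cluster_distribution(assignment_of(labels), labels)
        assert dist == {1: 10.0, 2: 20.0, 3: 30.0, 4: 40.0}
        assert sum(dist.values()) == pytest.approx(100.0, abs=1e-9)

    def test_hand_built_seven_gene_tally(self):
        labels = {"A": 1, "B": 1, "C": 2, "D": 3, "E": 3, "F": 3, "G": 4, "H": 4}
        subset = ["A", "C", "D", "E", "F", "G", "Missing"]  # 6 retained
        dist = gs.cluster_distribution(assignment_of(labels), subset)
        assert dist[1] == pytest.approx(100 / 6)
        assert dist[2] == pytest.approx(100 / 6)
        assert dist[3] == pytest.approx(300 / 6)
        assert dist[4] == pytest.approx(100 / 6)

    def test_empty_retained_set_errors(self):
        with pytest.raises(ValueError):
            gs.cluster_distribution(assignment_of({"A": 1}), ["Z"])


class TestEaseScore:
    def test_single_overlap_is_uninformative(self):
        assert gs.ease_score(1, 9, 9, 81) == 1.0
        assert gs.ease_score(0, 10, 10, 80) == 1.0

    def test_decremented_hypergeometric_tail(self):
        # background 100, term 10, list 10, overlap 5 -> P(X >= 4) on the
        # decremented table (population 99, successes 9, draws 9)
        assert gs.ease_score(5, 5, 5, 85) == pytest.approx(hypergeom.sf(3, 99, 9, 9))

    def test_ease_at_least_fisher_on_all_small_tables(self):
        """Exhaustive check on every 2x2 table with margins <= 12."""
        for a, b, c, d in itertools.product(range(7), repeat=4):
            if a + b > 12 or a + c > 12 or b + d > 12 or c + d > 12:
                continue
            if a + b + c + d == 0:
                continue
            ease = gs.ease_score(a, b, c, d)
            fisher = fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            assert ease >= fisher - 1e-12, (a, b, c, d)
            a2 = max(a - 1, 0)
            oracle = hypergeom.sf(a2 - 1, a2 + b + c + d, a2 + c, a2 + b)
            assert ease == pytest.approx(min(1.0, oracle), abs=1e-12), (a, b, c, d)


class TestEaseEnrichment:
    def test_counts_and_sorting(self):
        background = [f"G{i}" for i in range(100)]
        gene_list = background[:10]
        term2genes = {
            "hit": set(background[:5]) | set(background[10:15]),   # a=5, c=5
            "miss": set(background[50:60]),                        # a=0
        }
        results = gs.ease_enrichment(gene_list, background, term2genes)
        assert [r.term_name for r in results] == ["hit", "miss"]
        hit = results[0]
        assert (hit.a, hit.b, hit.c, hit.d) == (5, 5, 5, 85)
        assert hit.ease_p == pytest.approx(hypergeom.sf(3, 99, 9, 9))

    def test_bh_q_matches_hand_step_up(self):
        """q_i = min_{j >= i} p_(j) * m / j, computed by hand from the EASE p's."""
        rng = np.random.default_rng(4)
        background = [f"G{i}" for i in range(300)]
        gene_list = list(rng.choice(background, 60, replace=False))
        term2genes = {
            f"term{i}": set(rng.choice(background, 40, replace=False)) for i in range(25)
        }
        results = gs.ease_enrichment(gene_list, background, term2genes)
        ps = np.array([r.ease_p for r in results])  # already sorted ascending
        m = len(ps)
        expected_q = np.minimum.accumulate((ps * m / np.arange(1, m + 1))[::-1])[::-1]
        expected_q = np.minimum(expected_q, 1.0)
        np.testing.assert_allclose([r.bh_q for r in results], expected_q, atol=1e-12)

    def test_bh_q_monotone_in_p_rank(self):
        rng = np.random.default_rng(0)
        background = [f"G{i}" for i in range(200)]
        gene_list = list(rng.choice(background, 50, replace=False))
        term2genes = {
            f"term{i}": set(rng.choice(background, 30, replace=False)) for i in range(40)
        }
        results = gs.ease_enrichment(gene_list, background, term2genes)
        qs = [r.bh_q for r in results]  # results sorted by ease_p
        assert all(q1 <= q2 + 1e-12 for q1, q2 in zip(qs, qs[1:]))

    def test_list_outside_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            gs.ease_enrichment(["X"], ["A", "B"], {"t": {"A"}})

    def test_term_genes_intersected_with_background(self):
        results = gs.ease_enrichment(["A"], ["A", "B"], {"t": {"A", "Z1", "Z2"}})
        assert (results[0].a, results[0].c) == (1, 0)
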