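"""Enrichment scores, overlap bookkeeping and network summary statistics."""

import networkx as nx
import numpy as np
import pytest

from mi_remodel.datasets import remodeling_timepoint_detection
from mi_remodel.enrich import (
    RankedList,
    enrichment_score,
    network_summary,
    overlap_accounting,
    proportion_report,
    time_overlap_table,
)


def es_oracle(genes, correlations, gene_set, exponent):
    """Independent running-sum walk, computed step by step."""
    hits = [g in gene_set for g in genes]
    k = sum(hits)
    n = len(genes)
    weights = [abs(c) ** exponent for c in correlations]
    total_hit = sum(w for w, h in zip(weights, hits) if h)
    best = 0.0
    running = 0.0
    for g, w, h in zip(genes, weights, hits):
        if h:
            running += (w / total_hit) if total_hit > 0 else 1.0 / k
        else:
            running -= 1.0 / (n - k)
        if abs(running) > abs(best):
            best = running
    return best


class TestEnrichmentScore:
    def test_top_ranked_singleton_scores_one(self):
        r = RankedList(["g1", "g2", "g3", "g4"], [4.0, 3.0, 2.0, 1.0])
        assert enrichment_score(r, {"g1"}, weight_exponent=0) == 1.0

    def test_bottom_ranked_singleton_scores_minus_one(self):
        r = RankedList(["g1", "g2", "g3", "g4"], [4.0, 3.0, 2.0, 1.0])
        assert enrichment_score(r, {"g4"}, weight_exponent=0) == -1.0

    def test_full_set_degenerates_to_one(self):
        r = RankedList(["g1", "g2"], [1.0, 0.5])
        assert enrichment_score(r, {"g1", "g2"}) == 1.0

    def test_empty_intersection_rejected(self):
        r = RankedList(["g1"], [1.0])
        with pytest.raises(ValueError):
            enrichment_score(r, {"zz"})

    def test_agrees_with_running_sum_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(500):
            n = int(rng.integers(3, 40))
            corr = np.sort(rng.normal(size=n))[::-1]
            genes = [f"g{i}" for i in range(n)]
            k = int(rng.integers(1, n))
            gene_set = set(rng.choice(genes, size=k, replace=False))
            exponent = float(rng.choice([0.0, 1.0, 2.0]))
            expected = es_oracle(genes, corr, gene_set, exponent)
            r = RankedList(genes, list(corr))
            assert enrichment_score(r, gene_set, exponent) == pytest.approx(
                expected, abs=1e-12
            )

    def test_antisymmetry_under_list_reversal(self):
        # the unweighted walk sums to zero, so the reversed list's partial
        # sums are the negated forward sums: the ES magnitude is preserved
        # and the sign flips whenever the extreme deviation is unique
        rng = np.random.default_rng(13)
        checked = 0
        for _ in range(100):
            n = int(rng.integers(4, 30))
            corr = np.sort(rng.uniform(0.1, 1.0, size=n))[::-1]
            genes = [f"g{i}" for i in range(n)]
            k = int(rng.integers(1, n))
            gene_set = set(rng.choice(genes, size=k, replace=False))
            fwd = enrichment_score(RankedList(genes, list(corr)), gene_set, 0)
            rev = enrichment_score(
                RankedList(genes[::-1], list(-corr[::-1])), gene_set, 0
            )
            assert abs(rev) == pytest.approx(abs(fwd), abs=1e-9)
            # uniqueness check of the extreme via the oracle's partial sums
            steps = [
                1.0 / k if g in gene_set else -1.0 / (n - k) for g in genes
            ]
            partial = np.cumsum(steps)
            peak = np.max(np.abs(partial))
            if np.sum(np.abs(np.abs(partial) - peak) < 1e-12) == 1:
                assert rev == pytest.approx(-fwd, abs=1e-9)
                checked += 1
        assert checked > 50  # the signed assertion actually ran


class TestOverlapAccounting:
    @staticmethod
    def _sets(sizes_by_category, cohorts=("C6", "C30", "C45")):
        """Build term sets whose all-cohort intersections have given sizes."""
        out = {}
        counter = 0
        for cat, size in sizes_by_category.items():
            shared = {f"{cat}_t{counter + i}" for i in range(size)}
            counter += size
            out[cat] = {c: set(shared) | {f"{cat}_{c}_only"} for c in cohorts}
        return out

    def test_reported_common_total_is_sum_of_category_intersections(self):
        sets = self._sets({"KEGG": 8, "GO_function": 21, "GO_process": 72})
        counts = overlap_accounting(sets)
        assert counts.triple_common == {
            "KEGG": 8,
            "GO_function": 21,
            "GO_process": 72,
        }
        assert counts.common_total == 101

    def test_direction_split_adds_to_total(self):
        terms_up = {f"t{i}" for i in range(221)}
        terms_down = {f"d{i}" for i in range(134)}
        sets = {"all": {"C6": terms_up | terms_down, "C30": set()}}
        directions = {t: "up" for t in terms_up} | {t: "down" for t in terms_down}
        counts = overlap_accounting(sets, directions)
        assert counts.n_up == 221
        assert counts.n_down == 134
        assert counts.total_terms == counts.n_up + counts.n_down == 355

    def test_disjoint_cohorts_have_zero_intersections(self):
        sets = {"cat": {"C6": {"a"}, "C30": {"b"}}}
        counts = overlap_accounting(sets)
        assert counts.triple_common == {"cat": 0}
        assert counts.pairwise[("cat", "C30", "C6")] == 0

    def test_inclusion_exclusion_on_random_sets(self):
        rng = np.random.default_rng(5)
        universe = [f"t{i}" for i in range(60)]
        for _ in range(20):
            a, b, c = (
                set(rng.choice(universe, size=rng.integers(5, 40), replace=False))
                for _ in range(3)
            )
            sets = {"cat": {"C6": a, "C30": b, "C45": c}}
            counts = overlap_accounting(sets)
            lhs = len(a | b | c)
            rhs = (
                len(a) + len(b) + len(c)
                - counts.pairwise[("cat", "C30", "C6")]
                - counts.pairwise[("cat", "C45", "C6")]
                - counts.pairwise[("cat", "C30", "C45")]
                + counts.triple_common["cat"]
            )
            assert lhs == rhs == counts.total_terms


class TestNetworkSummary:
    def test_published_interactome_scale_average_degree(self):
        g = nx.gnm_random_graph(105, 128, seed=0)
        avg_degree, _ = network_summary(105, list(g.edges()))
        assert avg_degree == pytest.approx(2.44, abs=0.005)

    def test_triangle_graph(self):
        avg_degree, clustering = network_summary(3, [(0, 1), (1, 2), (0, 2)])
        assert avg_degree == 2.0
        assert clustering == 1.0

    def test_star_has_zero_clustering(self):
        _, clustering = network_summary(4, [(0, 1), (0, 2), (0, 3)])
        assert clustering == 0.0

    def test_foreign_endpoint_rejected(self):
        with pytest.raises(ValueError):
            network_summary(2, [(0, 5)])


class TestProportionReport:
    @pytest.mark.parametrize(
        "num,den,decimals,expected",
        [(52, 105, 1, 49.5), (42, 105, 0, 40.0), (0, 7, 1, 0.0), (1, 8, 1, 12.5)],
    )
    def test_half_up_percentages(self, num, den, decimals, expected):
        assert proportion_report(num, den, decimals) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            proportion_report(1, 0)


class TestTimeOverlap:
    def test_bundled_detection_matrix_yields_seven_proteins(self):
        overlap = time_overlap_table(remodeling_timepoint_detection())
        assert len(overlap) == 7
        assert overlap == sorted(
            ["DPP4", "RICTR", "MK11", "MK12", "PGS2", "KS6A4", "RCOR1"]
        )

    def test_protein_missing_one_day_excluded(self):
        import pandas as pd

        detection = pd.DataFrame(
            {"C6": [1], "C30": [1], "C45": [0], "R6": [0], "R30": [0], "R45": [0]},
            index=["X"],
        )
        assert time_overlap_table(detection) == []

    def test_empty_matrix(self):
        import pandas as pd

        assert time_overlap_table(pd.DataFrame()) == []
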