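"""Fisher/hypergeometric pathway overrepresentation and BH correction."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycoreg import synthetic
from glycoreg.enrichment import (
    benjamini_hochberg,
    build_contingency,
    degree_of_regulation,
    enrich_tf_pathways,
    hypergeometric_tail,
)
from glycoreg.errors import DomainError
from glycoreg.filtering import FilterConfig, filter_records
from glycoreg.ingest import PathwayClassification, TFGeneRecord


def enumeration_tail(k: int, K: int, n: int, N: int) -> float:
    """Oracle: enumerate every n-subset of an N-population with K successes."""
    population = [1] * K + [0] * (N - K)
    total = hits = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        hits += sum(population[i] for i in draw) >= k
    return hits / total if total else 1.0


class TestHypergeometricTail:
    def test_zero_successes_gives_one(self):
        assert hypergeometric_tail(0, 5, 4, 10) == 1.0

    def test_enumerated_examples(self):
        # all C(10,4) draws with >= 3 of the 5 successes: 55/210
        assert hypergeometric_tail(3, 5, 4, 10) == pytest.approx(55 / 210, rel=1e-12)
        # C(2,2) C(8,0) / C(10,2)
        assert hypergeometric_tail(2, 2, 2, 10) == pytest.approx(1 / 45, rel=1e-12)

    @pytest.mark.parametrize("k,K,n,N", [(3, 2, 4, 10), (1, 11, 4, 10), (1, 2, 11, 10), (-1, 2, 2, 10)])
    def test_inconsistent_margins_rejected(self, k, K, n, N):
        with pytest.raises(DomainError):
            hypergeometric_tail(k, K, n, N)

    @settings(max_examples=60, deadline=None)
    @given(data=st.data())
    def test_matches_enumeration_oracle(self, data):
        N = data.draw(st.integers(1, 9))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(0, min(K, n)))
        assert hypergeometric_tail(k, K, n, N) == pytest.approx(
            enumeration_tail(k, K, n, N), rel=1e-9, abs=1e-12
        )

    def test_monotone_decreasing_in_k(self):
        N, K, n = 40, 12, 15
        tails = [hypergeometric_tail(k, K, n, N) for k in range(min(K, n) + 1)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))


class TestBenjaminiHochberg:
    def test_step_up_collapses_equal_ratios(self):
        assert benjamini_hochberg([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_value_unchanged(self):
        assert benjamini_hochberg([0.3]) == pytest.approx([0.3])

    def test_all_equal_unchanged(self):
        assert benjamini_hochberg([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    def test_hand_derived_case_in_input_order(self):
        # sorted (0.005, 0.03, 0.04): adj_(3)=0.04, adj_(2)=min(3*0.03/2, 0.04)=0.04,
        # adj_(1)=min(3*0.005, 0.04)=0.015
        assert benjamini_hochberg([0.04, 0.005, 0.03]) == pytest.approx([0.04, 0.015, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            benjamini_hochberg([0.5, 1.2])

    @settings(max_examples=60, deadline=None)
    @given(
        p=st.lists(st.integers(0, 10000).map(lambda i: i / 10000), min_size=1, max_size=30),
        alpha=st.sampled_from([0.01, 0.05, 0.1, 0.2]),
    )
    def test_adjusted_values_reproduce_step_up_decisions(self, p, alpha):
        """Thresholding adj p at alpha equals the classic BH step-up rejection rule."""
        adj = benjamini_hochberg(p)
        assert np.all(adj >= np.asarray(p) - 1e-12) and np.all(adj <= 1.0)
        order = np.argsort(p, kind="mergesort")
        ranked = np.asarray(p)[order]
        m = len(p)
        below = [i for i in range(m) if ranked[i] <= alpha * (i + 1) / m]
        cutoff = ranked[max(below)] if below else -1.0
        classic = {int(order[i]) for i in range(m) if ranked[i] <= cutoff}
        assert {i for i in range(m) if adj[i] <= alpha} == classic

    @settings(max_examples=40, deadline=None)
    @given(p=st.lists(st.integers(0, 10000).map(lambda i: i / 10000), min_size=2, max_size=30))
    def test_rank_monotonicity(self, p):
        adj = benjamini_hochberg(p)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestContingency:
    def test_direct_counts(self, tiny_classification):
        edges = [
            TFGeneRecord("X", "FUT7", "C1", 0.9, 0.9),
            TFGeneRecord("X", "UNCLASSIFIED", "C1", 0.9, 0.9),
            TFGeneRecord("Y", "FUT7", "C1", 0.9, 0.9),
            TFGeneRecord("Y", "HAS1", "C1", 0.9, 0.9),
            TFGeneRecord("Z", "GALNT3", "C1", 0.9, 0.9),
            TFGeneRecord("Z", "HAS1", "C1", 0.9, 0.9),
        ]
        table = build_contingency("X", "Fucosylation", edges, tiny_classification)
        assert table == (1, 1, 1, 3)

    def test_unclassified_targets_count_zero(self, tiny_classification):
        edges = [
            TFGeneRecord("X", "NOV1", "C1", 0.9, 0.9),
            TFGeneRecord("Y", "FUT7", "C1", 0.9, 0.9),
        ]
        table = build_contingency("X", "Fucosylation", edges, tiny_classification)
        assert table.a == 0

    def test_margin_identity_on_random_fixture(self, tiny_classification):
        rng = np.random.default_rng(5)
        genes = ["FUT7", "GALNT3", "HAS1", "NOV1", "NOV2"]
        edges = []
        for tf in ["A", "B", "C"]:
            for g in genes:
                if rng.random() < 0.7:
                    edges.append(TFGeneRecord(tf, g, "C1", 0.9, 0.9))
        for tf in ["A", "B", "C"]:
            for pw in tiny_classification.pathways:
                t = build_contingency(tf, pw, edges, tiny_classification)
                assert t.a + t.b + t.c + t.d == len(edges)
                assert t.a + t.b == sum(1 for e in edges if e.tf == tf)

    def test_absent_tf_rejected(self, tiny_classification):
        edges = [TFGeneRecord("X", "FUT7", "C1", 0.9, 0.9)]
        with pytest.raises(DomainError):
            build_contingency("NOPE", "Fucosylation", edges, tiny_classification)

    def test_mixed_cancers_rejected(self, tiny_classification):
        edges = [
            TFGeneRecord("X", "FUT7", "C1", 0.9, 0.9),
            TFGeneRecord("X", "FUT7", "C2", 0.9, 0.9),
        ]
        with pytest.raises(DomainError):
            build_contingency("X", "Fucosylation", edges, tiny_classification)


class TestEnrichTFPathways:
    def _concentrated_table(self):
        """One TF hits an entire 10-gene pathway; 9 other TFs spread 90 edges."""
        classification = PathwayClassification(
            pathways=("P0", "P1"),
            assignment={f"g{j}": frozenset({"P0" if j < 10 else "P1"}) for j in range(100)},
        )
        edges = [TFGeneRecord("FOCAL", f"g{j}", "C1", 0.9, 0.9) for j in range(10)]
        rng = np.random.default_rng(2)
        for i in range(9):
            for j in rng.choice(100, size=10, replace=False):
                edges.append(TFGeneRecord(f"BG{i}", f"g{j}", "C1", 0.9, 0.9))
        return edges, classification

    def test_concentrated_tf_attains_smallest_p(self):
        edges, classification = self._concentrated_table()
        res = enrich_tf_pathways(edges, classification)
        best = res.loc[res["p"].idxmin()]
        assert (best["tf"], best["pathway"]) == ("FOCAL", "P0")

    def test_zero_hits_give_p_one_and_no_flag(self, tiny_classification):
        edges = [
            TFGeneRecord("X", "FUT7", "C1", 0.9, 0.9),
            TFGeneRecord("Y", "HAS1", "C1", 0.9, 0.9),
        ]
        res = enrich_tf_pathways(edges, tiny_classification)
        row = res[(res["tf"] == "X") & (res["pathway"] == "Hyaluronan synthesis")].iloc[0]
        assert row["p"] == 1.0 and not row["significant_raw"]

    def test_one_test_per_tf_pathway_pair(self, tiny_records, tiny_classification):
        res = enrich_tf_pathways(tiny_records, tiny_classification)
        assert len(res) == 2 * len(tiny_classification.pathways)

    def test_per_cancer_scope_adjusts_within_cancer(self, tiny_classification):
        edges = [
            TFGeneRecord("X", "FUT7", "C1", 0.9, 0.9),
            TFGeneRecord("Y", "HAS1", "C1", 0.9, 0.9),
            TFGeneRecord("X", "FUT7", "C2", 0.9, 0.9),
        ]
        g = enrich_tf_pathways(edges, tiny_classification, bh_scope="global")
        pc = enrich_tf_pathways(edges, tiny_classification, bh_scope="per_cancer")
        assert set(g.columns) == set(pc.columns)
        for cancer, grp in pc.groupby("cancer"):
            assert np.allclose(grp["p_adj"], benjamini_hochberg(grp["p"].to_numpy()))

    def test_restricted_background_drops_unclassified_edges(self, tiny_classification):
        edges = [
            TFGeneRecord("X", "FUT7", "C1", 0.9, 0.9),
            TFGeneRecord("X", "NOV1", "C1", 0.9, 0.9),
            TFGeneRecord("Y", "HAS1", "C1", 0.9, 0.9),
        ]
        res = enrich_tf_pathways(edges, tiny_classification, restrict_background=True)
        assert (res["a"] + res["b"] + res["c"] + res["d"] == 2).all()

    def test_null_raw_p_is_conservative(self):
        """Permutation-null raw p-values are stochastically >= uniform (one-sided KS)."""
        pvals = []
        for seed in range(20):
            cfg = synthetic.SyntheticConfig(n_tfs=30, n_genes=120, n_pathways=10, seed=300 + seed)
            truth = synthetic.generate(cfg)
            kept = filter_records(list(truth.table), FilterConfig(universe=truth.universe))
            res = enrich_tf_pathways(kept, truth.classification)
            pvals.extend(res["p"].tolist())
        p = np.sort(pvals)
        ecdf = np.arange(1, len(p) + 1) / len(p)
        d_plus = float(np.max(ecdf - p))  # excess of the ECDF above the uniform CDF
        assert d_plus < 0.02, d_plus

    def test_planted_pair_ranks_first_by_raw_p(self):
        """A strongly planted (TF, pathway) pair attains rank 1 by raw p in >=95% of replicates."""
        wins = 0
        n_rep = 200
        for seed in range(n_rep):
            cfg = synthetic.SyntheticConfig(
                n_tfs=50, n_genes=200, seed=7000 + seed,
                planted_pairs=(synthetic.PlantedPair(0, 0, 10.0),),
            )
            truth = synthetic.generate(cfg)
            kept = filter_records(list(truth.table), FilterConfig(universe=truth.universe))
            res = enrich_tf_pathways(kept, truth.classification)
            best = res.loc[res["p"].idxmin()]
            (cancer, tf, pw) = next(iter(truth.true_pairs))
            wins += (best["tf"], best["pathway"]) == (tf, pw)
        assert wins / n_rep >= 0.95, wins / n_rep


class TestDegreeOfRegulation:
    def test_exact_log_sums(self):
        res = pd.DataFrame(
            {
                "cancer": ["C1"] * 3,
                "tf": ["A", "B", "C"],
                "pathway": ["P"] * 3,
                "p": [0.001, 0.0001, 0.5],
                "p_adj": [0.01, 0.001, 0.9],
            }
        )
        deg = degree_of_regulation(res)
        row = deg.iloc[0]
        assert row["n_tfs"] == 2
        assert row["degree"] == pytest.approx(2 + 3)

    def test_no_significant_tfs_give_zeros(self):
        res = pd.DataFrame(
            {"cancer": ["C1"], "tf": ["A"], "pathway": ["P"], "p": [0.9], "p_adj": [0.95]}
        )
        deg = degree_of_regulation(res)
        assert (deg["n_tfs"] == 0).all() and (deg["degree"] == 0.0).all()
        assert degree_of_regulation(res.iloc[0:0]).empty
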