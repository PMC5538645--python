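import itertools
from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adiponet import enrichment as enr
from adiponet import network as net
from adiponet.io_formats import GeneSetCollection


def enum_hypergeom(k, K, n, N):
    """Exhaustive oracle: fraction of n-subsets of [N] hitting >= k of the
    first K elements."""
    total = comb(N, n)
    hits = sum(
        1 for draw in itertools.combinations(range(N), n)
        if sum(1 for e in draw if e < K) >= k
    )
    return hits / total


def exact_binom_tail(k, n, p0: Fraction):
    return float(sum(
        Fraction(comb(n, i)) * p0 ** i * (1 - p0) ** (n - i)
        for i in range(k, n + 1)
    ))


class TestHypergeom:
    def test_zero_overlap_certain(self):
        assert enr.hypergeom_overlap(0, 3, 3, 10) == 1.0

    def test_enumeration_case(self):
        assert enr.hypergeom_overlap(2, 3, 3, 6) == pytest.approx(0.5)
        assert enum_hypergeom(2, 3, 3, 6) == pytest.approx(0.5)

    def test_degenerate_full_draw(self):
        assert enr.hypergeom_overlap(3, 3, 6, 6) == pytest.approx(1.0)

    def test_matches_enumeration_sweep(self):
        for N in (4, 6, 8):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        assert enr.hypergeom_overlap(k, K, n, N) == pytest.approx(
                            enum_hypergeom(k, K, n, N), abs=1e-12
                        ), (k, K, n, N)

    def test_inconsistent_counts(self):
        with pytest.raises(ValueError):
            enr.hypergeom_overlap(5, 3, 3, 6)

    def test_log_space_extreme_tail(self):
        p = enr.hypergeom_overlap(200, 250, 250, 5000)
        assert 0 < p < 1e-100


class TestBinomial:
    def test_zero_certain(self):
        assert enr.binomial_overrep(0, 10, 0.5) == 1.0

    def test_exact_value(self):
        assert enr.binomial_overrep(5, 10, 0.5) == pytest.approx(
            0.623046875, abs=1e-12
        )
        assert exact_binom_tail(5, 10, Fraction(1, 2)) == pytest.approx(
            0.623046875
        )

    def test_all_successes_single_term(self):
        assert enr.binomial_overrep(4, 4, 0.01) == pytest.approx(1e-8, rel=1e-9)

    def test_matches_fraction_oracle(self):
        for n in range(1, 9):
            for k in range(n + 1):
                for p0 in (Fraction(1, 4), Fraction(3, 10)):
                    assert enr.binomial_overrep(k, n, float(p0)) == pytest.approx(
                        exact_binom_tail(k, n, p0), abs=1e-12
                    )

    def test_bad_p0(self):
        with pytest.raises(ValueError, match="p0"):
            enr.binomial_overrep(1, 2, 1.0)


class TestBhAdjust:
    def test_hand_evaluated_stepup(self):
        q = enr.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert enr.bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_ties(self):
        assert np.allclose(enr.bh_adjust([0.2] * 5), 0.2)

    def test_preserves_input_order(self):
        p = [0.04, 0.01, 0.03, 0.02]
        q = enr.bh_adjust(p)
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
        q2 = enr.bh_adjust([0.5, 0.001])
        assert q2[1] < q2[0]

    def test_deterministic_and_dominating(self, rng):
        # note: strict idempotency (BH(BH(p)) == BH(p)) does not hold for the
        # standard step-up, since re-adjustment re-inflates by m/rank; what
        # does hold is determinism and q >= p domination
        p = rng.random(50)
        q = enr.bh_adjust(p)
        assert np.allclose(enr.bh_adjust(p), q)
        assert (q >= p - 1e-15).all()
        assert (enr.bh_adjust(q) >= q - 1e-15).all()

    def test_idempotent_under_full_ties(self):
        q = enr.bh_adjust([0.2] * 6)
        assert np.allclose(enr.bh_adjust(q), q)

    def test_monotone_along_sorted_p(self, rng):
        p = rng.random(100)
        q = enr.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            enr.bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_properties_hold_for_arbitrary_pvalues(self, pvals):
        q = enr.bh_adjust(pvals)
        p = np.asarray(pvals)
        assert ((q >= p - 1e-12) & (q <= 1.0 + 1e-15)).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()
        # smallest q equals the step-up minimum
        m = len(p)
        expected_min = min(
            pv * m / rank for rank, pv in enumerate(sorted(p), start=1)
        )
        assert q.min() == pytest.approx(min(1.0, expected_min), abs=1e-12)


def brute_force_es(ordered_scores, hit_flags, weight=1.0):
    """Independent running-sum ES implementation (oracle)."""
    nr = sum(abs(s) ** weight for s, h in zip(ordered_scores, hit_flags) if h)
    n_miss = sum(1 for h in hit_flags if not h)
    running, best = 0.0, 0.0
    for s, h in zip(ordered_scores, hit_flags):
        running += (abs(s) ** weight) / nr if h else -1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


class TestGsea:
    def _scores(self, n=10):
        return pd.Series(
            np.linspace(5, -5, n), index=[f"g{i}" for i in range(n)]
        )

    def test_top_gene_set_es_one(self):
        res = enr.preranked_gsea(self._scores(), {"g0"}, n_perm=10, seed=0)
        assert res.es == pytest.approx(1.0)

    def test_sign_reversal_negates_es(self):
        s = self._scores()
        gene_set = {"g0", "g2"}
        res = enr.preranked_gsea(s, gene_set, n_perm=10, seed=0)
        flipped = enr.preranked_gsea(-s, gene_set, n_perm=10, seed=0)
        assert flipped.es == pytest.approx(-res.es)

    def test_es_matches_brute_force(self, rng):
        s = pd.Series(rng.normal(size=12), index=[f"g{i}" for i in range(12)])
        gene_set = {"g2", "g5", "g7"}
        res = enr.preranked_gsea(s, gene_set, n_perm=5, seed=1)
        ordering = sorted(s.index, key=lambda g: (-s[g], g))
        flags = [g in gene_set for g in ordering]
        assert res.es == pytest.approx(
            brute_force_es([s[g] for g in ordering], flags)
        )

    def test_reproducible_with_seed(self):
        s = self._scores(20)
        a = enr.preranked_gsea(s, {"g1", "g3"}, n_perm=200, seed=42)
        b = enr.preranked_gsea(s, {"g1", "g3"}, n_perm=200, seed=42)
        assert (a.es, a.nes, a.p_perm) == (b.es, b.nes, b.p_perm)

    def test_p_perm_floor(self):
        res = enr.preranked_gsea(self._scores(), {"g0"}, n_perm=99, seed=0)
        assert res.p_perm >= 1 / 100

    def test_relabeling_invariance(self, rng):
        s = pd.Series(rng.normal(size=15), index=[f"g{i}" for i in range(15)])
        mapping = {f"g{i}": f"h{14 - i}" for i in range(15)}
        s2 = pd.Series(s.to_numpy(), index=[mapping[g] for g in s.index])
        r1 = enr.preranked_gsea(s, {"g3", "g8"}, n_perm=100, seed=7)
        r2 = enr.preranked_gsea(s2, {mapping["g3"], mapping["g8"]},
                                n_perm=100, seed=7)
        assert r1.es == pytest.approx(r2.es)
        assert r1.p_perm == r2.p_perm

    def test_empty_and_universe_sets_error(self):
        s = self._scores()
        with pytest.raises(ValueError, match="no members"):
            enr.preranked_gsea(s, {"zz"}, n_perm=5, seed=0)
        with pytest.raises(ValueError, match="universe"):
            enr.preranked_gsea(s, set(s.index), n_perm=5, seed=0)


def _toy_graph():
    edges = pd.DataFrame(
        [("lnc1", f"m{i}", 0.5, 0.01) for i in range(4)]
        + [("m0", "m1", 0.3, 0.01), ("m5", "m6", 0.4, 0.01),
           ("lnc2", "m5", 0.4, 0.01)],
        columns=["gene_a", "gene_b", "pcor", "fdr"],
    )
    biotypes = {f"m{i}": "mRNA" for i in range(12)}
    biotypes.update({"lnc1": "lncRNA", "lnc2": "lncRNA"})
    return net.build_network(edges, biotypes, nodes=list(biotypes))


class TestAnnotateLncrnas:
    def test_planted_set_top_hit(self):
        g = _toy_graph()
        col = GeneSetCollection(sets={
            "target": ("m0", "m1", "m2", "m3"),
            "decoy": ("m8", "m9", "m10", "m11"),
        })
        table = enr.annotate_lncrnas(g, col, alpha=0.01)
        lnc1 = table[table.lncrna == "lnc1"].sort_values("p")
        assert lnc1.iloc[0]["set"] == "target"
        assert lnc1.iloc[0].p < 0.01
        assert bool(lnc1.iloc[0].significant)

    def test_empty_collection_empty_table(self):
        table = enr.annotate_lncrnas(
            _toy_graph(), GeneSetCollection(sets={}), alpha=0.01
        )
        assert len(table) == 0

    def test_isolated_lncrna_skipped(self):
        g = _toy_graph()
        g.add_node("lnc9", biotype="lncRNA")
        col = GeneSetCollection(sets={"target": ("m0", "m1")})
        table = enr.annotate_lncrnas(g, col)
        assert "lnc9" not in set(table.lncrna)


class TestClusterOverrep:
    def test_cluster_matching_set_is_top(self):
        g = _toy_graph()
        part = net.detect_communities(g)
        col = GeneSetCollection(sets={
            "target": ("m0", "m1", "m2", "m3"),
            "decoy": ("m8", "m9", "m10", "m11"),
        })
        table = enr.cluster_overrep(g, part, col)
        # the lnc1 cluster's tested mRNAs are exactly m0..m3
        best = table.sort_values("p").iloc[0]
        assert best["set"] == "target"

    def test_set_absent_from_universe_errors(self):
        g = _toy_graph()
        part = net.detect_communities(g)
        col = GeneSetCollection(sets={"ghost": ("zz1", "zz2")})
        with pytest.raises(ValueError, match="ghost"):
            enr.cluster_overrep(g, part, col)

    def test_singleton_cluster_single_trial(self):
        edges = pd.DataFrame([("lnc1", "m0", 0.5, 0.01)],
                             columns=["gene_a", "gene_b", "pcor", "fdr"])
        biotypes = {"lnc1": "lncRNA", "m0": "mRNA", "m1": "mRNA"}
        g = net.build_network(edges, biotypes, nodes=list(biotypes))
        part = net.detect_communities(g)
        col = GeneSetCollection(sets={"half": ("m0",)})
        table = enr.cluster_overrep(g, part, col, universe={"m0", "m1"})
        # tested list = {m0}, p0 = 1/2, k = 1 -> p = 0.5
        assert table.iloc[0].p == pytest.approx(0.5)
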