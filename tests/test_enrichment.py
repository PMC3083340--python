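"""Fisher over-representation, selection filters, clustering of results."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from tfsarray.enrichment import (
    cluster_matrix,
    enrich_groups,
    fisher_enrichment,
    hypergeom_tail,
    run_collections,
    select_enriched,
)
from tfsarray.io import GeneSet


def hypergeom_tail_oracle(k, m, K, N):
    """Exhaustive integer enumeration of P(X >= k)."""
    denom = comb(N, m)
    return sum(comb(K, i) * comb(N - K, m - i) for i in range(k, min(m, K) + 1)) / denom


def _genes(prefix, n):
    return [f"{prefix}{i:03d}" for i in range(n)]


class TestFisherEnrichment:
    def test_complete_overlap_matches_enumeration(self):
        universe = _genes("u", 100)
        group = universe[:10]
        gs = GeneSet("S", "d", frozenset(universe[:20]))
        rec = fisher_enrichment(group, gs, universe)
        assert rec.k == 10 and rec.m == 10 and rec.K == 20 and rec.N == 100
        assert rec.p == pytest.approx(hypergeom_tail_oracle(10, 10, 20, 100), abs=1e-12)
        assert rec.score == pytest.approx((10 / 10) / (20 / 100))

    def test_score_is_one_at_expectation(self):
        universe = _genes("u", 100)
        gs = GeneSet("S", "d", frozenset(universe[:10]))
        group = [universe[0]] + universe[50:59]  # k=1, m=10, K=10, N=100
        rec = fisher_enrichment(group, gs, universe)
        assert rec.score == pytest.approx(1.0)

    def test_zero_overlap(self):
        universe = _genes("u", 50)
        gs = GeneSet("S", "d", frozenset(universe[:10]))
        rec = fisher_enrichment(universe[40:], gs, universe)
        assert rec.k == 0 and rec.score == 0.0 and rec.p == 1.0

    def test_set_intersected_with_universe(self):
        universe = _genes("u", 20)
        gs = GeneSet("S", "d", frozenset(universe[:5]) | {"alien1", "alien2"})
        rec = fisher_enrichment(universe[:5], gs, universe)
        assert rec.K == 5

    def test_errors(self):
        with pytest.raises(ValueError, match="empty universe"):
            fisher_enrichment(["g"], GeneSet("S", "d", frozenset(["g"])), [])
        with pytest.raises(ValueError, match="not in universe"):
            fisher_enrichment(["zzz"], GeneSet("S", "d", frozenset(["g"])), ["g"])

    def test_tail_monotone_nonincreasing_in_k(self):
        for m, K, N in [(10, 20, 100), (5, 5, 30), (15, 40, 60)]:
            ks = np.arange(0, min(m, K) + 1)
            p = hypergeom_tail(ks, m, K, N)
            assert (np.diff(p) <= 1e-15).all()


class TestSelectEnriched:
    def _records(self, rows):
        return pd.DataFrame(
            rows, columns=["tfs_group", "set_name", "k", "m", "K", "N", "score", "p"]
        )

    def test_strict_thresholds(self):
        kept = self._records([("G1", "S1", 6, 20, 30, 100, 2.0, 0.0005)])
        dropped = self._records([("G1", "S2", 5, 20, 30, 100, 2.0, 0.0005)])
        sel_keep = select_enriched(kept)
        sel_drop = select_enriched(dropped)
        assert sel_keep.kept_sets == ["S1"] and sel_keep.kept_groups == ["G1"]
        assert sel_drop.kept_sets == [] and sel_drop.kept_groups == []

    def test_empty_selection_gives_empty_matrix(self):
        sel = select_enriched(
            self._records([("G1", "S1", 2, 20, 30, 100, 1.0, 0.5)])
        )
        assert sel.matrix().shape == (0, 0)

    def test_kept_set_brings_its_other_groups_into_matrix(self):
        recs = self._records(
            [("G1", "S1", 8, 20, 30, 100, 2.0, 1e-5),
             ("G2", "S1", 2, 20, 30, 100, 1.0, 0.2),
             ("G2", "S2", 9, 20, 30, 100, 2.5, 1e-6)]
        )
        sel = select_enriched(recs)
        assert sel.kept_sets == ["S1", "S2"]
        assert sel.kept_groups == ["G1", "G2"]
        mat = sel.matrix()
        assert mat.loc["S1", "G2"] == pytest.approx(-np.log10(0.2))


class TestClusterMatrix:
    def test_identical_rows_merge_first(self):
        mat = pd.DataFrame(
            [[1.0, 2.0, 3.0], [5.0, 1.0, 0.0], [1.0, 2.0, 3.0]],
            index=["a", "b", "c"], columns=["x", "y", "z"],
        )
        out = cluster_matrix(mat)
        ia, ic = out.row_order.index("a"), out.row_order.index("c")
        assert abs(ia - ic) == 1

    def test_small_matrix_passes_through(self):
        mat = pd.DataFrame([[1.0, 2.0, 3.0]], index=["a"], columns=list("xyz"))
        out = cluster_matrix(mat)
        assert out.row_order == ["a"] and out.col_order == list("xyz")
        assert out.row_linkage is None

    def test_two_block_structure_recovered(self):
        # oracle: the two row blocks are exactly anti-correlated across
        # columns, so any 2-cluster cut must separate them
        from scipy.cluster.hierarchy import fcluster

        rows = {
            "a1": [5.0, 4.8, 0.1, 0.2], "a2": [4.9, 5.1, 0.2, 0.1],
            "b1": [0.1, 0.2, 5.0, 4.9], "b2": [0.2, 0.1, 4.8, 5.2],
        }
        mat = pd.DataFrame.from_dict(rows, orient="index", columns=list("wxyz"))
        out = cluster_matrix(mat)
        labels = dict(zip(mat.index, fcluster(out.row_linkage, 2, criterion="maxclust")))
        assert labels["a1"] == labels["a2"]
        assert labels["b1"] == labels["b2"]
        assert labels["a1"] != labels["b1"]

    def test_constant_rows_handled(self):
        mat = pd.DataFrame(
            [[1.0, 1.0, 1.0], [1.0, 1.0, 1.0], [0.0, 3.0, 9.0]],
            index=["c1", "c2", "v"], columns=list("xyz"),
        )
        out = cluster_matrix(mat)
        assert set(out.row_order) == {"c1", "c2", "v"}

    def test_nonfinite_rejected(self):
        mat = pd.DataFrame([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError, match="non-finite"):
            cluster_matrix(mat)

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        mat = pd.DataFrame(rng.normal(size=(8, 5)))
        a, b = cluster_matrix(mat), cluster_matrix(mat)
        assert a.row_order == b.row_order and a.col_order == b.col_order


class TestRunCollections:
    def _setup(self):
        universe = _genes("u", 200)
        groups = {
            "9.1001": set(universe[:30]),
            "1.1000": set(universe[30:55]),
            "8.0001": set(universe[55:70]),
        }
        sets = [
            GeneSet(f"S{i}", "d", frozenset(universe[i * 20 : i * 20 + 25]))
            for i in range(5)
        ]
        return universe, groups, sets

    def test_cartesian_completeness(self):
        universe, groups, sets = self._setup()
        out = run_collections(groups, {"go": sets}, universe)
        assert len(out["go"]["records"]) == 15  # 3 groups x 5 sets

    def test_empty_collection_is_fine(self):
        universe, groups, _ = self._setup()
        out = run_collections(groups, {"mirna": []}, universe)
        assert out["mirna"]["records"].empty
        assert out["mirna"]["clustered"] is None

    def test_identifier_space_mismatch_warns(self):
        universe, groups, _ = self._setup()
        alien = [GeneSet("A", "d", frozenset(["x1", "x2", "x3"]))]
        with pytest.warns(UserWarning, match="identifier spaces"):
            run_collections(groups, {"motif": alien}, universe)

    def test_planted_set_destroyed_by_permutation(self):
        # permuting gene labels must destroy a planted enrichment: the
        # planted set's Fisher p under random groups is essentially uniform
        universe = _genes("u", 500)
        rng = np.random.default_rng(42)
        group = set(rng.choice(universe, size=40, replace=False))
        planted = GeneSet("P", "d", frozenset(sorted(group)[:30]))
        observed = fisher_enrichment(group, planted, universe).p
        assert observed < 1e-10
        perm_ps = []
        for _ in range(200):
            fake = rng.choice(universe, size=40, replace=False)
            perm_ps.append(fisher_enrichment(fake, planted, universe).p)
        perm_ps = np.array(perm_ps)
        assert (perm_ps <= observed).mean() <= 0.05
        assert np.median(perm_ps) > 0.05
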