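"""F_ST estimation, comparison enumeration, parallel sets, orientation."""

import numpy as np
import pytest
from scipy.stats import hypergeom, ks_2samp

from paradiverge.divergence import (
    build_fst_panel,
    divergent_set,
    enumerate_comparisons,
    orientation,
    orientation_skew,
    pairwise_fst,
    parallel_divergent,
    tree_path_edges,
    weir_cockerham_fst,
)
from paradiverge.io_model import (
    DivergenceComparison,
    GroupPair,
    GroupScheme,
    UndefinedStatisticError,
)

from conftest import make_table, path_edges_bruteforce, random_group_table, wc_theta_scalar


class TestWeirCockerham:
    def test_fixed_difference_gives_one(self):
        assert weir_cockerham_fst(20, 20, 0, 30, het1=0, het2=0) == pytest.approx(1.0)

    def test_identical_frequencies_give_nonpositive_theta(self):
        theta = weir_cockerham_fst(50, 100, 50, 100)
        assert theta <= 0  # finite-sample correction pushes below zero

    def test_example_against_independent_long_hand(self):
        # p1=0.9, p2=0.5, 50 diploids each, HWE heterozygosity
        theta = weir_cockerham_fst(90, 100, 50, 100)
        assert theta == pytest.approx(wc_theta_scalar(90, 100, 50, 100))

    def test_hundred_random_fixtures_match_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            n1 = int(rng.integers(2, 120)) * 2
            n2 = int(rng.integers(2, 120)) * 2
            a1 = int(rng.integers(0, n1 + 1))
            a2 = int(rng.integers(0, n2 + 1))
            if a1 + a2 == 0 or a1 + a2 == n1 + n2:
                continue
            h1 = int(rng.integers(0, min(a1, n1 - a1) + 1))
            h2 = int(rng.integers(0, min(a2, n2 - a2) + 1))
            got = weir_cockerham_fst(a1, n1, a2, n2, het1=h1, het2=h2)
            want = wc_theta_scalar(a1, n1, a2, n2, het1=h1, het2=h2)
            assert got == pytest.approx(want, rel=1e-10, abs=1e-12)

    def test_symmetry_in_groups(self):
        rng = np.random.default_rng(22)
        a1, n1, a2, n2 = 33, 80, 61, 122
        assert weir_cockerham_fst(a1, n1, a2, n2) == pytest.approx(
            weir_cockerham_fst(a2, n2, a1, n1))

    def test_count_scaling_changes_only_sample_size_terms(self):
        # frozen regression values: scaling all counts x10 keeps frequencies
        # but changes finite-sample corrections
        small = weir_cockerham_fst(9, 20, 5, 20)
        big = weir_cockerham_fst(90, 200, 50, 200)
        assert small != pytest.approx(big)
        assert big == pytest.approx(wc_theta_scalar(90, 200, 50, 200))

    def test_monomorphic_pooled_pair_is_error(self):
        with pytest.raises(UndefinedStatisticError):
            weir_cockerham_fst(0, 20, 0, 20)


def _random_tree(rng, n_tips):
    """Random binary newick over n_tips labelled groups."""
    nodes = [f"G{i}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        nodes = [n for k, n in enumerate(nodes) if k not in (int(i), int(j))]
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"


class TestEnumerateComparisons:
    def test_six_group_tree_gives_fifteen_comparisons_eleven_pairs(self, six_scheme):
        comps = enumerate_comparisons(six_scheme)
        assert len(comps) == 15
        pairs = {p for c in comps for p in (c.pair1, c.pair2)}
        assert len(pairs) == 11

    def test_four_tip_tree_gives_single_comparison(self, four_scheme):
        comps = enumerate_comparisons(four_scheme)
        assert len(comps) == 1
        assert {comps[0].pair1, comps[0].pair2} == {
            GroupPair.of("A", "B"), GroupPair.of("C", "D")}

    def test_three_groups_give_empty_list(self):
        sch = GroupScheme.__new__(GroupScheme)  # bypass >=4 group validation
        sch.pop_to_group = {"p1": "A", "p2": "B", "p3": "C"}
        sch.pop_sizes = {"p1": 1, "p2": 1, "p3": 1}
        sch.newick = "(A,(B,C));"
        import dendropy
        sch.tree = dendropy.Tree.get(data=sch.newick, schema="newick",
                                     suppress_internal_node_taxa=True)
        assert enumerate_comparisons(sch) == []

    def test_agrees_with_bipartition_bruteforce_on_random_trees(self):
        """Path-edge disjointness via the graph walk must match the
        bipartition-separation oracle on 200 random 4-8 tip trees."""
        rng = np.random.default_rng(23)
        for _ in range(200):
            n_tips = int(rng.integers(4, 9))
            newick = _random_tree(rng, n_tips)
            sch = GroupScheme(
                pop_to_group={f"p{i}": f"G{i}" for i in range(n_tips)},
                pop_sizes={f"p{i}": 5 for i in range(n_tips)},
                newick=newick,
            )
            got = {(c.pair1.labels, c.pair2.labels) for c in enumerate_comparisons(sch)}
            oracle_paths = path_edges_bruteforce(newick)
            from itertools import combinations
            tips = sorted(sch.groups)
            want = set()
            for p1, p2 in combinations(combinations(tips, 2), 2):
                if set(p1) & set(p2):
                    continue
                if oracle_paths[frozenset(p1)] & oracle_paths[frozenset(p2)]:
                    continue
                want.add(tuple(sorted([tuple(sorted(p1)), tuple(sorted(p2))])))
            got_norm = {tuple(sorted([a, b])) for a, b in got}
            assert got_norm == want

    def test_edge_disjointness_recorded(self, six_scheme):
        for comp in enumerate_comparisons(six_scheme):
            assert comp.edges1 and comp.edges2
            assert not comp.edges1 & comp.edges2


def _panel_from_fst(fst_matrix, pairs, seed=0, ids=None):
    from paradiverge.divergence import FstPanel
    from scipy.stats import rankdata

    fst = np.asarray(fst_matrix, dtype=float)
    n, k = fst.shape
    rng = np.random.default_rng(seed)
    strict = np.empty_like(fst, dtype=np.int64)
    dense = np.empty_like(strict)
    for j in range(k):
        dense[:, j] = rankdata(fst[:, j], method="dense")
        order = np.lexsort((rng.random(n), fst[:, j]))
        strict[order, j] = np.arange(1, n + 1)
    return FstPanel(
        ids=np.array(ids if ids is not None else [f"s{i}" for i in range(n)], dtype=object),
        pairs=tuple(pairs), fst=fst, dense_rank=dense, strict_rank=strict, seed=seed)


PAIR_AB = GroupPair.of("A", "B")
PAIR_CD = GroupPair.of("C", "D")
COMP_ABCD = DivergenceComparison(pair1=PAIR_AB, pair2=PAIR_CD)


class TestDivergentSets:
    def test_exact_size_and_threshold_property(self):
        rng = np.random.default_rng(24)
        panel = _panel_from_fst(rng.random((100, 1)), [PAIR_AB])
        sel = divergent_set(panel, PAIR_AB, 0.05)
        assert len(sel) == 5
        members = np.isin(panel.ids, list(sel))
        assert panel.fst[members, 0].min() >= panel.fst[~members, 0].max()

    def test_quarter_threshold_of_eight(self):
        panel = _panel_from_fst(np.arange(8)[:, None] / 10, [PAIR_AB])
        assert len(divergent_set(panel, PAIR_AB, 0.25)) == 2

    def test_all_ties_still_exact_size(self):
        panel = _panel_from_fst(np.zeros((40, 1)), [PAIR_AB], seed=5)
        assert len(divergent_set(panel, PAIR_AB, 0.1)) == 4

    def test_rank_construction_on_panel(self, six_scheme):
        rng = np.random.default_rng(25)
        t = random_group_table(six_scheme, 50, rng)
        panel = build_fst_panel(t, six_scheme, seed=1)
        n = panel.n_snps
        for j in range(panel.strict_rank.shape[1]):
            assert sorted(panel.strict_rank[:, j]) == list(range(1, n + 1))


class TestParallelDivergent:
    def test_identical_columns_give_maximal_overlap(self):
        rng = np.random.default_rng(26)
        col = rng.random(60)
        panel = _panel_from_fst(np.column_stack([col, col]), [PAIR_AB, PAIR_CD])
        res = parallel_divergent(panel, COMP_ABCD, 0.1)
        assert res.k == res.m == 6

    def test_disjoint_sets_give_zero(self):
        fst = np.zeros((20, 2))
        fst[:5, 0] = 1.0
        fst[5:10, 1] = 1.0
        panel = _panel_from_fst(fst, [PAIR_AB, PAIR_CD])
        assert parallel_divergent(panel, COMP_ABCD, 0.25).k == 0

    def test_ten_snp_fixture_intersection(self):
        # sets {s1,s2} and {s2,s9} at t = 0.2 -> k = 1 (s2)
        fst = np.zeros((10, 2))
        fst[[1, 2], 0] = [0.9, 0.8]
        fst[[2, 9], 1] = [0.7, 0.9]
        panel = _panel_from_fst(fst, [PAIR_AB, PAIR_CD])
        res = parallel_divergent(panel, COMP_ABCD, 0.2)
        assert res.parallel_ids == ["s2"] and res.k == 1
        assert res.categories == {"parallel": 1, "one_pair": 2, "none": 7}

    def test_overlap_matches_sortfree_oracle(self):
        rng = np.random.default_rng(27)
        fst = rng.random((200, 2))
        panel = _panel_from_fst(fst, [PAIR_AB, PAIR_CD])
        res = parallel_divergent(panel, COMP_ABCD, 0.05)
        # oracle: boolean top-m masks via argpartition, no sorting of sets
        m = res.m
        mask1 = np.zeros(200, bool)
        mask1[np.argpartition(panel.strict_rank[:, 0], -m)[-m:]] = True
        mask2 = np.zeros(200, bool)
        mask2[np.argpartition(panel.strict_rank[:, 1], -m)[-m:]] = True
        assert res.k == int((mask1 & mask2).sum())

    def test_permutation_null_is_hypergeometric(self):
        """Shuffling one pair's ranks reproduces the fixed-margins
        hypergeometric overlap law."""
        rng = np.random.default_rng(28)
        n, t, shuffles = 400, 0.1, 3000
        m = int(t * n)
        base = np.zeros(n, bool)
        base[:m] = True
        overlaps = np.empty(shuffles, dtype=int)
        for i in range(shuffles):
            overlaps[i] = int((base & rng.permutation(base)).sum())
        ref = hypergeom(n, m, m).rvs(size=shuffles, random_state=29)
        assert ks_2samp(overlaps, ref).pvalue > 0.01


class TestOrientation:
    GI = {"A": 0, "B": 1, "C": 2, "D": 3}

    def test_same_and_opposite(self):
        assert orientation(np.array([0.9, 0.1, 0.8, 0.2]), COMP_ABCD, self.GI) == "same"
        assert orientation(np.array([0.9, 0.1, 0.2, 0.8]), COMP_ABCD, self.GI) == "opposite"

    def test_tie_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            orientation(np.array([0.5, 0.5, 0.8, 0.2]), COMP_ABCD, self.GI)

    def test_allele_relabel_invariance(self):
        rng = np.random.default_rng(30)
        for _ in range(200):
            f = rng.uniform(0.01, 0.99, size=4)
            if f[0] == f[1] or f[2] == f[3]:
                continue
            assert orientation(f, COMP_ABCD, self.GI) == orientation(1 - f, COMP_ABCD, self.GI)

    def test_skew_values(self):
        def result(n_same, n_opp):
            from paradiverge.divergence import ParallelResult
            ids = [f"s{i}" for i in range(n_same + n_opp)]
            return ParallelResult(
                comparison=COMP_ABCD, threshold=0.05, m=10,
                divergent1=set(ids), divergent2=set(ids), parallel_ids=ids,
                n_same=n_same, n_opposite=n_opp, n_orientation_excluded=0,
                categories={}, per_snp_orientation={})

        assert orientation_skew(result(2, 0)) == 1.0
        assert orientation_skew(result(2, 2)) == 0.5
        assert orientation_skew(result(3, 1)) == 0.75
        assert orientation_skew(result(0, 0)) is None

    def test_orientation_tally_invariant_under_relabeling_table(self, six_scheme):
        """Flipping the tracked allele at every SNP leaves per-comparison
        orientation tallies unchanged."""
        rng = np.random.default_rng(31)
        t = random_group_table(six_scheme, 120, rng)
        from paradiverge.filtering import filter_globally_polymorphic, group_frequencies
        t = filter_globally_polymorphic(t, six_scheme)
        flipped = make_table(t.populations, t.nobs - t.alt, t.nobs, het=t.het,
                             chrom=t.chrom, pos=t.pos, ids=list(t.ids))
        comp = enumerate_comparisons(six_scheme)[0]
        for a, b in [(t, flipped)]:
            pa = build_fst_panel(a, six_scheme, seed=2)
            pb = build_fst_panel(b, six_scheme, seed=2)
            fa = group_frequencies(a, six_scheme)
            fb = group_frequencies(b, six_scheme)
            ra = parallel_divergent(pa, comp, 0.1, fa, six_scheme.groups)
            rb = parallel_divergent(pb, comp, 0.1, fb, six_scheme.groups)
            assert (ra.n_same, ra.n_opposite) == (rb.n_same, rb.n_opposite)
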