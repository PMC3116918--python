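"""Pairwise F_ST, divergence comparisons, parallel divergent SNPs, orientation.

A *divergence comparison* contrasts the per-SNP F_ST values of two
disjoint group pairs whose connecting paths on the unrooted group tree
share no branch, so the two divergences accrued on phylogenetically
independent branches.  For each pair the top fraction ``t`` of F_ST
ranks are the *divergent* SNPs; SNPs divergent in both pairs of a
comparison are *parallel divergent*.  Each parallel divergent SNP has a
binary *orientation*: whether the group with the relatively higher
tracked-allele frequency in the first pair aligns with the first or the
second group of the second pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
from scipy.stats import rankdata

from .io_model import (
    DivergenceComparison,
    GroupPair,
    GroupScheme,
    SnpTable,
    UndefinedStatisticError,
)
from .filtering import group_allele_counts

__all__ = [
    "pairwise_fst",
    "weir_cockerham_fst",
    "tree_path_edges",
    "enumerate_comparisons",
    "FstPanel",
    "build_fst_panel",
    "divergent_set",
    "ParallelResult",
    "parallel_divergent",
    "orientation",
    "orientation_skew",
]


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) two-deme F_ST


def weir_cockerham_fst(
    alt1, nobs1, alt2, nobs2, het1=None, het2=None
) -> np.ndarray:
    """Weir–Cockerham θ̂ = a/(a+b+c) for two demes, vectorized over SNPs.

    Counts are allele copies (``nobs`` = 2x diploids); ``het`` counts
    heterozygous individuals and, when omitted, HWE-expected
    heterozygosity 2p̂(1−p̂) is used.  Monomorphic pooled pairs yield an
    undefined (NaN-free) error if scalar, NaN if vectorized — callers are
    expected to have pre-filtered such SNPs.
    """
    alt1 = np.asarray(alt1, dtype=np.float64)
    alt2 = np.asarray(alt2, dtype=np.float64)
    nobs1 = np.asarray(nobs1, dtype=np.float64)
    nobs2 = np.asarray(nobs2, dtype=np.float64)
    if np.any(nobs1 < 2) or np.any(nobs2 < 2):
        raise UndefinedStatisticError("each group needs at least 2 allele copies")
    n1 = nobs1 / 2.0  # diploid sample sizes
    n2 = nobs2 / 2.0
    p1 = alt1 / nobs1
    p2 = alt2 / nobs2
    h1 = 2.0 * p1 * (1.0 - p1) if het1 is None else np.asarray(het1, np.float64) / n1
    h2 = 2.0 * p2 * (1.0 - p2) if het2 is None else np.asarray(het2, np.float64) / n2

    nbar = (n1 + n2) / 2.0
    nc = 2.0 * nbar - (n1**2 + n2**2) / (2.0 * nbar)
    pbar = (n1 * p1 + n2 * p2) / (2.0 * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
    hbar = (n1 * h1 + n2 * h2) / (2.0 * nbar)

    a = (nbar / nc) * (
        s2 - (pbar * (1.0 - pbar) - s2 / 2.0 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1.0 - pbar) - s2 / 2.0 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
    )
    c = hbar / 2.0
    denom = a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(denom != 0.0, a / denom, np.nan)
    pooled = (alt1 + alt2, nobs1 + nobs2)
    mono = (pooled[0] == 0) | (pooled[0] == pooled[1])
    if np.ndim(theta) == 0:
        if mono:
            raise UndefinedStatisticError("F_ST undefined for a monomorphic pooled pair")
        return float(theta)
    theta = np.asarray(theta)
    theta[mono] = np.nan
    return theta


def pairwise_fst(
    table: SnpTable, scheme: GroupScheme, pair: GroupPair
) -> np.ndarray:
    """Per-SNP Weir–Cockerham F_ST between the two groups of a pair."""
    pops1 = scheme.populations_of(pair.first)
    pops2 = scheme.populations_of(pair.second)
    alt1, n1 = table.pooled_counts(pops1)
    alt2, n2 = table.pooled_counts(pops2)
    h1 = table.pooled_het(pops1)
    h2 = table.pooled_het(pops2)
    return weir_cockerham_fst(alt1, n1, alt2, n2, h1, h2)


# ---------------------------------------------------------------------------
# Divergence comparison enumeration


def _unrooted_graph(scheme: GroupScheme) -> nx.Graph:
    """Undirected graph of the group tree with a degree-2 root contracted."""
    graph = nx.Graph()
    tree = scheme.tree
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        graph.add_edge(id(edge.tail_node), id(edge.head_node))
    labels = {}
    for leaf in tree.leaf_node_iter():
        labels[id(leaf)] = leaf.taxon.label
    # contract the artificial degree-2 root of a rooted-binary newick
    root = id(tree.seed_node)
    if root in graph and graph.degree[root] == 2 and root not in labels:
        a, b = list(graph.neighbors(root))
        graph.remove_node(root)
        graph.add_edge(a, b)
    nx.set_node_attributes(graph, labels, "label")
    return graph


def tree_path_edges(scheme: GroupScheme) -> dict[GroupPair, frozenset]:
    """Edge set of the tip-to-tip path for every group pair."""
    graph = _unrooted_graph(scheme)
    tip_node = {
        data["label"]: node
        for node, data in graph.nodes(data=True)
        if "label" in data
    }
    out: dict[GroupPair, frozenset] = {}
    for a, b in combinations(sorted(tip_node), 2):
        path = nx.shortest_path(graph, tip_node[a], tip_node[b])
        edges = frozenset(frozenset(e) for e in zip(path[:-1], path[1:]))
        out[GroupPair.of(a, b)] = edges
    return out


def enumerate_comparisons(scheme: GroupScheme) -> list[DivergenceComparison]:
    """All divergence comparisons: unordered pairs of disjoint group pairs
    whose tree paths share no edge.  Deterministic canonical order
    (lexicographic by pair labels); the six-group tree yields 15.
    """
    if len(scheme.groups) < 4:
        return []
    paths = tree_path_edges(scheme)
    pairs = sorted(paths, key=lambda p: p.labels)
    comparisons = []
    for p1, p2 in combinations(pairs, 2):
        if set(p1.labels) & set(p2.labels):
            continue
        if paths[p1] & paths[p2]:
            continue
        comparisons.append(
            DivergenceComparison(pair1=p1, pair2=p2, edges1=paths[p1], edges2=paths[p2])
        )
    return comparisons


# ---------------------------------------------------------------------------
# F_ST panel and ranks


@dataclass
class FstPanel:
    """Per-SNP F_ST values and ranks for every analyzed group pair.

    ``strict_rank`` is a seeded total order (1 = lowest F_ST, N = highest;
    exact ties broken uniformly at random with the panel seed) so that
    top-``m`` divergent sets have exactly ``m`` members.  ``dense_rank``
    keeps ties tied.
    """

    ids: np.ndarray
    pairs: tuple[GroupPair, ...]
    fst: np.ndarray  # (S, K)
    dense_rank: np.ndarray  # (S, K)
    strict_rank: np.ndarray  # (S, K), permutation of 1..S per column
    seed: int | None = None

    @property
    def n_snps(self) -> int:
        return len(self.ids)

    def column(self, pair: GroupPair) -> int:
        try:
            return self.pairs.index(pair)
        except ValueError as exc:
            raise KeyError(f"pair {pair} not in panel") from exc


def build_fst_panel(
    table: SnpTable,
    scheme: GroupScheme,
    pairs: list[GroupPair] | None = None,
    seed: int | None = None,
) -> FstPanel:
    """Compute F_ST and both rank conventions for the analyzed pairs."""
    from .filtering import analyzed_pairs

    if pairs is None:
        pairs = analyzed_pairs(scheme)
    rng = np.random.default_rng(seed)
    n = table.n_snps
    fst = np.empty((n, len(pairs)))
    dense = np.empty((n, len(pairs)), dtype=np.int64)
    strict = np.empty((n, len(pairs)), dtype=np.int64)
    for k, pair in enumerate(pairs):
        values = pairwise_fst(table, scheme, pair)
        if np.any(np.isnan(values)):
            raise UndefinedStatisticError(
                f"F_ST undefined for pair {pair} at some SNPs; pre-filter first"
            )
        fst[:, k] = values
        dense[:, k] = rankdata(values, method="dense")
        tiebreak = rng.random(n)
        order = np.lexsort((tiebreak, values))
        strict[order, k] = np.arange(1, n + 1)
    return FstPanel(
        ids=table.ids, pairs=tuple(pairs), fst=fst, dense_rank=dense,
        strict_rank=strict, seed=seed,
    )


def divergent_set(panel: FstPanel, pair: GroupPair, t: float) -> set[str]:
    """The floor(t*N) SNP ids with the highest F_ST for the pair."""
    if not 0 < t < 1:
        raise ValueError("threshold t must lie in (0, 1)")
    n = panel.n_snps
    m = int(np.floor(t * n))
    col = panel.strict_rank[:, panel.column(pair)]
    return set(panel.ids[col > n - m])


# ---------------------------------------------------------------------------
# Parallel divergent SNPs and orientation


@dataclass
class ParallelResult:
    """Parallel divergent SNPs of one divergence comparison."""

    comparison: DivergenceComparison
    threshold: float
    m: int
    divergent1: set[str]
    divergent2: set[str]
    parallel_ids: list[str]
    n_same: int
    n_opposite: int
    n_orientation_excluded: int
    categories: dict[str, int]  # parallel / one_pair / none counts
    per_snp_orientation: dict[str, str] = None  # snp_id -> same/opposite

    @property
    def k(self) -> int:
        return len(self.parallel_ids)

    @property
    def n_major(self) -> int:
        return max(self.n_same, self.n_opposite)

    @property
    def n_minor(self) -> int:
        return min(self.n_same, self.n_opposite)

    @property
    def major_orientation(self) -> str | None:
        if self.n_same == self.n_opposite:
            return None
        return "same" if self.n_same > self.n_opposite else "opposite"

    @property
    def skew(self) -> float | None:
        """Frequency of the major orientation; None when undefined (k=0
        after tie exclusions)."""
        tallied = self.n_same + self.n_opposite
        if tallied == 0:
            return None
        return self.n_major / tallied


def orientation(
    freq: np.ndarray, comparison: DivergenceComparison, group_index: dict[str, int]
) -> str:
    """Orientation of one SNP: 'same' iff the frequency differences within
    the two (canonically ordered) pairs have equal sign.

    ``freq`` holds the tracked-allele group frequencies; an exact tie
    within either pair makes the orientation undefined.
    """
    d1 = (
        freq[group_index[comparison.pair1.first]]
        - freq[group_index[comparison.pair1.second]]
    )
    d2 = (
        freq[group_index[comparison.pair2.first]]
        - freq[group_index[comparison.pair2.second]]
    )
    if d1 == 0 or d2 == 0:
        raise UndefinedStatisticError("orientation undefined at an exact frequency tie")
    return "same" if (d1 > 0) == (d2 > 0) else "opposite"


def parallel_divergent(
    panel: FstPanel,
    comparison: DivergenceComparison,
    t: float,
    group_freqs: np.ndarray | None = None,
    groups: tuple[str, ...] | None = None,
) -> ParallelResult:
    """Intersect the two divergent sets of a comparison and tally
    orientations.

    ``group_freqs`` (S, G) and ``groups`` supply pooled tracked-allele
    frequencies for the orientation tally; when omitted the tally is
    skipped (counts zero, skew undefined).
    """
    set1 = divergent_set(panel, comparison.pair1, t)
    set2 = divergent_set(panel, comparison.pair2, t)
    inter = set1 & set2
    id_index = {s: i for i, s in enumerate(panel.ids)}
    parallel_ids = sorted(inter, key=lambda s: id_index[s])

    n_same = n_opp = n_excluded = 0
    per_snp: dict[str, str] = {}
    if group_freqs is not None and groups is not None and parallel_ids:
        gi = {g: j for j, g in enumerate(groups)}
        for snp in parallel_ids:
            try:
                o = orientation(group_freqs[id_index[snp]], comparison, gi)
            except UndefinedStatisticError:
                n_excluded += 1
                continue
            per_snp[snp] = o
            if o == "same":
                n_same += 1
            else:
                n_opp += 1

    n = panel.n_snps
    one_pair = len(set1 ^ set2)
    categories = {
        "parallel": len(inter),
        "one_pair": one_pair,
        "none": n - len(inter) - one_pair,
    }
    m = int(np.floor(t * n))
    return ParallelResult(
        comparison=comparison,
        threshold=t,
        m=m,
        divergent1=set1,
        divergent2=set2,
        parallel_ids=parallel_ids,
        n_same=n_same,
        n_opposite=n_opp,
        n_orientation_excluded=n_excluded,
        categories=categories,
        per_snp_orientation=per_snp,
    )


def orientation_skew(result: ParallelResult) -> float | None:
    """Frequency of the more common orientation; None when k = 0."""
    return result.skew


def group_frequency_matrix(table: SnpTable, scheme: GroupScheme):
    """(freqs, groups) convenience wrapper for the orientation tally."""
    from .filtering import group_frequencies

    return group_frequencies(table, scheme), scheme.groups
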