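"""Shared fixtures and independent oracle implementations.

The oracle functions here are deliberately written long-hand and
independently of the package internals so they can serve as
cross-checks (dual-implementation tests).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from paradiverge.io_model import GroupScheme, SnpTable
from paradiverge.simulate import default_scheme


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture(scope="session")
def six_scheme() -> GroupScheme:
    """The six-group HGDP-like scheme on the study topology."""
    return default_scheme()


@pytest.fixture(scope="session")
def four_scheme() -> GroupScheme:
    return GroupScheme(
        pop_to_group={"a1": "A", "b1": "B", "c1": "C", "d1": "D"},
        pop_sizes={"a1": 10, "b1": 12, "c1": 9, "d1": 11},
        newick="((A,B),(C,D));",
    )


def make_table(
    pops,
    alt,
    nobs,
    het=None,
    chrom=None,
    pos=None,
    ids=None,
    dosages=None,
) -> SnpTable:
    """Construct a SnpTable from plain lists/arrays."""
    alt = np.asarray(alt)
    s = alt.shape[0]
    return SnpTable(
        ids=np.array(ids if ids is not None else [f"snp{i}" for i in range(s)], dtype=object),
        chrom=np.array(chrom if chrom is not None else ["1"] * s, dtype=object),
        pos=np.asarray(pos if pos is not None else (np.arange(s) + 1) * 20_000_000),
        populations=tuple(pops),
        alt=alt,
        nobs=np.asarray(nobs),
        het=None if het is None else np.asarray(het),
        dosages=dosages,
    )


@pytest.fixture()
def table_factory():
    return make_table


def random_group_table(scheme: GroupScheme, n_snps: int, rng: np.random.Generator,
                       base=None) -> SnpTable:
    """A random diploid count table over a scheme's populations: each SNP
    gets an independent frequency per group plus binomial sampling."""
    pops = tuple(sorted(scheme.pop_to_group))
    groups = scheme.groups
    if base is None:
        base = rng.uniform(0.2, 0.8, size=(n_snps, len(groups)))
    gi = {g: j for j, g in enumerate(groups)}
    alt = np.empty((n_snps, len(pops)), dtype=np.int64)
    nobs = np.empty_like(alt)
    het = np.empty_like(alt)
    for j, p in enumerate(pops):
        n = scheme.pop_sizes[p]
        freq = base[:, gi[scheme.pop_to_group[p]]]
        n_aa = rng.binomial(n, freq**2)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_het = np.where(freq < 1, 2 * freq * (1 - freq) / (1 - freq**2), 0.0)
        n_het = rng.binomial(n - n_aa, np.clip(p_het, 0, 1))
        alt[:, j] = 2 * n_aa + n_het
        het[:, j] = n_het
        nobs[:, j] = 2 * n
    return make_table(pops, alt, nobs, het=het)


# ---------------------------------------------------------------------------
# Oracles


def wc_theta_scalar(ac1, an1, ac2, an2, het1=None, het2=None) -> float:
    """Long-hand scalar Weir & Cockerham (1984) two-deme theta.

    Written directly from the published variance-component definitions,
    independent of the package's vectorized implementation.
    """
    r = 2
    n1 = an1 / 2.0
    n2 = an2 / 2.0
    p1 = ac1 / an1
    p2 = ac2 / an2
    if het1 is None:
        h1 = 2.0 * p1 * (1.0 - p1)
    else:
        h1 = het1 / n1
    if het2 is None:
        h2 = 2.0 * p2 * (1.0 - p2)
    else:
        h2 = het2 / n2
    nbar = (n1 + n2) / r
    csq = ((n1 - nbar) ** 2 + (n2 - nbar) ** 2) / ((r - 1) * nbar**2) if nbar else 0.0
    nc = nbar * (1.0 - csq / r)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    ssq = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        ssq
        - (1.0 / (nbar - 1.0))
        * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * ssq - hbar / 4.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1.0 - pbar)
        - ((r - 1.0) / r) * ssq
        - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
    )
    c = hbar / 2.0
    denom = a + b + c
    return float("nan") if denom == 0 else a / denom


def overlap_distribution_exhaustive(n: int, m: int):
    """Exact overlap distribution of two independent size-m subsets of n
    items, by enumerating the second subset against a fixed first one
    (valid by symmetry).  Returns pmf indexed by overlap 0..m."""
    from itertools import combinations

    first = set(range(m))
    counts = np.zeros(m + 1, dtype=np.int64)
    total = 0
    for second in combinations(range(n), m):
        counts[len(first & set(second))] += 1
        total += 1
    return counts / total


def path_edges_bruteforce(newick: str):
    """Tip-pair path edge sets via the bipartition-separation rule: the
    path between tips a and b consists of exactly the edges whose tip
    bipartition separates a from b.  Independent of the package's
    graph-walk implementation."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True)
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    # collect one tip-side per edge, skipping the root edge and one of the
    # two duplicate root-adjacent edges of a rooted-binary representation
    sides = []
    seen = set()
    for node in tree.postorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        key = min(below, frozenset(tips) - below, key=sorted)
        if key in seen or len(below) in (0, len(tips)):
            continue
        seen.add(key)
        sides.append(below)
    out = {}
    for i, a in enumerate(tips):
        for b in tips[i + 1:]:
            out[frozenset((a, b))] = frozenset(
                s for s in sides if (a in s) != (b in s)
            )
    return out
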