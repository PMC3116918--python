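"""Null models and significance tests for parallel divergence.

Under neutrality the two divergent sets of a comparison are two
independent draws of m = floor(t*N) SNPs from N, so their overlap K
follows the fixed-margins hypergeometric law

    K ~ Hypergeometric(N, m, m),
    E[K] = m^2/N  (approx. N t^2),
    SD[K] = sqrt(m * (m/N) * (1 - m/N) * (N - m)/(N - 1)).

Orientations of the K parallel divergent SNPs are i.i.d. fair coin flips
under neutrality, so the expected skew is E[max(X, K-X)]/K with
X ~ Binomial(K, 1/2).  Observed counts are tested with Fisher's exact
test on the 2x2 divergent-by-divergent table, skews with an exact
binomial test, and both against simulation nulls via an add-one
empirical p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.stats import rankdata

from .divergence import FstPanel, divergent_set
from .io_model import DivergenceComparison, ParadivergeError

__all__ = [
    "NullSpec",
    "expected_parallel_count",
    "null_sd",
    "fisher_parallel_test",
    "binomial_skew_expectation",
    "skew_test",
    "empirical_null_pvalue",
    "nondivergent_rank_correlation",
    "category_enrichment",
    "ComparisonTests",
    "comparison_tests",
]


@dataclass(frozen=True)
class NullSpec:
    """Null-model geometry: N analyzed SNPs, threshold t, m divergent per pair."""

    n_snps: int
    threshold: float

    def __post_init__(self) -> None:
        if not 0 < self.m < self.n_snps:
            raise ValueError("need 0 < floor(t*N) < N")

    @property
    def m(self) -> int:
        return int(np.floor(self.threshold * self.n_snps))


def expected_parallel_count(spec: NullSpec, *, exact: bool = False) -> float:
    """Expected parallel divergent SNPs per comparison under the null.

    The headline closed form is N*t^2; with ``exact=True`` the
    fixed-margins hypergeometric mean m^2/N is returned instead.
    """
    if exact:
        return spec.m**2 / spec.n_snps
    return spec.n_snps * spec.threshold**2


def null_sd(spec: NullSpec) -> float:
    """Standard deviation of the overlap of two independent size-m subsets
    of N SNPs (hypergeometric with both margins m).

    The margin is taken at its real value m = t*N, so the closed form
    sqrt(m * (m/N) * (1 - m/N) * (N - m)/(N - 1)) pairs with the N*t^2
    expectation; whenever t*N is an integer this is exactly the
    hypergeometric standard deviation.
    """
    n = spec.n_snps
    m = spec.threshold * n
    return float(np.sqrt(m * (m / n) * (1 - m / n) * (n - m) / (n - 1)))


def fisher_parallel_test(spec: NullSpec, k: int) -> float:
    """Two-sided Fisher's exact p for observing k parallel divergent SNPs.

    The 2x2 table crosses divergent-in-pair-1 by divergent-in-pair-2 with
    both margins m and grand total N.
    """
    n, m = spec.n_snps, spec.m
    if not 0 <= k <= m:
        raise ParadivergeError(f"overlap k={k} outside [0, m={m}]")
    table = [[k, m - k], [m - k, n - 2 * m + k]]
    return float(sps.fisher_exact(table, alternative="two-sided")[1])


def binomial_skew_expectation(k: int) -> float:
    """E[max(X, k-X)]/k for X ~ Binomial(k, 1/2), by exact summation.

    This is the expected orientation skew among k parallel divergent SNPs
    when both orientations are equally probable; it decays to 1/2 like
    sqrt(1/(2*pi*k)).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = np.arange(k + 1)
    pmf = sps.binom.pmf(x, k, 0.5)
    return float(np.sum(pmf * np.maximum(x, k - x)) / k)


def skew_test(n_major: int, k: int) -> float:
    """Two-sided exact binomial p for the orientation tally: doubled
    one-tail P(X >= n_major) at p=1/2, capped at 1."""
    if n_major < k - n_major:
        raise ValueError("n_major must be the majority count")
    p = 2.0 * sps.binom.sf(n_major - 1, k, 0.5)
    return float(min(1.0, p))


def empirical_null_pvalue(observed: float, simulated) -> float:
    """Add-one empirical p: (1 + #{sim >= observed}) / (n_sim + 1)."""
    sim = np.asarray(list(simulated), dtype=float)
    if sim.size == 0:
        raise ValueError("need at least one simulated value")
    return float((1 + int(np.sum(sim >= observed))) / (sim.size + 1))


def nondivergent_rank_correlation(
    panel: FstPanel, comparison: DivergenceComparison, t: float
) -> tuple[float, float]:
    """Admixture diagnostic: correlation of re-ranked F_ST among SNPs not
    divergent in either pair of the comparison.

    Gene flow between the pairs would leave residual correlation even
    after the divergent tails are removed; under independence the
    correlation is ~0.  Returns (correlation, p-value).
    """
    set1 = divergent_set(panel, comparison.pair1, t)
    set2 = divergent_set(panel, comparison.pair2, t)
    removed = set1 | set2
    keep = np.array([s not in removed for s in panel.ids])
    if keep.sum() < 10:
        raise ParadivergeError("too few non-divergent SNPs for the rank regression")
    c1 = panel.fst[keep, panel.column(comparison.pair1)]
    c2 = panel.fst[keep, panel.column(comparison.pair2)]
    r1 = rankdata(c1)
    r2 = rankdata(c2)
    r, p = sps.pearsonr(r1, r2)
    return float(r), float(p)


def category_enrichment(
    parallel_ids, background_ids, annotations: dict[str, frozenset]
):
    """Per-category fold enrichment of parallel divergent SNPs.

    SNP-level test: for each category, fold = (proportion of parallel
    SNPs in the category) / (proportion of background SNPs in it), with a
    two-sided Fisher's exact p on the 2x2 SNP table.  Returns a DataFrame
    (category, n_parallel, n_background, fold, p, p_bonferroni).
    Categories absent from the background are skipped.
    """
    import pandas as pd

    parallel = set(parallel_ids)
    background = set(background_ids)
    if not parallel <= background:
        raise ParadivergeError("parallel set must be a subset of the background")
    if not parallel:
        return pd.DataFrame(
            columns=["category", "n_parallel", "n_background", "fold", "p", "p_bonferroni"]
        )
    categories: dict[str, set[str]] = {}
    for snp in background:
        for cat in annotations.get(snp, ()):  # un-annotated SNPs contribute nothing
            categories.setdefault(cat, set()).add(snp)
    rows = []
    for cat, members in sorted(categories.items()):
        a = len(parallel & members)
        n_par = len(parallel)
        n_bg_cat = len(members)
        n_bg = len(background)
        table = [[a, n_par - a], [n_bg_cat - a, (n_bg - n_par) - (n_bg_cat - a)]]
        p = float(sps.fisher_exact(table, alternative="two-sided")[1])
        fold = (a / n_par) / (n_bg_cat / n_bg)
        rows.append((cat, a, n_bg_cat, fold, p))
    frame = pd.DataFrame(rows, columns=["category", "n_parallel", "n_background", "fold", "p"])
    frame["p_bonferroni"] = np.minimum(1.0, frame["p"] * len(frame))
    return frame


@dataclass
class ComparisonTests:
    """All attached tests for one comparison's observed overlap and skew."""

    k: float
    expected: float
    sd: float
    fisher_p: float
    bonferroni_significant: bool
    skew: float | None
    skew_expected: float | None
    skew_p: float | None
    empirical_p: float | None = None
    empirical_skew_p: float | None = None


def comparison_tests(
    spec: NullSpec,
    k: int,
    n_major: int,
    *,
    n_comparisons: int = 15,
    alpha: float = 0.05,
    simulated_counts=None,
    simulated_skews=None,
) -> ComparisonTests:
    """Bundle the analytic and (optional) simulation tests for one comparison."""
    fisher_p = fisher_parallel_test(spec, min(k, spec.m))
    skew = None if k == 0 else n_major / k
    return ComparisonTests(
        k=k,
        expected=expected_parallel_count(spec),
        sd=null_sd(spec),
        fisher_p=fisher_p,
        bonferroni_significant=fisher_p < alpha / n_comparisons,
        skew=skew,
        skew_expected=None if k == 0 else binomial_skew_expectation(k),
        skew_p=None if k == 0 else skew_test(n_major, k),
        empirical_p=(
            empirical_null_pvalue(k, simulated_counts)
            if simulated_counts is not None
            else None
        ),
        empirical_skew_p=(
            empirical_null_pvalue(skew, simulated_skews)
            if simulated_skews is not None and skew is not None
            else None
        ),
    )
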