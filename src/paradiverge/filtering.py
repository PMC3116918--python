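"""Reduce a SnpTable to the analysis set.

Four filters define the analysis set, each controlling a confounder of
the parallel-divergence test:

1. *Globally polymorphic* — segregating within every analyzed group pair
   (pooled counts), so that shared alleles are plausibly identical by
   descent rather than recent mutations.
2. *Intermediate frequency* — global minor-allele frequency above a bound
   (default 0.4), controlling for the dependence of drift-driven
   divergence on ancestral frequency.
3. *Unlinked* — pairwise composite linkage disequilibrium |D| below a
   bound (default 0.1) within a physical window (default 10 Mb), averaged
   over one large representative population per group.
4. *Similar spectrum* — the minor-allele-frequency spectrum (10 bins of
   5%) must stay nearly identical across groups while SNPs are accreted,
   controlling ascertainment and demography.

Filters 3 and 4 are enforced by :func:`sample_independent_subset`, a
seeded greedy accretion over a shuffled candidate order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_model import (
    AnalysisConfig,
    GroupScheme,
    SnpTable,
    UndefinedStatisticError,
)

__all__ = [
    "group_allele_counts",
    "group_frequencies",
    "global_maf",
    "filter_globally_polymorphic",
    "filter_intermediate_frequency",
    "composite_ld",
    "mean_composite_ld",
    "sfs_bin_index",
    "sfs_bins",
    "SfsProfile",
    "spectra_compatible",
    "SubsetReplicate",
    "sample_independent_subset",
    "verify_subset",
]


# ---------------------------------------------------------------------------
# Group-level counts and frequencies


def group_allele_counts(table: SnpTable, scheme: GroupScheme):
    """Pooled (alt, n_obs) counts per group; arrays of shape (S, G)."""
    groups = scheme.groups
    alt = np.empty((table.n_snps, len(groups)), dtype=np.int64)
    nobs = np.empty_like(alt)
    for j, g in enumerate(groups):
        a, n = table.pooled_counts(scheme.populations_of(g))
        alt[:, j] = a
        nobs[:, j] = n
    return alt, nobs


def group_frequencies(table: SnpTable, scheme: GroupScheme) -> np.ndarray:
    """Pooled tracked-allele frequency per group, shape (S, G)."""
    alt, nobs = group_allele_counts(table, scheme)
    if np.any(nobs == 0):
        raise UndefinedStatisticError("a group has zero genotyped copies at some SNP")
    return alt / nobs


def global_maf(table: SnpTable, scheme: GroupScheme) -> np.ndarray:
    """Global minor-allele frequency of the pooled counts over all analyzed
    populations; values in [0, 0.5]."""
    pops = [p for p in table.populations if p in scheme.pop_to_group]
    alt, nobs = table.pooled_counts(pops)
    if np.any(nobs == 0):
        raise UndefinedStatisticError("all n_obs zero at some SNP; frequency undefined")
    freq = alt / nobs
    return np.minimum(freq, 1.0 - freq)


# ---------------------------------------------------------------------------
# Polymorphism / frequency filters


def analyzed_pairs(scheme: GroupScheme):
    """Group pairs appearing in at least one valid divergence comparison."""
    from .divergence import enumerate_comparisons

    pairs = []
    for comp in enumerate_comparisons(scheme):
        for pair in (comp.pair1, comp.pair2):
            if pair not in pairs:
                pairs.append(pair)
    return sorted(pairs, key=lambda p: p.labels)


def filter_globally_polymorphic(
    table: SnpTable, scheme: GroupScheme, pairs=None
) -> SnpTable:
    """Keep SNPs segregating within every analyzed group pair (pooled)."""
    if pairs is None:
        pairs = analyzed_pairs(scheme)
    keep = np.ones(table.n_snps, dtype=bool)
    for pair in pairs:
        pops = scheme.populations_of(pair.first) + scheme.populations_of(pair.second)
        alt, nobs = table.pooled_counts(pops)
        keep &= (alt > 0) & (alt < nobs)
    return table.subset(keep)


def filter_intermediate_frequency(
    table: SnpTable, scheme: GroupScheme, maf_bound: float = 0.4
) -> SnpTable:
    """Keep SNPs with global minor-allele frequency strictly above the bound."""
    return table.subset(global_maf(table, scheme) > maf_bound)


# ---------------------------------------------------------------------------
# Composite linkage disequilibrium


def composite_ld(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Genotypic composite disequilibrium Δ between two loci.

    Δ = (1/2n) Σ_i gA_i gB_i − 2 p̂_A p̂_B for dosage vectors g in {0,1,2}
    over the same n ≥ 2 individuals.  Under phased HWE data this reduces
    to the gametic coefficient D.
    """
    ga = np.asarray(dosage_a, dtype=np.float64)
    gb = np.asarray(dosage_b, dtype=np.float64)
    if ga.shape != gb.shape or ga.ndim != 1:
        raise ValueError("dosage vectors must be 1-D and of equal length")
    n = len(ga)
    if n < 2:
        raise UndefinedStatisticError("composite LD needs at least 2 individuals")
    pa = ga.mean() / 2.0
    pb = gb.mean() / 2.0
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise UndefinedStatisticError("composite LD undefined at a monomorphic locus")
    return float((ga @ gb) / (2.0 * n) - 2.0 * pa * pb)


def mean_composite_ld(
    dosages_a: dict[str, np.ndarray], dosages_b: dict[str, np.ndarray]
) -> float:
    """Mean composite Δ over representative populations.

    Populations where Δ is undefined (monomorphic locus) are skipped; if
    it is undefined everywhere an error is raised.
    """
    values = []
    for pop, ga in dosages_a.items():
        try:
            values.append(composite_ld(ga, dosages_b[pop]))
        except UndefinedStatisticError:
            continue
    if not values:
        raise UndefinedStatisticError("composite LD undefined in every population")
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# Site-frequency-spectrum profiles


def sfs_bin_index(maf: np.ndarray, n_bins: int = 10, width: float = 0.05) -> np.ndarray:
    """Bin index of a minor-allele frequency: left-closed, right-open bins,
    with the final bin closed at 0.5."""
    idx = np.floor(np.asarray(maf) / width).astype(np.int64)
    return np.minimum(idx, n_bins - 1)


@dataclass
class SfsProfile:
    """Per-group minor-allele-frequency spectrum (bin counts)."""

    groups: tuple[str, ...]
    counts: np.ndarray  # (G, B) int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        totals = self.counts.sum(axis=1)
        if len(set(totals.tolist())) > 1:
            raise ValueError("SFS bin counts must sum identically across groups")

    @property
    def n_snps(self) -> int:
        return int(self.counts[0].sum()) if len(self.counts) else 0


def sfs_bins(
    table: SnpTable, scheme: GroupScheme, n_bins: int = 10, width: float = 0.05
) -> SfsProfile:
    """Per-group spectrum of the table's SNPs over group-level MAF."""
    freqs = group_frequencies(table, scheme)
    mafs = np.minimum(freqs, 1.0 - freqs)
    counts = np.zeros((freqs.shape[1], n_bins), dtype=np.int64)
    for j in range(freqs.shape[1]):
        bins = sfs_bin_index(mafs[:, j], n_bins, width)
        counts[j] = np.bincount(bins, minlength=n_bins)
    return SfsProfile(groups=scheme.groups, counts=counts)


def spectra_compatible(
    profile: SfsProfile, rel_tol: float = 0.05, abs_floor: int = 100
) -> bool:
    """True iff every bin's count differs between every two groups by less
    than ``abs_floor``, or by at most ``rel_tol`` of the larger count."""
    counts = profile.counts
    n_groups, n_bins = counts.shape
    for b in range(n_bins):
        col = counts[:, b]
        for i in range(n_groups):
            for j in range(i + 1, n_groups):
                diff = abs(int(col[i]) - int(col[j]))
                if diff < abs_floor:
                    continue
                if diff > rel_tol * max(col[i], col[j]):
                    return False
    return True


def _bin_ok(diff: int, mx: int, rel_tol: float, abs_floor: int) -> bool:
    # max-vs-min check is sufficient for the pairwise rule (monotone in the
    # pair spread; see tests for the pairwise oracle).
    return diff < abs_floor or diff <= rel_tol * mx


# ---------------------------------------------------------------------------
# Greedy independent-subset sampling


@dataclass
class SubsetReplicate:
    """One seeded draw of an unlinked, spectrum-matched SNP subset."""

    index: int
    seed: int
    snp_ids: list[str]
    profile: SfsProfile
    n_candidates: int = 0
    n_rejected_ld: int = 0
    n_rejected_sfs: int = 0

    @property
    def size(self) -> int:
        return len(self.snp_ids)


def sample_independent_subset(
    table: SnpTable,
    scheme: GroupScheme,
    config: AnalysisConfig,
    seed: int,
    *,
    index: int = 0,
    target_size: int | None = None,
) -> SubsetReplicate:
    """Greedy randomized accretion of an unlinked, spectrum-matched subset.

    Candidates are shuffled with the seed and accepted one by one iff
    (a) |mean composite D| over representative populations stays below the
    LD bound against every already-accepted SNP within the window on the
    same chromosome, and (b) the running per-group spectrum including the
    SNP remains compatible.  A rejected SNP is skipped permanently within
    the replicate.  Accretion stops after one full pass, or as soon as
    ``target_size`` SNPs (if given) have been accepted.

    The table is assumed to be globally polymorphic and intermediate
    frequency already.
    """
    rng = np.random.default_rng(seed)
    n = table.n_snps
    order = rng.permutation(n)

    freqs = group_frequencies(table, scheme)
    mafs = np.minimum(freqs, 1.0 - freqs)
    bins = np.column_stack(
        [
            sfs_bin_index(mafs[:, j], config.sfs_bins, config.sfs_bin_width)
            for j in range(mafs.shape[1])
        ]
    )  # (S, G)

    reps = scheme.representatives
    rep_pops = [reps[g] for g in scheme.groups]
    have_dosages = table.dosages is not None and all(
        p in table.dosages for p in rep_pops
    )

    n_groups = len(scheme.groups)
    counts = np.zeros((n_groups, config.sfs_bins), dtype=np.int64)
    accepted: list[int] = []
    # per-chromosome sorted accepted positions for the LD window lookup
    by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    n_rej_ld = n_rej_sfs = 0

    import bisect

    if target_size is None:
        target_size = config.target_size

    for i in order:
        chrom = table.chrom[i]
        pos = int(table.pos[i])
        # (a) LD rule against accepted neighbours within the window
        neighbours = []
        if chrom in by_chrom:
            positions, indices = by_chrom[chrom]
            lo = bisect.bisect_left(positions, pos - config.ld_window)
            hi = bisect.bisect_right(positions, pos + config.ld_window)
            neighbours = indices[lo:hi]
        if neighbours:
            if not have_dosages:
                raise UndefinedStatisticError(
                    "LD pruning requires dosage matrices for the representative "
                    "populations when SNPs fall within the same window"
                )
            ok = True
            for j in neighbours:
                d = mean_composite_ld(
                    {p: table.dosages[p][i] for p in rep_pops},
                    {p: table.dosages[p][j] for p in rep_pops},
                )
                if abs(d) >= config.ld_bound:
                    ok = False
                    break
            if not ok:
                n_rej_ld += 1
                continue
        # (b) running-spectrum rule, checking only the bins this SNP touches
        row_bins = bins[i]
        ok = True
        for b in set(row_bins.tolist()):
            col = counts[:, b] + (row_bins == b)
            diff = int(col.max() - col.min())
            if not _bin_ok(diff, int(col.max()), config.sfs_rel_tol, config.sfs_abs_floor):
                ok = False
                break
        if not ok:
            n_rej_sfs += 1
            continue
        counts[np.arange(n_groups), row_bins] += 1
        accepted.append(int(i))
        if chrom not in by_chrom:
            by_chrom[chrom] = ([], [])
        positions, indices = by_chrom[chrom]
        k = bisect.bisect_left(positions, pos)
        positions.insert(k, pos)
        indices.insert(k, int(i))
        if target_size is not None and len(accepted) >= target_size:
            break

    profile = SfsProfile(groups=scheme.groups, counts=counts)
    return SubsetReplicate(
        index=index,
        seed=seed,
        snp_ids=[table.ids[i] for i in accepted],
        profile=profile,
        n_candidates=n,
        n_rejected_ld=n_rej_ld,
        n_rejected_sfs=n_rej_sfs,
    )


def verify_subset(
    table: SnpTable,
    scheme: GroupScheme,
    replicate: SubsetReplicate,
    config: AnalysisConfig,
) -> bool:
    """Post-hoc full verification of a subset: re-checks the pairwise LD
    rule and spectrum compatibility from scratch (independent of the
    accretion bookkeeping)."""
    sub = table.subset_ids(replicate.snp_ids)
    profile = sfs_bins(sub, scheme, config.sfs_bins, config.sfs_bin_width)
    if not spectra_compatible(profile, config.sfs_rel_tol, config.sfs_abs_floor):
        return False
    if not np.array_equal(np.sort(profile.counts, 0), np.sort(replicate.profile.counts, 0)):
        return False
    reps = scheme.representatives
    rep_pops = [reps[g] for g in scheme.groups]
    order = np.lexsort((sub.pos, sub.chrom.astype(str)))
    for a_idx in range(len(order)):
        i = order[a_idx]
        for b_idx in range(a_idx + 1, len(order)):
            j = order[b_idx]
            if sub.chrom[i] != sub.chrom[j]:
                break
            if abs(int(sub.pos[i]) - int(sub.pos[j])) > config.ld_window:
                break
            if sub.dosages is None:
                raise UndefinedStatisticError(
                    "subset contains same-window SNP pairs but no dosage data"
                )
            d = mean_composite_ld(
                {p: sub.dosages[p][i] for p in rep_pops},
                {p: sub.dosages[p][j] for p in rep_pops},
            )
            if abs(d) >= config.ld_bound:
                return False
    return True
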