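"""Domain types and I/O for the parallel-divergence pipeline.

The pipeline works on per-population allele counts rather than raw
genotype matrices: for every biallelic autosomal SNP we keep, for each
population, the number of alternate-allele copies observed, the number of
allele copies genotyped, and (optionally) the number of heterozygous
individuals.  Two input dialects are supported:

* VCF 4.x with diploid genotypes, aggregated via a sample→population map;
* a long-format allele-count TSV with columns
  ``snp  chrom  pos  pop  alt  n  [het]`` (``n`` counts allele copies,
  i.e. twice the number of genotyped diploids; ``het`` counts heterozygous
  individuals and may be omitted).

The population map is a TSV with header ``sample  population  group``;
the same file drives both genotype aggregation and group-scheme
construction.  The group tree is a Newick string whose tips are group
labels; it is treated as unrooted.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("paradiverge")

_AUTOSOME_EXCLUDE = {"X", "Y", "MT", "M", "CHRX", "CHRY", "CHRM", "CHRMT"}


class ParadivergeError(Exception):
    """Base class for pipeline errors."""


class ParseError(ParadivergeError):
    """Malformed input file."""


class EmptyInputError(ParadivergeError):
    """No usable records after parsing/filtering."""


class UndefinedStatisticError(ParadivergeError):
    """A statistic (frequency, LD, F_ST) is undefined for the given counts."""


class ConfigError(ParadivergeError):
    """Invalid analysis configuration."""


# ---------------------------------------------------------------------------
# SnpTable


@dataclass
class SnpTable:
    """Per-SNP, per-population allele counts.

    Attributes
    ----------
    ids : (S,) array of SNP identifiers (unique).
    chrom : (S,) array of chromosome labels.
    pos : (S,) int64 array of 1-based positions.
    populations : ordered population labels.
    alt : (S, P) int array of alternate-allele copies.
    nobs : (S, P) int array of allele copies genotyped (2x diploids with calls).
    het : optional (S, P) int array of heterozygous-individual counts.
    dosages : optional mapping population -> (S, n_individuals) int8 dosage
        matrix (0/1/2), kept only for populations needed by LD pruning.
    annotations : optional mapping snp_id -> frozenset of category labels.
    """

    ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    populations: tuple[str, ...]
    alt: np.ndarray
    nobs: np.ndarray
    het: np.ndarray | None = None
    dosages: dict[str, np.ndarray] | None = None
    annotations: Mapping[str, frozenset] | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.populations = tuple(self.populations)
        self.alt = np.asarray(self.alt, dtype=np.int64)
        self.nobs = np.asarray(self.nobs, dtype=np.int64)
        if self.het is not None:
            self.het = np.asarray(self.het, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        s, p = self.alt.shape
        if self.nobs.shape != (s, p) or len(self.populations) != p:
            raise ValueError("inconsistent SnpTable array shapes")
        if len(self.ids) != s or len(self.chrom) != s or len(self.pos) != s:
            raise ValueError("inconsistent SnpTable row metadata")
        if len(set(self.ids)) != s:
            raise ValueError("snp_id values must be unique")
        if np.any(self.alt < 0) or np.any(self.alt > self.nobs):
            raise ValueError("alt counts must satisfy 0 <= alt <= n_obs")
        if self.het is not None:
            if self.het.shape != (s, p):
                raise ValueError("het shape mismatch")
            if np.any(self.het < 0) or np.any(2 * self.het > self.nobs):
                raise ValueError("het counts exceed genotyped individuals")

    @property
    def n_snps(self) -> int:
        return len(self.ids)

    def pop_index(self, pops: Iterable[str]) -> np.ndarray:
        lookup = {p: i for i, p in enumerate(self.populations)}
        try:
            return np.array([lookup[p] for p in pops], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"population {exc} absent from table") from exc

    def pooled_counts(self, pops: Iterable[str]) -> tuple[np.ndarray, np.ndarray]:
        """Pooled (alt, n_obs) allele counts over the given populations."""
        idx = self.pop_index(pops)
        return self.alt[:, idx].sum(axis=1), self.nobs[:, idx].sum(axis=1)

    def pooled_het(self, pops: Iterable[str]) -> np.ndarray | None:
        if self.het is None:
            return None
        idx = self.pop_index(pops)
        return self.het[:, idx].sum(axis=1)

    def subset(self, mask_or_index) -> "SnpTable":
        """Row-subset the table (boolean mask or integer index array)."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        dos = None
        if self.dosages is not None:
            dos = {p: m[idx] for p, m in self.dosages.items()}
        return SnpTable(
            ids=self.ids[idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            populations=self.populations,
            alt=self.alt[idx],
            nobs=self.nobs[idx],
            het=None if self.het is None else self.het[idx],
            dosages=dos,
            annotations=self.annotations,
        )

    def subset_ids(self, snp_ids: Iterable[str]) -> "SnpTable":
        order = {s: i for i, s in enumerate(self.ids)}
        return self.subset(np.array([order[s] for s in snp_ids], dtype=np.intp))

    # -- TSV dialect -------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format counts frame (the package's TSV dialect)."""
        s, p = self.alt.shape
        frame = pd.DataFrame(
            {
                "snp": np.repeat(self.ids, p),
                "chrom": np.repeat(self.chrom, p),
                "pos": np.repeat(self.pos, p),
                "pop": np.tile(np.array(self.populations, dtype=object), s),
                "alt": self.alt.ravel(),
                "n": self.nobs.ravel(),
            }
        )
        if self.het is not None:
            frame["het"] = self.het.ravel()
        return frame

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SnpTable":
        required = {"snp", "chrom", "pos", "pop", "alt", "n"}
        missing = required - set(frame.columns)
        if missing:
            raise ParseError(f"counts table missing columns: {sorted(missing)}")
        pops = tuple(sorted(frame["pop"].unique()))
        has_het = "het" in frame.columns and frame["het"].notna().all()
        wide_alt = frame.pivot_table(index="snp", columns="pop", values="alt", sort=False)
        wide_n = frame.pivot_table(index="snp", columns="pop", values="n", sort=False)
        if wide_alt.isna().any().any() or wide_n.isna().any().any():
            raise ParseError("counts table is not complete over snp x pop")
        meta = frame.drop_duplicates("snp").set_index("snp")
        order = list(wide_alt.index)
        table = cls(
            ids=np.array(order, dtype=object),
            chrom=meta.loc[order, "chrom"].to_numpy(dtype=object),
            pos=meta.loc[order, "pos"].to_numpy(dtype=np.int64),
            populations=pops,
            alt=wide_alt[list(pops)].to_numpy(dtype=np.int64),
            nobs=wide_n[list(pops)].to_numpy(dtype=np.int64),
            het=(
                frame.pivot_table(index="snp", columns="pop", values="het", sort=False)
                .loc[order, list(pops)]
                .to_numpy(dtype=np.int64)
                if has_het
                else None
            ),
        )
        return table

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SnpTable":
        try:
            frame = pd.read_csv(path, sep="\t", dtype={"snp": str, "chrom": str, "pop": str})
        except Exception as exc:
            raise ParseError(f"cannot parse counts TSV {path}: {exc}") from exc
        if frame.empty:
            raise EmptyInputError(f"no SNP records in {path}")
        return cls.from_frame(frame)


# ---------------------------------------------------------------------------
# Group scheme


@dataclass(frozen=True)
class GroupPair:
    """Unordered pair of distinct group labels (stored sorted)."""

    first: str
    second: str

    def __post_init__(self) -> None:
        if self.first == self.second:
            raise ValueError("group pair labels must differ")
        if self.first > self.second:
            object.__setattr__(self, "first", self.second)
            object.__setattr__(self, "second", self.first)

    @classmethod
    def of(cls, a: str, b: str) -> "GroupPair":
        lo, hi = sorted((a, b))
        return cls(lo, hi)

    @property
    def labels(self) -> tuple[str, str]:
        return (self.first, self.second)

    def __str__(self) -> str:
        return f"{self.first}-{self.second}"


@dataclass(frozen=True)
class DivergenceComparison:
    """Two disjoint group pairs whose tree paths share no edge."""

    pair1: GroupPair
    pair2: GroupPair
    edges1: frozenset = frozenset()
    edges2: frozenset = frozenset()

    def __post_init__(self) -> None:
        groups = {*self.pair1.labels, *self.pair2.labels}
        if len(groups) != 4:
            raise ValueError("divergence comparison needs four distinct groups")
        if self.edges1 and self.edges2 and (self.edges1 & self.edges2):
            raise ValueError("group-pair tree paths are not edge-disjoint")

    @property
    def label(self) -> str:
        return f"{self.pair1} vs {self.pair2}"

    def __str__(self) -> str:
        return self.label


@dataclass
class GroupScheme:
    """Population→group assignment plus the unrooted group tree."""

    pop_to_group: dict[str, str]
    pop_sizes: dict[str, int]
    newick: str
    tree: dendropy.Tree = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.tree is None:
            self.tree = dendropy.Tree.get(
                data=self.newick, schema="newick", suppress_internal_node_taxa=True
            )
        tips = {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}
        groups = set(self.pop_to_group.values())
        if len(groups) < 4:
            raise ValueError("a group scheme requires at least four groups")
        if tips != groups:
            raise ValueError(
                "tree tips and group labels disagree: "
                f"tips-only={sorted(tips - groups)} groups-only={sorted(groups - tips)}"
            )
        missing = set(self.pop_sizes) ^ set(self.pop_to_group)
        if missing:
            raise ValueError(f"populations without both group and size: {sorted(missing)}")

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.pop_to_group.values())))

    def populations_of(self, group: str) -> tuple[str, ...]:
        return tuple(sorted(p for p, g in self.pop_to_group.items() if g == group))

    @property
    def representatives(self) -> dict[str, str]:
        """Largest-sample population per group (ties broken by name)."""
        reps: dict[str, str] = {}
        for g in self.groups:
            pops = self.populations_of(g)
            reps[g] = min(pops, key=lambda p: (-self.pop_sizes[p], p))
        return reps

    def group_pairs(self) -> list[GroupPair]:
        return [GroupPair.of(a, b) for a, b in combinations(self.groups, 2)]


# ---------------------------------------------------------------------------
# Analysis configuration


@dataclass
class AnalysisConfig:
    """Thresholds of the filtering and divergence stages.

    threshold : divergence threshold t, the top fraction of F_ST ranks
        called divergent (default 0.05).
    maf_bound : global minor-allele-frequency lower bound for the
        "intermediate frequency" filter (default 0.4, strict).
    ld_bound : upper bound on |mean composite D| between retained SNPs
        (default 0.1, strict).
    ld_window : LD window in bp; pairs with |pos_i - pos_j| <= window on the
        same chromosome are checked (default 10 Mb).
    sfs_bins/sfs_bin_width : the minor-allele-frequency spectrum binning
        (default 10 bins of width 0.05 covering [0, 0.5]).
    sfs_rel_tol/sfs_abs_floor : spectrum-matching rule: a bin may differ
        between groups by < abs_floor counts, or by at most rel_tol of the
        larger bin (defaults 100 and 0.05).
    """

    threshold: float = 0.05
    maf_bound: float = 0.4
    ld_bound: float = 0.1
    ld_window: int = 10_000_000
    sfs_bins: int = 10
    sfs_bin_width: float = 0.05
    sfs_rel_tol: float = 0.05
    sfs_abs_floor: int = 100
    seed: int | None = None
    n_replicates: int = 1
    target_size: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ConfigError("threshold must lie in (0, 1)")
        if not 0 < self.maf_bound <= 0.5:
            raise ConfigError("maf_bound must lie in (0, 0.5]")
        if abs(self.sfs_bins * self.sfs_bin_width - 0.5) > 1e-9:
            raise ConfigError("sfs_bins * sfs_bin_width must equal 0.5")


# ---------------------------------------------------------------------------
# Readers


def read_popmap(source: str | Path | pd.DataFrame) -> pd.DataFrame:
    """Read the sample→population→group map (TSV with header)."""
    if isinstance(source, pd.DataFrame):
        frame = source.copy()
    else:
        try:
            frame = pd.read_csv(source, sep="\t", dtype=str)
        except Exception as exc:
            raise ParseError(f"cannot parse population map {source}: {exc}") from exc
    required = {"sample", "population", "group"}
    missing = required - set(frame.columns)
    if missing:
        raise ParseError(f"population map missing columns: {sorted(missing)}")
    return frame


def read_group_scheme(
    popmap: str | Path | pd.DataFrame, newick: str | Path
) -> GroupScheme:
    """Build a GroupScheme from a population map and a Newick group tree."""
    frame = read_popmap(popmap)
    newick_str = str(newick)
    path = Path(newick_str)
    if not newick_str.lstrip().startswith("(") and path.exists():
        newick_str = path.read_text()
    pop_to_group = dict(
        frame.drop_duplicates("population")[["population", "group"]].itertuples(
            index=False, name=None
        )
    )
    conflicting = frame.groupby("population")["group"].nunique()
    if (conflicting > 1).any():
        bad = sorted(conflicting[conflicting > 1].index)
        raise ParseError(f"populations mapped to multiple groups: {bad}")
    pop_sizes = frame.groupby("population")["sample"].nunique().to_dict()
    return GroupScheme(pop_to_group=pop_to_group, pop_sizes=pop_sizes, newick=newick_str)


def _is_autosomal(chrom: str) -> bool:
    return str(chrom).upper() not in _AUTOSOME_EXCLUDE


def read_genotypes(
    path: str | Path,
    popmap: str | Path | pd.DataFrame,
    *,
    keep_dosages: Iterable[str] | None = None,
) -> SnpTable:
    """Read genotypes (VCF or counts TSV) into a SnpTable.

    VCF input is aggregated to per-population counts using the sample→
    population map; samples absent from the map are ignored with a logged
    warning.  Multi-allelic sites, non-SNPs, non-autosomes, and sites
    monomorphic across all populations are dropped (counts logged).
    ``keep_dosages`` lists populations whose per-individual dosage vectors
    are retained for LD pruning (VCF input only).
    """
    path = Path(path)
    if path.suffix in {".tsv", ".txt", ".counts"}:
        return SnpTable.read_tsv(path)
    return _read_vcf(path, popmap, keep_dosages=keep_dosages)


def _read_vcf(
    path: Path,
    popmap: str | Path | pd.DataFrame,
    *,
    keep_dosages: Iterable[str] | None = None,
) -> SnpTable:
    from cyvcf2 import VCF

    frame = read_popmap(popmap)
    sample_to_pop = dict(frame[["sample", "population"]].itertuples(index=False, name=None))
    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise ParseError(f"cannot open VCF {path}: {exc}") from exc

    samples = vcf.samples
    unknown = [s for s in samples if s not in sample_to_pop]
    if unknown:
        logger.warning("ignoring %d VCF samples absent from population map", len(unknown))
    pops = tuple(sorted({sample_to_pop[s] for s in samples if s in sample_to_pop}))
    if not pops:
        raise EmptyInputError("no VCF samples matched the population map")
    pop_cols: dict[str, np.ndarray] = {
        p: np.array([i for i, s in enumerate(samples) if sample_to_pop.get(s) == p])
        for p in pops
    }
    keep_dosages = set(keep_dosages or ())

    ids, chroms, poss = [], [], []
    alt_rows, n_rows, het_rows = [], [], []
    dos_rows: dict[str, list[np.ndarray]] = {p: [] for p in keep_dosages}
    n_multi = n_nonsnp = n_nonauto = n_mono = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        if len(var.REF) != 1 or len(var.ALT[0]) != 1 or var.ALT[0] not in "ACGT":
            n_nonsnp += 1
            continue
        if not _is_autosomal(var.CHROM):
            n_nonauto += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gts = var.gt_types
        alt_row, n_row, het_row = [], [], []
        for p in pops:
            g = gts[pop_cols[p]]
            called = g != 2
            het = int((g == 1).sum())
            alt_row.append(het + 2 * int((g == 3).sum()))
            n_row.append(2 * int(called.sum()))
            het_row.append(het)
        alt_arr = np.array(alt_row)
        n_arr = np.array(n_row)
        if alt_arr.sum() == 0 or alt_arr.sum() == n_arr.sum():
            n_mono += 1
            continue
        snp_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        ids.append(snp_id)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        alt_rows.append(alt_arr)
        n_rows.append(n_arr)
        het_rows.append(np.array(het_row))
        for p in keep_dosages:
            g = gts[pop_cols[p]]
            dose = np.where(g == 1, 1, np.where(g == 3, 2, np.where(g == 0, 0, -1)))
            dos_rows[p].append(dose.astype(np.int8))
    if n_multi or n_nonsnp or n_nonauto or n_mono:
        logger.info(
            "VCF filter: dropped %d multi-allelic, %d non-SNP, %d non-autosomal, "
            "%d monomorphic sites",
            n_multi,
            n_nonsnp,
            n_nonauto,
            n_mono,
        )
    if not ids:
        raise EmptyInputError(f"no usable biallelic autosomal SNPs in {path}")
    return SnpTable(
        ids=np.array(ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        populations=pops,
        alt=np.vstack(alt_rows),
        nobs=np.vstack(n_rows),
        het=np.vstack(het_rows),
        dosages={p: np.vstack(v) for p, v in dos_rows.items()} if keep_dosages else None,
    )


def read_annotations(path: str | Path) -> dict[str, frozenset]:
    """Read a SNP annotation TSV (columns ``snp``, ``category``)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if not {"snp", "category"} <= set(frame.columns):
        raise ParseError("annotation table needs columns 'snp' and 'category'")
    grouped = frame.groupby("snp")["category"].agg(lambda s: frozenset(s))
    return grouped.to_dict()
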