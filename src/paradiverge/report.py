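"""Rank-sector grids and per-SNP replicate summaries.

The sector grid is the heat-map analogue for one divergence comparison:
both pairs' F_ST ranks are cut into ``b`` quantile bins (ascending) and
SNPs are counted per cell.  Because ranks are a (seeded) permutation,
every row and column sums to N/b up to remainder spreading, and the
top-right cell at b = 20 is exactly the parallel divergent count at
t = 0.05.  The bottom-left cell counts "parallel conserved" SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .divergence import FstPanel, ParallelResult
from .io_model import ConfigError, DivergenceComparison

__all__ = ["SectorGrid", "rank_sector_counts", "replicate_hit_summary", "render_grid"]


@dataclass
class SectorGrid:
    """b x b matrix of SNP counts over rank-quantile bins (ascending)."""

    comparison: DivergenceComparison
    n_bins: int
    counts: np.ndarray  # (b, b); rows = pair1 bins, cols = pair2 bins

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = int(self.counts.sum())
        row_sums = self.counts.sum(axis=1)
        col_sums = self.counts.sum(axis=0)
        lo, hi = n // self.n_bins, -(-n // self.n_bins)
        if not (np.all(row_sums >= lo) and np.all(row_sums <= hi)):
            raise ValueError("sector grid row margins are not rank-fixed")
        if not (np.all(col_sums >= lo) and np.all(col_sums <= hi)):
            raise ValueError("sector grid column margins are not rank-fixed")

    @property
    def n_snps(self) -> int:
        return int(self.counts.sum())

    @property
    def parallel_divergent_count(self) -> int:
        """Top-right cell: SNPs in the highest rank bin of both pairs."""
        return int(self.counts[-1, -1])

    @property
    def parallel_conserved_count(self) -> int:
        """Bottom-left cell: SNPs in the lowest rank bin of both pairs."""
        return int(self.counts[0, 0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[f"p1_bin{i}" for i in range(self.n_bins)],
            columns=[f"p2_bin{i}" for i in range(self.n_bins)],
        )


def _rank_bins(strict_rank: np.ndarray, n: int, b: int) -> np.ndarray:
    """Quantile-bin ascending strict ranks so the TOP bin holds exactly
    floor(N/b) SNPs (cut points counted from the top; remainders spread
    deterministically over the lower bins)."""
    cuts = n - np.floor(np.arange(b, -1, -1) * n / b).astype(np.int64)
    # cuts[0] = 0 (all ranks above it), cuts[b] = n; bin j = (cuts[j], cuts[j+1]]
    return np.searchsorted(cuts[1:-1], strict_rank, side="left")


def rank_sector_counts(
    panel: FstPanel, comparison: DivergenceComparison, b: int = 20
) -> SectorGrid:
    """Count SNPs per (pair1 rank bin, pair2 rank bin) cell."""
    if b < 2:
        raise ConfigError("sector grid needs at least 2 bins")
    n = panel.n_snps
    r1 = panel.strict_rank[:, panel.column(comparison.pair1)]
    r2 = panel.strict_rank[:, panel.column(comparison.pair2)]
    b1 = _rank_bins(r1, n, b)
    b2 = _rank_bins(r2, n, b)
    counts = np.zeros((b, b), dtype=np.int64)
    np.add.at(counts, (b1, b2), 1)
    return SectorGrid(comparison=comparison, n_bins=b, counts=counts)


def replicate_hit_summary(
    replicate_subsets: list[list[str]],
    replicate_results: list[list[ParallelResult]],
) -> pd.DataFrame:
    """Per-SNP tallies across subset replicates.

    ``replicate_subsets[r]`` lists the SNP ids included in replicate r;
    ``replicate_results[r]`` the per-comparison results for that
    replicate.  Returns a long table (snp, comparison, n_included,
    n_parallel, n_same, n_opposite, consensus_orientation) covering every
    SNP that was parallel divergent at least once, for every comparison
    in which it was; SNPs absent from all subsets are omitted.
    """
    if not replicate_subsets:
        raise ValueError("need at least one replicate")
    included: dict[str, int] = {}
    for ids in replicate_subsets:
        for s in ids:
            included[s] = included.get(s, 0) + 1

    tallies: dict[tuple[str, str], dict[str, int]] = {}
    for results in replicate_results:
        for res in results:
            for snp in res.parallel_ids:
                key = (snp, res.comparison.label)
                t = tallies.setdefault(key, {"n_parallel": 0, "same": 0, "opposite": 0})
                t["n_parallel"] += 1
                orient = (res.per_snp_orientation or {}).get(snp)
                if orient is not None:
                    t[orient] += 1
    rows = []
    for (snp, comp), t in sorted(tallies.items()):
        same, opp = t["same"], t["opposite"]
        if same > opp:
            consensus = "same"
        elif opp > same:
            consensus = "opposite"
        else:
            consensus = "tied" if same else "untallied"
        rows.append(
            {
                "snp": snp,
                "comparison": comp,
                "n_included": included.get(snp, 0),
                "n_parallel": t["n_parallel"],
                "n_same": same,
                "n_opposite": opp,
                "consensus_orientation": consensus,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "snp", "comparison", "n_included", "n_parallel",
            "n_same", "n_opposite", "consensus_orientation",
        ],
    )


def render_grid(grid: SectorGrid, path) -> None:
    """Optional heat-map rendering of a sector grid (PNG/SVG by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(grid.counts, origin="lower", cmap="Greys")
    ax.set_xlabel(f"{grid.comparison.pair2} rank bin (ascending F_ST)")
    ax.set_ylabel(f"{grid.comparison.pair1} rank bin (ascending F_ST)")
    ax.set_title(grid.comparison.label)
    fig.colorbar(im, ax=ax, label="SNPs")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
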