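"""ChIP enrichment-region calling, tiling and differential testing.

Narrow marks (H3K4me3-like) are called as punctate peaks with the same
greedy threshold/min-distance machinery used for the capture mask; broad
marks (H3K27me3, H3K36me3, H3K27ac domains) are called as contiguous runs
of enriched windows.  Large regions are broken into non-overlapping 1 kb
tiles, each tile is tested for a read-density change between conditions,
and adjacent significant tiles are re-merged into differential blocks whose
aggregate p-value comes from Fisher's combined probability method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet, merge_intervals, overlap_pairs
from .io import GeneModel, SampleSheet
from .methylome import call_assayable_loci
from .stats import (
    TestResult,
    bh_adjust,
    estimate_dispersion,
    fisher_combine,
    nb_exact_test,
    two_sample_t,
)

# the settings the narrow/broad callers were run with in the source study
NARROW_PARAMS = {"size": 600, "min_dist": 600, "tag_threshold": 10}
BROAD_PARAMS = {"size": 2000, "min_dist": 4000, "tag_threshold": 40,
                "fdr": 1e-4}


@dataclass
class EnrichedRegion:
    interval: GenomicInterval
    mark: str
    mode: str                      # narrow | broad
    params: dict = field(default_factory=dict)


@dataclass
class TileStat:
    interval: GenomicInterval
    region_index: int
    test: TestResult | None = None
    padj: float = float("nan")
    significant: bool = False


@dataclass
class DifferentialBlock:
    interval: GenomicInterval
    tiles: list[TileStat]
    combined_p: float
    direction: str                 # gain | loss
    mark: str


@dataclass
class GeneEpiProfile:
    """Per-gene t-statistics for expression, H3K9ac and H3K27me3."""

    gene_id: str
    tss: int
    chrom: str
    t_expression: float = float("nan")
    t_h3k9ac: float = float("nan")
    t_h3k27me3: float = float("nan")


def call_enriched_regions(
    windows: IntervalSet,
    pooled_counts: np.ndarray,
    mark: str,
    mode: str,
    size: int,
    min_dist: int,
    tag_threshold: float,
    fdr: float | None = None,
) -> list[EnrichedRegion]:
    """Call enrichment regions on pooled per-window counts for one mark.

    Narrow mode selects peak windows greedily (threshold + min-distance
    suppression) and reports a region of ``size`` bp from each peak window
    start.  Broad mode takes maximal runs of windows with count >=
    tag_threshold, merges runs separated by < min_dist, and discards merged
    runs shorter than ``size`` bp.
    """
    if size <= 0 or min_dist <= 0 or tag_threshold <= 0:
        raise ValueError("params must be positive")
    counts = np.asarray(pooled_counts, dtype=float)
    params = {"size": size, "min_dist": min_dist,
              "tag_threshold": tag_threshold, "fdr": fdr}
    if mode == "narrow":
        mask = call_assayable_loci(
            windows, counts, window=size, min_dist=min_dist,
            tag_threshold=tag_threshold,
        )
        return [
            EnrichedRegion(
                GenomicInterval(iv.chrom, iv.start, iv.start + size),
                mark, "narrow", params,
            )
            for iv in mask.loci
        ]
    if mode != "broad":
        raise ValueError(f"unknown mode {mode!r}")
    hot = [windows[i] for i in np.flatnonzero(counts >= tag_threshold)]
    runs = merge_intervals(IntervalSet(hot), 0)
    merged = merge_intervals(runs, min_dist - 1)
    return [
        EnrichedRegion(iv, mark, "broad", params)
        for iv in merged
        if len(iv) >= size
    ]


def tile_regions(regions: list[EnrichedRegion],
                 tile: int = 1000) -> list[TileStat]:
    """Partition each region into non-overlapping tiles of at most tile bp.

    Regions no longer than one tile pass through whole; the last tile of a
    longer region may be shorter.  Tiles exactly conserve covered bases.
    """
    tiles: list[TileStat] = []
    for ri, region in enumerate(regions):
        iv = region.interval
        if len(iv) <= tile:
            tiles.append(TileStat(iv, ri))
            continue
        for s in range(iv.start, iv.end, tile):
            tiles.append(
                TileStat(GenomicInterval(iv.chrom, s, min(s + tile, iv.end)), ri)
            )
    return tiles


def differential_tiles(
    tiles: list[TileStat],
    windows: IntervalSet,
    counts: pd.DataFrame,
    samples: SampleSheet,
    alpha: float = 0.05,
) -> list[TileStat]:
    """NB exact test per tile, vHMEC vs HMEC, BH-corrected across tiles."""
    vh = samples.ids(condition="vHMEC")
    hm = samples.ids(condition="HMEC")
    if len(vh) < 2 or len(hm) < 2:
        raise ValueError("need >= 2 samples per condition")
    cols = vh + hm
    libs = counts[cols].sum(axis=0).to_numpy()
    phi = estimate_dispersion(
        counts[cols].to_numpy(), libs,
        ["vHMEC"] * len(vh) + ["HMEC"] * len(hm),
    )
    tile_set = IntervalSet([t.interval for t in tiles])
    order = sorted(range(len(tiles)), key=lambda i: tiles[i].interval)
    sums = np.zeros((len(tiles), len(cols)))
    vals = counts[cols].to_numpy()
    for wi, ti in overlap_pairs(windows, tile_set):
        sums[order[ti]] += vals[wi]
    for i, t in enumerate(tiles):
        res = nb_exact_test(sums[i, : len(vh)], sums[i, len(vh):], libs, phi)
        t.test = res
    padj = bh_adjust([t.test.p for t in tiles])
    for t, q in zip(tiles, padj):
        t.padj = float(q)
        t.significant = bool(q < alpha)
    return tiles


def merge_significant_tiles(tiles: list[TileStat],
                            mark: str = "") -> list[DifferentialBlock]:
    """Merge maximal runs of adjacent, same-signed significant tiles.

    Adjacent means abutting coordinates on the same chromosome; the merged
    block's p-value combines member tile p-values by Fisher's method.
    Singleton significant tiles pass through with their own p.
    """
    ordered = sorted((t for t in tiles if t.significant),
                     key=lambda t: t.interval)
    blocks: list[DifferentialBlock] = []
    run: list[TileStat] = []

    def flush():
        if not run:
            return
        iv = GenomicInterval(run[0].interval.chrom, run[0].interval.start,
                             run[-1].interval.end)
        combined = fisher_combine([t.test.p for t in run])
        direction = "gain" if run[0].test.effect > 0 else "loss"
        blocks.append(DifferentialBlock(iv, list(run), combined.p,
                                        direction, mark))

    for t in ordered:
        if run and (
            t.interval.chrom == run[-1].interval.chrom
            and t.interval.start == run[-1].interval.end
            and t.test.effect * run[-1].test.effect > 0
        ):
            run.append(t)
        else:
            flush()
            run = [t]
    flush()
    return blocks


def tss_block_stats(
    gene_models: list[GeneModel],
    windows: IntervalSet,
    signal: pd.DataFrame,
    samples: SampleSheet,
    flank: int = 2000,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Two-sample t per gene on signal summed over TSS +/- flank.

    Returns a DataFrame indexed by gene_id with columns statistic, p,
    effect, clipped (True when the window ran off a chromosome edge).
    """
    vh = samples.ids(condition="vHMEC")
    hm = samples.ids(condition="HMEC")
    if len(vh) < 2 or len(hm) < 2:
        raise ValueError("need >= 2 samples per condition")
    blocks = []
    clipped = []
    for g in gene_models:
        lo = g.tss - flank
        hi = g.tss + flank
        clip = lo < 0
        lo = max(0, lo)
        if chrom_sizes and g.interval.chrom in chrom_sizes:
            size = chrom_sizes[g.interval.chrom]
            clip = clip or hi > size
            hi = min(hi, size)
        blocks.append(GenomicInterval(g.interval.chrom, lo, hi))
        clipped.append(clip)
    block_set = IntervalSet(blocks)
    order = sorted(range(len(blocks)), key=lambda i: blocks[i])
    sums = np.zeros((len(blocks), signal.shape[1]))
    vals = signal.to_numpy()
    for wi, bi in overlap_pairs(windows, block_set):
        sums[order[bi]] += vals[wi]
    sdf = pd.DataFrame(sums, index=[g.gene_id for g in gene_models],
                       columns=signal.columns)
    rows = []
    for gi, g in enumerate(gene_models):
        res = two_sample_t(sdf.loc[g.gene_id, vh].to_numpy(),
                           sdf.loc[g.gene_id, hm].to_numpy())
        rows.append((g.gene_id, res.statistic, res.p, res.effect, clipped[gi]))
    return pd.DataFrame(
        rows, columns=["gene_id", "statistic", "p", "effect", "clipped"]
    ).set_index("gene_id")
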