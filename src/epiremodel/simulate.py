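"""Synthetic data generation for every pipeline stage.

Emulates the statistical structure of the study inputs — CpG-density-driven
MBD-capture counts with a fully methylated (SssI) control, peak/domain
ChIP counts for five histone marks in paired conditions, donor-structured
expression, tumour/normal beta matrices with implanted hypermethylated
marker regions, and qPCR Ct tables — together with a ground-truth manifest
so downstream sensitivity and specificity are scoreable.

Every generator is deterministic given its integer seed.  The default
design mirrors the study: four donors, each with a finite-lifespan HMEC
culture and variant (vHMEC) cultures at an early and a late passage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet
from .io import GeneModel, SampleSheet

MARKS = ("H3K4me3", "H3K27ac", "H3K36me3", "H3K27me3", "H3K9ac")
DONORS = ("D1", "D2", "D3", "D4")


@dataclass
class GenomeConfig:
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 6_000_000, "chr2": 4_000_000}
    )
    window: int = 300
    n_genes: int = 400
    island_fraction: float = 0.04      # fraction of genome inside CpG islands
    island_len_range: tuple[int, int] = (600, 2100)
    background_weight: tuple[float, float] = (0.02, 0.15)
    island_weight: tuple[float, float] = (0.6, 1.0)
    tfbs_factors: dict[str, int] = field(
        default_factory=lambda: {"MYC": 250, "E2F1": 250}
    )


@dataclass
class SyntheticGenome:
    """A small genome with CpG-density structure, genes and TFBS tracks."""

    chrom_sizes: dict[str, int]
    window: int
    windows: IntervalSet
    cpg_weight: np.ndarray          # per window, in [0, 1]
    baseline_meth: np.ndarray       # per window, in [0, 1]
    islands: IntervalSet
    genes: list[GeneModel]
    tfbs: dict[str, IntervalSet]

    def window_ids(self) -> list[str]:
        return [str(iv) for iv in self.windows]

    def n_windows(self) -> int:
        return len(self.windows)


@dataclass
class SimulationTruth:
    """Ground truth implanted by the generators, for recovery scoring."""

    dmrs: list[tuple[GenomicInterval, str, float]] = field(default_factory=list)
    chip_domains: dict[str, dict[str, IntervalSet]] = field(default_factory=dict)
    lrea_blocks: list[dict] = field(default_factory=list)
    lres_blocks: list[dict] = field(default_factory=list)
    de_genes: dict[str, float] = field(default_factory=dict)
    tumour_markers: list[GenomicInterval] = field(default_factory=list)
    basal_markers: list[GenomicInterval] = field(default_factory=list)
    spread_probes: list[str] = field(default_factory=list)
    mirna_folds: dict[str, float] = field(default_factory=dict)

    def dmr_intervals(self, direction: str | None = None) -> IntervalSet:
        ivs = [iv for iv, d, _ in self.dmrs if direction in (None, d)]
        return IntervalSet(ivs)


def default_sample_sheet() -> SampleSheet:
    """Four donors, each with HMEC and early/late-passage vHMEC cultures."""
    rows = []
    for donor in DONORS:
        rows.append((f"{donor}_HMEC", donor, "HMEC", "NA"))
        rows.append((f"{donor}_vHMEC_early", donor, "vHMEC", "early"))
        rows.append((f"{donor}_vHMEC_late", donor, "vHMEC", "late"))
    return SampleSheet(
        pd.DataFrame(rows, columns=["sample_id", "donor", "condition", "timepoint"])
    )


def chip_sample_sheet(n_per_condition: int = 3) -> SampleSheet:
    rows = [
        (f"chip_{cond}_{i + 1}", f"D{i + 1}", cond, "NA")
        for cond in ("HMEC", "vHMEC")
        for i in range(n_per_condition)
    ]
    return SampleSheet(
        pd.DataFrame(rows, columns=["sample_id", "donor", "condition", "timepoint"])
    )


# ---------------------------------------------------------------------------
# genome


def make_genome(config: GenomeConfig | None = None, seed: int = 0) -> SyntheticGenome:
    """Build a synthetic genome: windows, CpG weights, islands, genes, TFBS.

    CpG weight per window is a two-component mixture (low background, high
    inside islands); baseline methylation is low at most island windows and
    intermediate-to-high elsewhere, matching the usual somatic landscape.
    """
    cfg = config or GenomeConfig()
    rng = np.random.default_rng(seed)
    w = cfg.window

    windows: list[GenomicInterval] = []
    for chrom in sorted(cfg.chrom_sizes):
        size = cfg.chrom_sizes[chrom]
        for start in range(0, size - w + 1, w):
            windows.append(GenomicInterval(chrom, start, start + w))
    window_set = IntervalSet(windows)
    n_win = len(window_set)

    # islands: non-overlapping spans aligned to nothing in particular
    islands: list[GenomicInterval] = []
    genome_size = sum(cfg.chrom_sizes.values())
    mean_len = sum(cfg.island_len_range) / 2.0
    n_islands = int(cfg.island_fraction * genome_size / mean_len)
    for chrom in sorted(cfg.chrom_sizes):
        size = cfg.chrom_sizes[chrom]
        share = int(round(n_islands * size / genome_size))
        starts = np.sort(
            rng.choice(size // (4 * w), size=min(share, size // (8 * w)),
                       replace=False)
        ) * (4 * w)
        for s in starts:
            length = int(rng.integers(*cfg.island_len_range))
            end = min(int(s) + length, size)
            if end - s >= cfg.island_len_range[0]:
                islands.append(GenomicInterval(chrom, int(s), end))
    island_set = IntervalSet(islands)

    lo, hi = cfg.background_weight
    cpg = rng.uniform(lo, hi, size=n_win)
    in_island = np.zeros(n_win, dtype=bool)
    from .intervals import overlap_pairs

    for i, _ in overlap_pairs(window_set, island_set):
        in_island[i] = True
    ilo, ihi = cfg.island_weight
    cpg[in_island] = rng.uniform(ilo, ihi, size=int(in_island.sum()))

    baseline = rng.uniform(0.35, 0.85, size=n_win)
    n_isl = int(in_island.sum())
    if n_isl:
        shore_like = rng.random(n_isl) < 0.3
        low = rng.uniform(0.05, 0.25, size=n_isl)
        mid = rng.uniform(0.5, 0.85, size=n_isl)
        baseline[in_island] = np.where(shore_like, mid, low)

    genes = _place_genes(cfg, island_set, rng)

    tfbs: dict[str, IntervalSet] = {}
    for factor, count in cfg.tfbs_factors.items():
        sites = []
        for _ in range(count):
            chrom = rng.choice(sorted(cfg.chrom_sizes))
            size = cfg.chrom_sizes[chrom]
            s = int(rng.integers(0, size - 20))
            sites.append(GenomicInterval(chrom, s, s + 12))
        tfbs[factor] = IntervalSet(sites)

    return SyntheticGenome(
        dict(cfg.chrom_sizes), w, window_set, cpg, baseline, island_set,
        genes, tfbs
    )


def _place_genes(cfg: GenomeConfig, islands: IntervalSet,
                 rng: np.random.Generator) -> list[GeneModel]:
    genome_size = sum(cfg.chrom_sizes.values())
    if cfg.n_genes * 25_000 > genome_size:
        raise ValueError("config asks for more genes than fit the genome")
    genes: list[GeneModel] = []
    per_chrom = {
        chrom: int(round(cfg.n_genes * size / genome_size))
        for chrom, size in cfg.chrom_sizes.items()
    }
    gid = 0
    for chrom in sorted(cfg.chrom_sizes):
        size = cfg.chrom_sizes[chrom]
        n = per_chrom[chrom]
        # regular TSS grid with jitter keeps genes non-overlapping per strand
        pitch = size // (n + 1)
        for i in range(n):
            tss = (i + 1) * pitch + int(rng.integers(-pitch // 8, pitch // 8))
            length = int(rng.integers(2_000, min(20_000, pitch)))
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                iv = GenomicInterval(chrom, tss, min(tss + length, size), "+")
            else:
                iv = GenomicInterval(chrom, max(tss - length, 0), tss + 1, "-")
            genes.append(GeneModel(f"gene{gid:04d}", iv, strand))
            gid += 1
    return genes


# ---------------------------------------------------------------------------
# truth


@dataclass
class TruthConfig:
    n_hyper_dmrs: int = 60
    n_hypo_dmrs: int = 20
    dmr_effect: float = 0.4            # shift in methylation level in vHMEC
    dmr_windows: tuple[int, int] = (2, 3)
    n_broad_domains: int = 12          # per broad mark, per shared truth set
    domain_len_range: tuple[int, int] = (3_000, 8_000)
    n_lrea: int = 3
    n_lres: int = 3
    block_genes: tuple[int, int] = (5, 10)
    n_de_genes: int = 60
    expression_effect: float = 2.0     # log2 shift in vHMEC
    n_tumour_markers: int = 8
    n_basal_markers: int = 4
    marker_delta_beta: float = 0.4
    spread_delta_beta: float = 0.25
    n_mirna_silenced: int = 4
    mirna_fold: float = 0.25


def make_truth(genome: SyntheticGenome, config: TruthConfig | None = None,
               seed: int = 0) -> SimulationTruth:
    """Implant DMRs, chromatin domains, LRER gene blocks, tumour markers
    and silenced miRNAs into the genome, returning the manifest."""
    cfg = config or TruthConfig()
    rng = np.random.default_rng(seed)
    truth = SimulationTruth()

    # DMRs sit on CpG-dense (solidly assayable) windows — capture-based
    # calling can only see methylation change where reads are attracted at
    # all; hyper DMRs need a low baseline with headroom, hypo DMRs high
    weight_ok = genome.cpg_weight >= 0.8
    base = genome.baseline_meth
    hyper_pool = np.flatnonzero(weight_ok & (base + cfg.dmr_effect <= 0.95))
    hypo_pool = np.flatnonzero(weight_ok & (base - cfg.dmr_effect >= 0.05))
    used: set[int] = set()

    def carve(pool: np.ndarray, n: int, direction: str):
        ok = set(int(i) for i in pool)
        pool = rng.permutation(pool)
        made = 0
        for start_idx in pool:
            if made >= n:
                break
            span = int(rng.integers(*cfg.dmr_windows, endpoint=True))
            idxs = list(range(start_idx, min(start_idx + span, genome.n_windows())))
            ivs = [genome.windows[i] for i in idxs]
            if any(i in used or i not in ok for i in idxs):
                continue
            if len({iv.chrom for iv in ivs}) != 1:
                continue
            used.update(idxs)
            region = GenomicInterval(ivs[0].chrom, ivs[0].start, ivs[-1].end)
            effect = cfg.dmr_effect if direction == "hyper" else -cfg.dmr_effect
            truth.dmrs.append((region, direction, effect))
            made += 1

    carve(hyper_pool, cfg.n_hyper_dmrs, "hyper")
    carve(hypo_pool, cfg.n_hypo_dmrs, "hypo")

    lrer_genes = _select_lrer_blocks(genome, cfg, truth, rng)
    _implant_chromatin(genome, cfg, truth, rng, skip_genes=lrer_genes)
    _apply_lrer_effects(genome, cfg, truth)

    # remaining differentially expressed genes outside LRER blocks
    in_blocks = {
        g for blk in truth.lrea_blocks + truth.lres_blocks for g in blk["genes"]
    }
    free = [g.gene_id for g in genome.genes if g.gene_id not in in_blocks]
    picked = rng.choice(free, size=min(cfg.n_de_genes, len(free)), replace=False)
    for i, g in enumerate(picked):
        sign = 1.0 if i % 2 == 0 else -1.0
        truth.de_genes[str(g)] = sign * cfg.expression_effect

    _implant_markers(genome, cfg, truth, rng)

    for i in range(cfg.n_mirna_silenced):
        truth.mirna_folds[f"mir-{i + 1:03d}"] = cfg.mirna_fold
    return truth


def _implant_chromatin(genome, cfg, truth, rng,
                       skip_genes: set[str] | None = None) -> None:
    """Shared broad domains plus promoter/enhancer peaks per condition."""
    domains = {m: {"HMEC": [], "vHMEC": []} for m in MARKS}
    chroms = sorted(genome.chrom_sizes)
    for _ in range(cfg.n_broad_domains):
        chrom = str(rng.choice(chroms))
        size = genome.chrom_sizes[chrom]
        length = int(rng.integers(*cfg.domain_len_range))
        s = int(rng.integers(0, size - length))
        iv = GenomicInterval(chrom, s, s + length)
        mark = str(rng.choice(["H3K27me3", "H3K36me3"]))
        for cond in ("HMEC", "vHMEC"):
            domains[mark][cond].append(iv)

    # promoters: active (K4me3+K27ac+K9ac), bivalent (K4me3+K27me3),
    # transcribed gene bodies (K36me3); enhancers intergenic (K27ac);
    # genes inside LRER blocks keep their chromatin for the block effects
    genes = [g for g in genome.genes
             if not skip_genes or g.gene_id not in skip_genes]
    rng.shuffle(genes)
    n = len(genes)
    for g in genes[: n // 3]:
        peak = _tss_peak(genome, g, 800)
        for mark in ("H3K4me3", "H3K27ac", "H3K9ac"):
            for cond in ("HMEC", "vHMEC"):
                domains[mark][cond].append(peak)
        body = g.interval
        if len(body) >= 3000:
            for cond in ("HMEC", "vHMEC"):
                domains["H3K36me3"][cond].append(
                    GenomicInterval(body.chrom, body.start, body.end)
                )
    for g in genes[n // 3 : n // 3 + n // 10]:
        peak = _tss_peak(genome, g, 800)
        for mark in ("H3K4me3", "H3K27me3"):
            for cond in ("HMEC", "vHMEC"):
                domains[mark][cond].append(peak)
    for _ in range(40):
        chrom = str(rng.choice(chroms))
        s = int(rng.integers(0, genome.chrom_sizes[chrom] - 1200))
        iv = GenomicInterval(chrom, s, s + 1000)
        for cond in ("HMEC", "vHMEC"):
            domains["H3K27ac"][cond].append(iv)

    truth.chip_domains = {
        m: {c: IntervalSet(v) for c, v in bycond.items()}
        for m, bycond in domains.items()
    }


def _tss_peak(genome, gene: GeneModel, half: int) -> GenomicInterval:
    size = genome.chrom_sizes[gene.interval.chrom]
    s = max(0, gene.tss - half)
    e = min(size, gene.tss + half)
    return GenomicInterval(gene.interval.chrom, s, e)


def _select_lrer_blocks(genome, cfg, truth, rng) -> set[str]:
    """Pick disjoint runs of consecutive genes for LREA/LRES blocks."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genome.genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    for genes in by_chrom.values():
        genes.sort(key=lambda g: g.tss)

    taken: set[str] = set()
    jobs = ["LREA"] * cfg.n_lrea + ["LRES"] * cfg.n_lres
    for kind in jobs:
        for _ in range(200):  # rejection sample a free run of genes
            chrom = str(rng.choice(sorted(by_chrom)))
            genes = by_chrom[chrom]
            nblk = int(rng.integers(*cfg.block_genes, endpoint=True))
            if len(genes) < nblk:
                continue
            i0 = int(rng.integers(0, len(genes) - nblk + 1))
            block = genes[i0 : i0 + nblk]
            if any(g.gene_id in taken for g in block):
                continue
            taken.update(g.gene_id for g in block)
            span = GenomicInterval(
                chrom,
                min(g.interval.start for g in block),
                max(g.interval.end for g in block),
            )
            rec = {
                "type": kind,
                "interval": span,
                "genes": [g.gene_id for g in block],
            }
            (truth.lrea_blocks if kind == "LREA" else truth.lres_blocks).append(rec)
            break
    return taken


def _apply_lrer_effects(genome, cfg, truth) -> None:
    """Concordant chromatin + expression shifts for the selected blocks.

    LRES blocks gain H3K27me3 and lose H3K9ac in vHMEC with expression down;
    LREA blocks the reverse.
    """
    by_id = {g.gene_id: g for g in genome.genes}
    for rec in truth.lrea_blocks + truth.lres_blocks:
        kind = rec["type"]
        sign = 1.0 if kind == "LREA" else -1.0
        for gid in rec["genes"]:
            g = by_id[gid]
            truth.de_genes[gid] = sign * cfg.expression_effect
            peak = _tss_peak(genome, g, 800)
            if kind == "LRES":
                truth.chip_domains["H3K27me3"]["vHMEC"].intervals.append(peak)
                truth.chip_domains["H3K9ac"]["HMEC"].intervals.append(peak)
            else:
                truth.chip_domains["H3K9ac"]["vHMEC"].intervals.append(peak)
                truth.chip_domains["H3K27me3"]["HMEC"].intervals.append(peak)
    # re-sort mutated interval sets
    for m in truth.chip_domains:
        for c in truth.chip_domains[m]:
            truth.chip_domains[m][c] = IntervalSet(
                truth.chip_domains[m][c].intervals
            )


def _implant_markers(genome, cfg, truth, rng) -> None:
    islands = list(genome.islands)
    if len(islands) < cfg.n_tumour_markers + cfg.n_basal_markers:
        raise ValueError("not enough islands for the requested markers")
    idx = rng.choice(
        len(islands), size=cfg.n_tumour_markers + cfg.n_basal_markers,
        replace=False,
    )
    truth.tumour_markers = [islands[i] for i in idx[: cfg.n_tumour_markers]]
    truth.basal_markers = [islands[i] for i in idx[cfg.n_tumour_markers :]]


# ---------------------------------------------------------------------------
# MBD capture counts


def simulate_mbd_counts(
    genome: SyntheticGenome,
    samples: SampleSheet,
    truth: SimulationTruth,
    depth: float = 30.0,
    dispersion: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Window-by-sample MBD capture counts plus an 'SssI' control column.

    Per window the expected count is depth * CpG_weight * methylation_level;
    the SssI control is fully methylated (level 1).  Implanted DMRs shift the
    vHMEC level by the truth effect at both time points; HMEC is untouched.
    """
    rng = np.random.default_rng(seed)
    n_win = genome.n_windows()
    level_hmec = genome.baseline_meth.copy()
    level_vhmec = genome.baseline_meth.copy()
    from .intervals import overlap_pairs

    # IntervalSet sorts; keep effects aligned with the sorted order
    order = sorted(range(len(truth.dmrs)), key=lambda i: truth.dmrs[i][0])
    dmr_set = IntervalSet([truth.dmrs[i][0] for i in order])
    effects = [truth.dmrs[i][2] for i in order]
    for wi, di in overlap_pairs(genome.windows, dmr_set):
        level_vhmec[wi] = float(np.clip(level_vhmec[wi] + effects[di], 0.0, 1.0))

    cols: dict[str, np.ndarray] = {}
    for _, row in samples.table.iterrows():
        level = level_vhmec if row["condition"] == "vHMEC" else level_hmec
        mean = depth * genome.cpg_weight * level
        cols[row["sample_id"]] = _nb_draw(rng, mean, dispersion)
    cols["SssI"] = _nb_draw(rng, depth * genome.cpg_weight, dispersion)
    return pd.DataFrame(cols, index=genome.window_ids())


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    mean = np.maximum(np.asarray(mean, dtype=float), 0.0)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    out = np.zeros(mean.shape, dtype=int)
    pos = mean > 0
    out[pos] = rng.negative_binomial(r, r / (r + mean[pos]))
    return out


# ---------------------------------------------------------------------------
# ChIP counts


def simulate_chip_counts(
    genome: SyntheticGenome,
    samples: SampleSheet,
    truth: SimulationTruth,
    window: int = 200,
    background_mean: float = 2.0,
    enrichment_fold: float = 8.0,
    dispersion: float = 0.05,
    seed: int = 0,
) -> tuple[IntervalSet, dict[str, pd.DataFrame]]:
    """Per-mark window-by-sample ChIP counts over a fine tiling.

    Windows inside a truth domain of a mark (for the sample's condition) have
    expected count background_mean * enrichment_fold; everything else sits at
    the NB background.
    """
    rng = np.random.default_rng(seed)
    windows: list[GenomicInterval] = []
    for chrom in sorted(genome.chrom_sizes):
        size = genome.chrom_sizes[chrom]
        for start in range(0, size - window + 1, window):
            windows.append(GenomicInterval(chrom, start, start + window))
    window_set = IntervalSet(windows)
    ids = [str(iv) for iv in window_set]
    from .intervals import overlap_pairs

    result: dict[str, pd.DataFrame] = {}
    for mark in MARKS:
        enriched = {}
        for cond in ("HMEC", "vHMEC"):
            mask = np.zeros(len(window_set), dtype=bool)
            dom = truth.chip_domains.get(mark, {}).get(cond, IntervalSet())
            for wi, _ in overlap_pairs(window_set, dom):
                mask[wi] = True
            enriched[cond] = mask
        cols = {}
        for _, row in samples.table.iterrows():
            mean = np.where(
                enriched[row["condition"]],
                background_mean * enrichment_fold,
                background_mean,
            )
            cols[row["sample_id"]] = _nb_draw(rng, mean, dispersion)
        result[mark] = pd.DataFrame(cols, index=ids)
    return window_set, result


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    genome: SyntheticGenome,
    samples: SampleSheet,
    truth: SimulationTruth,
    sigma: float = 0.5,
    donor_sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-by-sample log2 expression with donor effects and vHMEC shifts.

    Truth genes shift by their log2 effect in every vHMEC sample, so the
    change is consistent between the early and late time points.
    """
    rng = np.random.default_rng(seed)
    gene_ids = [g.gene_id for g in genome.genes]
    base = rng.normal(8.0, 2.0, size=len(gene_ids))
    donors = sorted(set(samples.table["donor"]))
    donor_shift = {
        d: rng.normal(0.0, donor_sd, size=len(gene_ids)) for d in donors
    }
    effect = np.array([truth.de_genes.get(g, 0.0) for g in gene_ids])
    cols = {}
    for _, row in samples.table.iterrows():
        mu = base + donor_shift[row["donor"]]
        if row["condition"] == "vHMEC":
            mu = mu + effect
        cols[row["sample_id"]] = mu + rng.normal(0.0, sigma, size=len(gene_ids))
    return pd.DataFrame(cols, index=gene_ids)


# ---------------------------------------------------------------------------
# beta matrices


@dataclass
class ProbeLayout:
    probe_ids: list[str]
    probes: IntervalSet            # sorted, aligned with probe_ids
    base_mean: np.ndarray          # per-probe normal-tissue mean beta


def make_probe_layout(genome: SyntheticGenome, probes_per_island: int = 5,
                      n_background: int = 400, seed: int = 0) -> ProbeLayout:
    """Scatter array probes: clustered inside islands, sparse elsewhere."""
    rng = np.random.default_rng(seed)
    entries: list[tuple[GenomicInterval, float]] = []
    for isl in genome.islands:
        k = max(2, int(rng.poisson(probes_per_island)))
        offs = np.sort(rng.integers(0, max(1, len(isl) - 2), size=k))
        for o in offs:
            pos = isl.start + int(o)
            entries.append((GenomicInterval(isl.chrom, pos, pos + 2),
                            float(rng.uniform(0.08, 0.25))))
    chroms = sorted(genome.chrom_sizes)
    for _ in range(n_background):
        chrom = str(rng.choice(chroms))
        pos = int(rng.integers(0, genome.chrom_sizes[chrom] - 2))
        entries.append((GenomicInterval(chrom, pos, pos + 2),
                        float(rng.uniform(0.3, 0.9))))
    entries.sort(key=lambda t: t[0])
    ivs = [iv for iv, _ in entries]
    means = np.array([m for _, m in entries])
    ids = [f"cg{i:06d}" for i in range(len(ivs))]
    return ProbeLayout(ids, IntervalSet(ivs), means)


def simulate_beta_matrix(
    layout: ProbeLayout,
    truth: SimulationTruth,
    n_tumour: int = 120,
    n_normal: int = 60,
    basal_fraction: float = 0.3,
    marker_delta: float = 0.4,
    spread_delta: float = 0.25,
    concentration: float = 30.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SampleSheet]:
    """Probe-by-sample beta values with implanted hypermethylated markers.

    Tumour-marker probes are elevated by marker_delta in every tumour;
    basal-marker probes only in basal-like tumours.  One probe immediately
    flanking each tumour-marker region on each side is elevated by the
    smaller spread_delta, emulating methylation spreading beyond the region.
    """
    if n_tumour < 4 or n_normal < 4:
        raise ValueError("need >= 4 tumour and >= 4 normal samples")
    rng = np.random.default_rng(seed)
    n_probe = len(layout.probe_ids)
    marker_set = IntervalSet(list(truth.tumour_markers))
    basal_set = IntervalSet(list(truth.basal_markers))
    from .intervals import overlaps_any

    in_marker = np.asarray(overlaps_any(layout.probes, marker_set))
    in_basal = np.asarray(overlaps_any(layout.probes, basal_set))
    spread = np.zeros(n_probe, dtype=bool)
    for j in range(n_probe):
        if in_marker[j]:
            for k in (j - 1, j + 1):
                if 0 <= k < n_probe and not in_marker[k] \
                        and layout.probes[k].chrom == layout.probes[j].chrom:
                    spread[k] = True
    truth.spread_probes = [
        layout.probe_ids[j] for j in np.flatnonzero(spread)
    ]

    n_basal_t = int(round(n_tumour * basal_fraction))
    rows = []
    for i in range(n_tumour):
        subtype = "basal" if i < n_basal_t else "other"
        rows.append((f"T{i + 1:03d}", "NA", "NA", "NA", "tumour", subtype))
    for i in range(n_normal):
        rows.append((f"N{i + 1:03d}", "NA", "NA", "NA", "normal", "NA"))
    sheet = SampleSheet(pd.DataFrame(
        rows,
        columns=["sample_id", "donor", "condition", "timepoint", "group",
                 "subtype"],
    ))

    cols = {}
    for _, row in sheet.table.iterrows():
        mean = layout.base_mean.copy()
        if row["group"] == "tumour":
            mean = np.where(in_marker, mean + marker_delta, mean)
            mean = np.where(spread, mean + spread_delta, mean)
            if row["subtype"] == "basal":
                mean = np.where(in_basal, mean + marker_delta, mean)
        mean = np.clip(mean, 0.02, 0.98)
        a = mean * concentration
        b = (1.0 - mean) * concentration
        cols[row["sample_id"]] = rng.beta(a, b)
    betas = pd.DataFrame(cols, index=layout.probe_ids)
    return betas, sheet


# ---------------------------------------------------------------------------
# miRNA Ct tables


def simulate_ct_table(
    truth: SimulationTruth,
    n_mirna: int = 60,
    n_undetected: int = 6,
    n_invariant: int = 6,
    controls: tuple[str, ...] = ("ctrl-1", "ctrl-2"),
    donors: tuple[str, ...] = DONORS,
    noise_sd: float = 0.3,
    donor_sd: float = 0.7,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """A miRNA-by-sample Ct table for paired HMEC/vHMEC cultures.

    Ct = base + donor effect - log2(fold) + technical noise, with truth
    folds applied in vHMEC only.  The per-(miRNA, donor) effect models
    biological expression variation between donors; it is shared by the
    paired HMEC/vHMEC cultures and so cancels in paired contrasts.
    Control genes are near-constant, undetected miRNAs carry the Ct = 40
    sentinel, and invariant miRNAs have neither donor effects nor
    appreciable noise.
    """
    rng = np.random.default_rng(seed)
    samples = [f"{d}_{c}" for d in donors for c in ("HMEC", "vHMEC")]
    names = list(truth.mirna_folds)
    i = 1
    while len(names) < n_mirna:
        cand = f"mir-{i + 500:03d}"
        if cand not in truth.mirna_folds:
            names.append(cand)
        i += 1
    names = names[:n_mirna]
    undetected = set(names[-n_undetected:]) if n_undetected else set()
    invariant = set(
        names[-(n_undetected + n_invariant) : -n_undetected or None]
    ) if n_invariant else set()

    rows = {}
    for ctrl in controls:
        rows[ctrl] = 18.0 + rng.normal(0.0, 0.02, size=len(samples))
    for name in names:
        base = float(rng.uniform(22.0, 30.0))
        fold = truth.mirna_folds.get(name, 1.0)
        flat = name in invariant
        donor_eff = {
            d: 0.0 if flat else float(rng.normal(0.0, donor_sd))
            for d in donors
        }
        vals = []
        for s in samples:
            if name in undetected:
                vals.append(40.0)
                continue
            sd = 0.01 if flat else noise_sd
            donor = s.split("_")[0]
            ct = base + donor_eff[donor] + rng.normal(0.0, sd)
            if s.endswith("_vHMEC") and fold != 1.0:
                ct -= math.log2(fold)
            vals.append(min(ct, 40.0))
        rows[name] = np.asarray(vals)
    table = pd.DataFrame(rows, index=samples).T
    table.index.name = "mirna"
    return table, list(controls)
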