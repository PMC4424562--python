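"""Long-range epigenetic regulation (LREA/LRES) domain detection.

Scans each chromosome with a window of consecutive genes, seeding a domain
wherever enough genes shift concordantly in one data type: activation
(LREA) means expression or promoter H3K9ac up, or H3K27me3 down, in vHMEC;
silencing (LRES) is the mirror image.  Overlapping seed windows of the same
type merge, and the domain spans its first to last concordant gene.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chip import GeneEpiProfile, tss_block_stats
from .intervals import GenomicInterval, IntervalSet
from .io import GeneModel, SampleSheet
from .stats import moderated_t

# sign each data type contributes to an *activation* call
_ACTIVATION_SIGN = {"expression": 1.0, "H3K9ac": 1.0, "H3K27me3": -1.0}
_SLOT = {"expression": "t_expression", "H3K9ac": "t_h3k9ac",
         "H3K27me3": "t_h3k27me3"}


@dataclass
class LrerRegion:
    interval: GenomicInterval
    kind: str                      # LREA | LRES
    seed_data_type: str            # expression | H3K9ac | H3K27me3
    gene_ids: list[str]
    t_values: dict[str, list[float]] = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def span_bp(self) -> int:
        return len(self.interval)

    @property
    def name(self) -> str:
        short = {"expression": "exp", "H3K9ac": "k9ac", "H3K27me3": "k27me3"}
        return f"{self.kind}.{short[self.seed_data_type]}"


def compute_gene_stats(
    expression: pd.DataFrame,
    k9ac_windows: IntervalSet,
    k9ac_signal: pd.DataFrame,
    k27me3_windows: IntervalSet,
    k27me3_signal: pd.DataFrame,
    gene_models: list[GeneModel],
    samples: SampleSheet,
    chrom_sizes: dict[str, int] | None = None,
) -> list[GeneEpiProfile]:
    """Join expression and TSS-block chromatin t-statistics per gene.

    Expression uses the moderated t (vHMEC vs HMEC); H3K9ac and H3K27me3
    use the ordinary t on signal summed over TSS +/- 2 kb.  A gene absent
    from a data type keeps NaN in that slot, which call_lrer treats as
    non-concordant.
    """
    vh = samples.ids(condition="vHMEC")
    hm = samples.ids(condition="HMEC")
    expr_genes = [g for g in gene_models if g.gene_id in expression.index]
    t_expr = {}
    if expr_genes:
        sub = expression.loc[[g.gene_id for g in expr_genes]]
        res = moderated_t(sub[vh], sub[hm])
        t_expr = dict(zip(res.index, res["statistic"]))

    chip_samples = samples
    k9 = tss_block_stats(gene_models, k9ac_windows, k9ac_signal,
                         chip_samples, chrom_sizes=chrom_sizes)
    k27 = tss_block_stats(gene_models, k27me3_windows, k27me3_signal,
                          chip_samples, chrom_sizes=chrom_sizes)
    profiles = []
    for g in gene_models:
        profiles.append(GeneEpiProfile(
            g.gene_id, g.tss, g.interval.chrom,
            t_expression=float(t_expr.get(g.gene_id, math.nan)),
            t_h3k9ac=float(k9.loc[g.gene_id, "statistic"])
            if g.gene_id in k9.index else math.nan,
            t_h3k27me3=float(k27.loc[g.gene_id, "statistic"])
            if g.gene_id in k27.index else math.nan,
        ))
    return profiles


def call_lrer(
    profiles: list[GeneEpiProfile],
    window_genes: int = 5,
    min_concordant: int = 3,
    t_threshold: float = 3.0,
) -> list[LrerRegion]:
    """Sliding-window detection of concordant multi-gene domains.

    A window of ``window_genes`` consecutive genes seeds a domain when at
    least ``min_concordant`` of them exceed |t| > t_threshold in one data
    type, all pointing the same way for one direction.  Same-type
    overlapping seed windows merge; the domain runs from its first to its
    last concordant gene and reports evidence from all three data types.
    """
    if not (0 < min_concordant <= window_genes):
        raise ValueError("require 0 < min_concordant <= window_genes")
    by_chrom: dict[str, list[GeneEpiProfile]] = {}
    for p in profiles:
        by_chrom.setdefault(p.chrom, []).append(p)
    regions: list[LrerRegion] = []
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda p: p.tss)
        if len(genes) < window_genes:
            warnings.warn(f"{chrom}: fewer than {window_genes} genes; skipped")
            continue
        regions.extend(
            _call_chromosome(genes, window_genes, min_concordant, t_threshold)
        )
    return regions


def _concordant(profile: GeneEpiProfile, data_type: str, kind: str,
                t_threshold: float) -> bool:
    t = getattr(profile, _SLOT[data_type])
    if not math.isfinite(t) or abs(t) <= t_threshold:
        return False
    sign = _ACTIVATION_SIGN[data_type] * (1.0 if kind == "LREA" else -1.0)
    return t * sign > 0


def _call_chromosome(genes, window_genes, min_concordant, t_threshold):
    n = len(genes)
    regions = []
    for kind in ("LREA", "LRES"):
        for data_type in _ACTIVATION_SIGN:
            hits = np.array([
                _concordant(g, data_type, kind, t_threshold) for g in genes
            ])
            # seed windows, as index ranges [i, i + window_genes)
            seeded = [
                i for i in range(n - window_genes + 1)
                if hits[i : i + window_genes].sum() >= min_concordant
            ]
            if not seeded:
                continue
            # merge overlapping seed windows
            groups: list[tuple[int, int]] = []
            lo = hi = seeded[0]
            for i in seeded[1:]:
                if i <= hi + window_genes - 1:
                    hi = i
                else:
                    groups.append((lo, hi))
                    lo = hi = i
            groups.append((lo, hi))
            for lo, hi in groups:
                idx = [
                    j for j in range(lo, hi + window_genes) if hits[j]
                ]
                members = genes[idx[0] : idx[-1] + 1]
                iv = GenomicInterval(
                    members[0].chrom,
                    min(g.tss for g in members),
                    max(g.tss for g in members) + 1,
                )
                regions.append(LrerRegion(
                    iv, kind, data_type,
                    [g.gene_id for g in members],
                    {
                        dt: [getattr(g, _SLOT[dt]) for g in members]
                        for dt in _ACTIVATION_SIGN
                    },
                ))
    return regions


def summarize_lrer(regions: list[LrerRegion]) -> dict:
    """Counts, mean span and mean genes per region, split by type."""
    out = {}
    for kind in ("LREA", "LRES"):
        sub = [r for r in regions if r.kind == kind]
        out[f"n_{kind}"] = len(sub)
        out[f"mean_span_bp_{kind}"] = (
            float(np.mean([r.span_bp for r in sub])) if sub else 0.0
        )
        out[f"mean_genes_{kind}"] = (
            float(np.mean([r.n_genes for r in sub])) if sub else 0.0
        )
    return out


def lrer_table(regions: list[LrerRegion]) -> pd.DataFrame:
    rows = [{
        "chrom": r.interval.chrom,
        "start": r.interval.start,
        "end": r.interval.end,
        "name": r.name,
        "type": r.kind,
        "seed_data_type": r.seed_data_type,
        "n_genes": r.n_genes,
        "span_bp": r.span_bp,
        "genes": ",".join(r.gene_ids),
    } for r in regions]
    return pd.DataFrame(rows)
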