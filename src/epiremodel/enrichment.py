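"""Feature-overlap and gene-set enrichment.

Interval enrichment (DMRs against CpG islands, promoters, TFBS, chromatin
states) uses the locus-bootstrap permutation test with BH correction across
the tested features; gene-set enrichment of promoter-hypermethylated gene
lists uses the upper-tail hypergeometric test against a declared universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .intervals import GenomicInterval, IntervalSet, overlap_pairs
from .io import GeneModel
from .stats import bh_adjust, hypergeom_test, permutation_enrichment


@dataclass
class EnrichmentRecord:
    feature: str
    observed: float
    expected: float
    fold: float
    p: float
    padj: float
    direction: str                 # enriched | depleted


def feature_enrichment(
    query: IntervalSet,
    feature_sets: dict[str, IntervalSet],
    universe: IntervalSet,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[EnrichmentRecord]:
    """Permutation overlap enrichment of a query set per named feature."""
    results = []
    for fi, (name, feature) in enumerate(sorted(feature_sets.items())):
        res = permutation_enrichment(query, feature, universe,
                                     n_perm=n_perm, seed=seed + fi)
        results.append((name, res))
    padj = bh_adjust([r.p for _, r in results])
    return [
        EnrichmentRecord(name, r.observed, r.expected, r.fold, r.p,
                         float(q), r.direction)
        for (name, r), q in zip(results, padj)
    ]


def map_dmrs_to_promoters(
    dmrs: IntervalSet,
    gene_models: list[GeneModel],
    flank_bp: int = 2000,
) -> list[str]:
    """Unique gene ids whose promoter (TSS +/- flank) overlaps any DMR.

    The mapping is many-to-many (a DMR may hit several promoters and a
    promoter several DMRs); genes are reported once, in genomic order.
    """
    if flank_bp <= 0:
        raise ValueError("flank_bp must be > 0")
    promoters = []
    ids = []
    for g in gene_models:
        lo = max(0, g.tss - flank_bp)
        promoters.append(GenomicInterval(g.interval.chrom, lo, g.tss + flank_bp))
        ids.append(g.gene_id)
    order = sorted(range(len(promoters)), key=lambda i: promoters[i])
    prom_set = IntervalSet(list(promoters))
    hit: list[str] = []
    seen = set()
    for _, pi in sorted(overlap_pairs(dmrs, prom_set), key=lambda t: t[1]):
        gid = ids[order[pi]]
        if gid not in seen:
            seen.add(gid)
            hit.append(gid)
    return hit


def gene_set_enrichment(
    query_genes: list[str],
    gene_sets: dict[str, list[str]],
    universe_genes: list[str],
) -> list[EnrichmentRecord]:
    """Hypergeometric over-representation of query genes in each gene set."""
    universe = set(universe_genes)
    query = set(query_genes) & universe
    n = len(query)
    records = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & universe
        k = len(query & members)
        res = hypergeom_test(k, len(members), n, len(universe))
        expected = n * len(members) / len(universe) if universe else 0.0
        records.append((name, k, expected, res))
    padj = bh_adjust([r.p for _, _, _, r in records])
    return [
        EnrichmentRecord(
            name, float(k), float(expected),
            (k / expected) if expected > 0 else float("nan"),
            r.p, float(q),
            "enriched" if expected == 0 or k >= expected else "depleted",
        )
        for (name, k, expected, r), q in zip(records, padj)
    ]


def enrichment_table(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "feature": r.feature,
        "observed": r.observed,
        "expected": r.expected,
        "fold": r.fold,
        "p": r.p,
        "padj": r.padj,
        "direction": r.direction,
    } for r in records])
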