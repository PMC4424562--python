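"""Chromatin-state annotation from overlapping histone-mark regions.

Segments the genome at every region boundary of the four classifying marks
(H3K4me3, H3K27ac, H3K36me3, H3K27me3) and maps each segment's
presence/absence vector to one of eight functional categories.  The
combination table follows standard chromatin semantics: bivalency
(K4me3+K27me3) dominates, K27ac separates active promoters from enhancers,
K36me3 marks transcription, and K27me3 without K4me3 is Polycomb
repression.
"""

from __future__ import annotations

from dataclasses import dataclass

from .intervals import GenomicInterval, IntervalSet
from .methylome import AssayableLoci, DmrResult
from .stats import EnrichmentResult, permutation_enrichment

CLASSIFYING_MARKS = ("H3K4me3", "H3K27ac", "H3K36me3", "H3K27me3")

STATES = (
    "Promoter_1",
    "Promoter_2",
    "Promoter_3",
    "Bivalent_Promoter",
    "Enhancer",
    "Transcribed_Enhancer",
    "Transcribed",
    "Polycomb_Repressed",
    "Unclassified",
)

# precedence-ordered rules: (required marks, forbidden marks) -> state
_RULES: tuple[tuple[frozenset, frozenset, str], ...] = (
    (frozenset({"H3K4me3", "H3K27me3"}), frozenset(), "Bivalent_Promoter"),
    (frozenset({"H3K4me3", "H3K27ac"}), frozenset(), "Promoter_1"),
    (frozenset({"H3K4me3", "H3K36me3"}), frozenset(), "Promoter_3"),
    (frozenset({"H3K4me3"}), frozenset(), "Promoter_2"),
    (frozenset({"H3K27ac", "H3K36me3"}), frozenset(), "Transcribed_Enhancer"),
    # the conflicting K27ac+K27me3 (no K4me3) vector falls to repression
    (frozenset({"H3K27ac"}), frozenset({"H3K27me3"}), "Enhancer"),
    (frozenset({"H3K27me3"}), frozenset({"H3K4me3"}), "Polycomb_Repressed"),
    (frozenset({"H3K36me3"}), frozenset(), "Transcribed"),
)


@dataclass
class StateAnnotation:
    interval: GenomicInterval
    state: str
    condition: str
    marks: tuple[bool, bool, bool, bool]   # (K4me3, K27ac, K36me3, K27me3)


def classify_state(mark_vector: tuple[bool, bool, bool, bool]) -> str:
    """Map a (K4me3, K27ac, K36me3, K27me3) presence vector to its state.

    Total and deterministic over all 16 combinations; the first matching
    rule in precedence order wins and the empty vector is Unclassified.
    """
    present = {m for m, on in zip(CLASSIFYING_MARKS, mark_vector) if on}
    for required, forbidden, state in _RULES:
        if required <= present and not (forbidden & present):
            return state
    return "Unclassified"


def segment_genome(
    mark_regions: dict[str, IntervalSet],
    condition: str = "NA",
) -> list[StateAnnotation]:
    """Flat segmentation at every mark-region boundary, with state calls.

    Each elementary segment (between consecutive breakpoints) carries the
    presence vector of the four classifying marks; segments carrying no
    mark are dropped.  Per-mark covered bases are conserved exactly.
    """
    for mark in mark_regions:
        if mark not in CLASSIFYING_MARKS:
            raise ValueError(f"unknown classifying mark {mark!r}")
    from .intervals import merge_intervals

    merged = {
        mark: merge_intervals(ivs, 0) for mark, ivs in mark_regions.items()
    }
    breaks: dict[str, set[int]] = {}
    for ivs in merged.values():
        for iv in ivs:
            breaks.setdefault(iv.chrom, set()).update((iv.start, iv.end))
    # per-mark, per-chrom sorted (start, end) lists for bisect containment
    import bisect

    lookup: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for mark, ivs in merged.items():
        d: dict[str, list[tuple[int, int]]] = {}
        for iv in ivs:
            d.setdefault(iv.chrom, []).append((iv.start, iv.end))
        lookup[mark] = d

    def covers(mark: str, chrom: str, lo: int, hi: int) -> bool:
        spans = lookup.get(mark, {}).get(chrom, [])
        j = bisect.bisect_right(spans, (lo, float("inf"))) - 1
        return j >= 0 and spans[j][0] <= lo and hi <= spans[j][1]

    out: list[StateAnnotation] = []
    for chrom in sorted(breaks):
        pts = sorted(breaks[chrom])
        for lo, hi in zip(pts, pts[1:]):
            vector = tuple(
                covers(mark, chrom, lo, hi) for mark in CLASSIFYING_MARKS
            )
            if not any(vector):
                continue
            out.append(StateAnnotation(
                GenomicInterval(chrom, lo, hi),
                classify_state(vector), condition, vector,
            ))
    return out


def state_intervals(annotations: list[StateAnnotation],
                    state: str) -> IntervalSet:
    return IntervalSet([a.interval for a in annotations if a.state == state])


def state_enrichment(
    dmrs: list[DmrResult],
    annotations: list[StateAnnotation],
    universe: AssayableLoci,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict[str, dict[str, EnrichmentResult]]:
    """Permutation enrichment of hyper/hypo DMRs in each chromatin state."""
    out: dict[str, dict[str, EnrichmentResult]] = {}
    for direction in ("hyper", "hypo"):
        query = IntervalSet([
            d.interval for d in dmrs if d.stable and d.direction == direction
        ])
        per_state: dict[str, EnrichmentResult] = {}
        if len(query) == 0:
            out[direction] = per_state
            continue
        for si, state in enumerate(s for s in STATES if s != "Unclassified"):
            feature = state_intervals(annotations, state)
            if len(feature) == 0:
                continue
            per_state[state] = permutation_enrichment(
                query, feature, universe.loci, n_perm=n_perm,
                seed=seed + si,
            )
        out[direction] = per_state
    return out
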