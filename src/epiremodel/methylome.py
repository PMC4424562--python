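"""Assayable-locus masking and DMR calling from MBD-capture window counts.

MBD capture coverage tracks methylated-CpG density, so windows that fail to
attract reads even in a fully methylated (SssI-treated) control are
unassayable and are masked out before any differential testing.  Loci that
pass the mask are then tested for read-density change between HMEC and
vHMEC at both the early and the late vHMEC passage; a region is a *stable*
DMR when both contrasts are significant in the same direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet, overlap_pairs
from .io import SampleSheet
from .stats import bh_adjust, estimate_dispersion, nb_exact_test


@dataclass
class AssayableLoci:
    """The mask of loci with reliable capture in the SssI control."""

    loci: IntervalSet
    sssi_counts: np.ndarray
    window: int = 300
    min_dist: int = 300
    tag_threshold: int = 18

    def __len__(self) -> int:
        return len(self.loci)


@dataclass
class DmrResult:
    interval: GenomicInterval
    direction: str                 # hyper | hypo
    log2fc_early: float
    log2fc_late: float
    p_early: float
    p_late: float
    padj_early: float
    padj_late: float
    stable: bool = False


def parse_window_index(ids) -> IntervalSet:
    """Parse 'chrom:start-end' row ids back into an IntervalSet (in order)."""
    ivs = []
    for wid in ids:
        chrom, span = wid.rsplit(":", 1)
        start, end = span.split("-")
        ivs.append(GenomicInterval(chrom, int(start), int(end)))
    return IntervalSet(ivs)


def call_assayable_loci(
    windows: IntervalSet,
    sssi_counts: np.ndarray,
    window: int = 300,
    min_dist: int = 300,
    tag_threshold: int = 18,
) -> AssayableLoci:
    """Greedy selection of assayable loci from SssI control coverage.

    Candidate windows with count >= tag_threshold are taken in descending
    count order (position breaks ties); a selected locus suppresses any
    candidate whose start lies within min_dist of its own start.
    """
    counts = np.asarray(sssi_counts, dtype=float)
    if len(windows) != counts.size:
        raise ValueError("counts must align with windows")
    if counts.size == 0:
        warnings.warn("empty input; assayable mask is empty")
        return AssayableLoci(IntervalSet(), counts, window, min_dist,
                             tag_threshold)
    cand = np.flatnonzero(counts >= tag_threshold)
    order = sorted(cand, key=lambda i: (-counts[i], windows[i].chrom,
                                        windows[i].start))
    import bisect

    chosen: list[int] = []
    taken: dict[str, list[int]] = {}
    for i in order:
        iv = windows[i]
        starts = taken.setdefault(iv.chrom, [])
        j = bisect.bisect_left(starts, iv.start)
        near = (j > 0 and iv.start - starts[j - 1] < min_dist) or (
            j < len(starts) and starts[j] - iv.start < min_dist
        )
        if near:
            continue
        starts.insert(j, iv.start)
        chosen.append(i)
    chosen.sort(key=lambda i: windows[i])
    return AssayableLoci(
        IntervalSet([windows[i] for i in chosen]),
        counts[chosen],
        window, min_dist, tag_threshold,
    )


def count_in_loci(
    window_counts: pd.DataFrame,
    windows: IntervalSet,
    loci: AssayableLoci,
) -> pd.DataFrame:
    """Sum window counts into assayable loci, per sample.

    Library size per sample is its total count within the mask; stored in
    ``.attrs["lib_sizes"]``.
    """
    if len(windows) != window_counts.shape[0]:
        raise ValueError("window_counts rows must align with windows")
    n_loci = len(loci.loci)
    out = np.zeros((n_loci, window_counts.shape[1]))
    vals = window_counts.to_numpy()
    for wi, li in overlap_pairs(windows, loci.loci):
        out[li] += vals[wi]
    result = pd.DataFrame(
        out, index=[str(iv) for iv in loci.loci], columns=window_counts.columns
    )
    result.attrs["lib_sizes"] = result.sum(axis=0).to_numpy()
    return result


def call_dmrs(
    counts: pd.DataFrame,
    samples: SampleSheet,
    alpha: float = 0.05,
) -> list[DmrResult]:
    """NB exact tests of vHMEC (early and late) against HMEC per locus.

    The common dispersion is estimated once, pooling within-group moments
    across all conditions; a locus is a stable DMR when BH-adjusted p <
    alpha in *both* time-point contrasts with the same fold-change sign.
    """
    hmec = samples.ids(condition="HMEC")
    early = samples.ids(condition="vHMEC", timepoint="early")
    late = samples.ids(condition="vHMEC", timepoint="late")
    for name, ids in (("HMEC", hmec), ("early vHMEC", early),
                      ("late vHMEC", late)):
        if len(ids) < 2:
            raise ValueError(f"need >= 2 {name} samples")
    cols = hmec + early + late
    mat = counts[cols]
    libs = mat.sum(axis=0).to_numpy()
    groups = ["HMEC"] * len(hmec) + ["early"] * len(early) + ["late"] * len(late)
    phi = estimate_dispersion(mat.to_numpy(), libs, groups)

    lib_by_col = dict(zip(cols, libs))
    results: list[DmrResult] = []
    contrasts = {}
    for key, ids in (("early", early), ("late", late)):
        a = counts[ids].to_numpy()
        b = counts[hmec].to_numpy()
        la = np.array([lib_by_col[c] for c in ids])
        lb = np.array([lib_by_col[c] for c in hmec])
        libvec = np.concatenate([la, lb])
        tests = [
            nb_exact_test(a[i], b[i], libvec, phi) for i in range(a.shape[0])
        ]
        contrasts[key] = tests

    padj_early = bh_adjust([t.p for t in contrasts["early"]])
    padj_late = bh_adjust([t.p for t in contrasts["late"]])
    intervals = parse_window_index(counts.index)
    for i, iv in enumerate(intervals):
        te, tl = contrasts["early"][i], contrasts["late"][i]
        same_sign = te.effect * tl.effect > 0
        stable = bool(
            padj_early[i] < alpha and padj_late[i] < alpha and same_sign
        )
        direction = "hyper" if te.effect + tl.effect > 0 else "hypo"
        results.append(DmrResult(
            iv, direction, te.effect, tl.effect, te.p, tl.p,
            float(padj_early[i]), float(padj_late[i]), stable,
        ))
    return results


def stable_dmrs(results: list[DmrResult],
                direction: str | None = None) -> list[DmrResult]:
    return [r for r in results if r.stable
            and direction in (None, r.direction)]


def dmr_summary(results: list[DmrResult]) -> dict:
    stable = [r for r in results if r.stable]
    return {
        "n_loci_tested": len(results),
        "n_stable": len(stable),
        "n_hyper": sum(r.direction == "hyper" for r in stable),
        "n_hypo": sum(r.direction == "hypo" for r in stable),
    }


def dmr_table(results: list[DmrResult]) -> pd.DataFrame:
    rows = [{
        "chrom": r.interval.chrom,
        "start": r.interval.start,
        "end": r.interval.end,
        "direction": r.direction,
        "log2fc_early": r.log2fc_early,
        "log2fc_late": r.log2fc_late,
        "p_early": r.p_early,
        "p_late": r.p_late,
        "padj_early": r.padj_early,
        "padj_late": r.padj_late,
        "stable": r.stable,
    } for r in results]
    return pd.DataFrame(rows)
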