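"""Methylation biomarker discovery on array beta values.

Candidate regions (typically capture-derived DMRs mapped onto array probes)
are scored per sample by mean beta over member probes, the cohort is split
75/25 into stratified training and test sets, regions are ranked by
training AUC, and only regions whose *test* AUC clears the gate are kept
(0.95 for tumour-vs-normal, 0.7 for basal-vs-other-tumour, where the basal
path also demands at least one member probe hypermethylated in basal
tumours).  Selected regions may then be extended probe-by-probe while the
immediately adjacent probes are themselves significantly hypermethylated in
the training cohort — methylation spreading beyond the original region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet, overlap_pairs
from .io import SampleSheet
from .stats import auc_mann_whitney, bh_adjust, moderated_t

M_EPS = 0.01


@dataclass
class RocCandidate:
    region: GenomicInterval
    probes: list[str]
    train_auc: float
    test_auc: float
    comparison: str                # tumour_vs_normal | basal_vs_other_tumours
    direction: str = "hyper"
    extended_probes: list[str] = field(default_factory=list)
    extended_train_auc: float = math.nan
    extended_test_auc: float = math.nan
    region_extended: GenomicInterval | None = None

    @property
    def extended_region(self) -> GenomicInterval:
        return self.region_extended if self.region_extended else self.region


def beta_to_m(betas: pd.DataFrame | np.ndarray,
              eps: float = M_EPS) -> pd.DataFrame | np.ndarray:
    """Logit-like M-value transform, finite at beta = 0 and 1."""
    b = np.asarray(betas, dtype=float) if not isinstance(betas, pd.DataFrame) \
        else betas
    return np.log2((b + eps) / (1.0 - b + eps))


def differential_probes(
    betas: pd.DataFrame,
    samples: SampleSheet,
    class_a: tuple[str, str],
    class_b: tuple[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Moderated t on M-values, class_a vs class_b ((column, value) pairs).

    Returns per-probe statistic, p, padj, delta_beta (mean_a - mean_b) and
    a ``hyper`` flag (significant with positive delta toward class_a).
    """
    ids_a = samples.ids(**{class_a[0]: class_a[1]})
    ids_b = samples.ids(**{class_b[0]: class_b[1]})
    if len(ids_a) < 4 or len(ids_b) < 4:
        raise ValueError("need >= 4 samples per class")
    m = beta_to_m(betas)
    res = moderated_t(m[ids_a], m[ids_b])
    res["padj"] = bh_adjust(res["p"].to_numpy())
    res["delta_beta"] = (
        betas[ids_a].mean(axis=1) - betas[ids_b].mean(axis=1)
    ).to_numpy()
    res["hyper"] = (res["padj"] < alpha) & (res["delta_beta"] > 0)
    return res


def region_score(betas: pd.DataFrame, probes: list[str]) -> pd.Series:
    """Mean beta over member probes per sample; NaN probes are ignored."""
    present = [p for p in probes if p in betas.index]
    if not present:
        return pd.Series(math.nan, index=betas.columns)
    return betas.loc[present].mean(axis=0, skipna=True)


def probes_in_region(probe_ids: list[str], probes: IntervalSet,
                     region: GenomicInterval) -> list[str]:
    return [
        probe_ids[i]
        for i, _ in overlap_pairs(probes, IntervalSet([region]))
    ]


def stratified_split(
    labels: pd.Series,
    train_fraction: float = 0.75,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Seeded stratified split of sample ids into train/test cohorts."""
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for value in sorted(labels.unique()):
        ids = sorted(labels.index[labels == value])
        rng.shuffle(ids)
        n_train = int(round(train_fraction * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        train.extend(ids[:n_train])
        test.extend(ids[n_train:])
    for value in sorted(labels.unique()):
        if value not in set(labels[train]) or value not in set(labels[test]):
            raise ValueError(f"class {value!r} absent from a cohort")
    return sorted(train), sorted(test)


def roc_select(
    betas: pd.DataFrame,
    samples: SampleSheet,
    regions: list[tuple[GenomicInterval, list[str]]],
    comparison: str = "tumour_vs_normal",
    train_fraction: float = 0.75,
    test_auc_min: float | None = None,
    train_rank_n: int | None = None,
    seed: int = 0,
) -> list[RocCandidate]:
    """Seeded 75/25 train/test ROC selection of candidate regions.

    Regions are ranked by training AUC (optionally truncated to the top
    train_rank_n); a region is selected when its test-cohort AUC meets the
    gate.  The basal comparison additionally requires >= 1 member probe
    hypermethylated in basal versus other tumours in the training cohort.
    """
    if comparison == "tumour_vs_normal":
        labels = samples.table.set_index("sample_id")["group"]
        pos_label, neg_label = "tumour", "normal"
        gate = 0.95 if test_auc_min is None else test_auc_min
    elif comparison == "basal_vs_other_tumours":
        tum = samples.table[samples.table["group"] == "tumour"]
        labels = tum.set_index("sample_id")["subtype"]
        pos_label, neg_label = "basal", "other"
        gate = 0.7 if test_auc_min is None else test_auc_min
    else:
        raise ValueError(f"unknown comparison {comparison!r}")
    labels = labels[labels.index.intersection(betas.columns)]
    train, test = stratified_split(labels, train_fraction, seed)

    hyper_in_basal: pd.Index | None = None
    if comparison == "basal_vs_other_tumours":
        train_sheet = SampleSheet(
            samples.table[samples.table["sample_id"].isin(train)].copy()
        )
        stats = differential_probes(
            betas[train], train_sheet, ("subtype", "basal"),
            ("subtype", "other"),
        )
        hyper_in_basal = stats.index[stats["hyper"]]

    def cohort_auc(probes: list[str], ids: list[str]) -> float:
        score = region_score(betas[ids], probes)
        pos = score[[i for i in ids if labels.get(i) == pos_label]]
        neg = score[[i for i in ids if labels.get(i) == neg_label]]
        return auc_mann_whitney(pos.to_numpy(), neg.to_numpy())

    scored = []
    for region, probes in regions:
        if not probes:
            continue
        if hyper_in_basal is not None and \
                not set(probes) & set(hyper_in_basal):
            continue
        scored.append((region, probes, cohort_auc(probes, train)))
    scored.sort(key=lambda t: -t[2])
    if train_rank_n is not None:
        scored = scored[:train_rank_n]

    out = []
    for region, probes, train_auc in scored:
        test_auc = cohort_auc(probes, test)
        if test_auc >= gate:
            out.append(RocCandidate(region, probes, float(train_auc),
                                    float(test_auc), comparison))
    return out


def spread_extend(
    candidate: RocCandidate,
    betas: pd.DataFrame,
    probe_ids: list[str],
    probes: IntervalSet,
    train_probe_stats: pd.DataFrame,
    samples: SampleSheet,
    train_ids: list[str],
    test_ids: list[str],
    max_gap_probes: int = 1,
    delta_beta_min: float = 0.1,
    alpha: float = 0.05,
) -> RocCandidate:
    """Grow a candidate region over adjacent hypermethylated probes.

    Walks outward one probe at a time on each side, keeping probes that are
    significantly hypermethylated in the *training* cohort (BH < alpha and
    delta beta > delta_beta_min) and tolerating at most ``max_gap_probes``
    consecutive non-significant probes before stopping.  Train and test AUC
    are recomputed on the extended probe set; the operation is idempotent.
    """
    labels = samples.table.set_index("sample_id")["group"]

    def is_spread(pid: str) -> bool:
        if pid not in train_probe_stats.index:
            return False
        row = train_probe_stats.loc[pid]
        return bool(row["padj"] < alpha and row["delta_beta"] > delta_beta_min)

    pos_of = {pid: i for i, pid in enumerate(probe_ids)}
    member = sorted((pos_of[p] for p in candidate.probes
                     if p in pos_of))
    if not member:
        return candidate
    chrom = probes[member[0]].chrom
    extended = set(member)
    for step in (-1, 1):
        i = member[0] if step < 0 else member[-1]
        gap = 0
        while True:
            i += step
            if not (0 <= i < len(probe_ids)) or probes[i].chrom != chrom:
                break
            if is_spread(probe_ids[i]):
                extended.add(i)
                gap = 0
            else:
                gap += 1
                if gap > max_gap_probes:
                    break
    ext_ids = [probe_ids[i] for i in sorted(extended)]
    lo = min(probes[i].start for i in extended)
    hi = max(probes[i].end for i in extended)
    region = GenomicInterval(chrom, min(lo, candidate.region.start),
                             max(hi, candidate.region.end))

    def cohort_auc(pids: list[str], ids: list[str]) -> float:
        score = region_score(betas[ids], pids)
        pos = score[[i for i in ids if labels.get(i) == "tumour"]]
        neg = score[[i for i in ids if labels.get(i) == "normal"]]
        return auc_mann_whitney(pos.to_numpy(), neg.to_numpy())

    return RocCandidate(
        candidate.region, candidate.probes, candidate.train_auc,
        candidate.test_auc, candidate.comparison, candidate.direction,
        extended_probes=ext_ids,
        extended_train_auc=float(cohort_auc(ext_ids, train_ids)),
        extended_test_auc=float(cohort_auc(ext_ids, test_ids)),
        region_extended=region,
    )


def methylation_expression_correlation(
    betas: pd.DataFrame,
    expression: pd.Series,
    probes: list[str],
) -> tuple[dict[str, float], float]:
    """Squared Pearson correlation of methylation with paired expression.

    Returns (per-probe R^2, region-score R^2) across the shared samples; a
    constant methylation or expression vector yields R^2 = 0.
    """
    shared = [s for s in betas.columns if s in expression.index]
    expr = expression[shared].to_numpy(dtype=float)
    per_probe = {}
    for p in probes:
        if p not in betas.index:
            continue
        per_probe[p] = _r_squared(betas.loc[p, shared].to_numpy(), expr)
    score = region_score(betas[shared], probes).to_numpy()
    return per_probe, _r_squared(score, expr)


def _r_squared(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)
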