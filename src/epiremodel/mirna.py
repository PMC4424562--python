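"""Relative qPCR quantification of miRNA expression (TLDA-style).

Ct values are normalised per sample against the mean of the included
control genes (dCt), lowly or invariably expressed miRNAs are filtered out,
fold changes come from the ddCt rule (fold = 2^-ddCt), per-donor paired t
tests flag differential miRNAs, and silenced miRNAs are intersected with
predicted targets (mirSVR score strictly below -0.5) and validated targets
among up-regulated genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

UNDETECTED_CT = 40.0


@dataclass(frozen=True)
class TargetPrediction:
    mirna: str
    gene: str
    source: str                    # predicted | validated
    mirsvr: float = math.nan

    def __post_init__(self) -> None:
        if self.source == "predicted" and not math.isfinite(self.mirsvr):
            raise ValueError("predicted entries must carry a mirSVR score")


def _check_controls(ct: pd.DataFrame, controls: list[str]) -> pd.DataFrame:
    missing = [c for c in controls if c not in ct.index]
    if missing:
        raise ValueError(f"control genes absent from table: {missing}")
    ctl = ct.loc[controls]
    bad = ctl.columns[(ctl >= UNDETECTED_CT).any(axis=0)]
    if len(bad):
        raise ValueError(
            f"control gene undetected in samples: {sorted(bad)}"
        )
    return ctl


def delta_ct(ct: pd.DataFrame, controls: list[str]) -> pd.DataFrame:
    """Per-sample control-normalised Ct: dCt = Ct - mean(Ct of controls)."""
    ctl = _check_controls(ct, controls)
    dct = ct.drop(index=controls).sub(ctl.mean(axis=0), axis=1)
    return dct


def ddct(
    ct: pd.DataFrame,
    controls: list[str],
    reference_samples: list[str],
    target_samples: list[str],
) -> pd.DataFrame:
    """ddCt and fold change (2^-ddCt) per miRNA, target vs reference."""
    dct = delta_ct(ct, controls)
    dd = dct[target_samples].mean(axis=1) - dct[reference_samples].mean(axis=1)
    return pd.DataFrame({"ddct": dd, "fold": np.power(2.0, -dd)})


def filter_expressed(
    ct: pd.DataFrame,
    controls: list[str],
    max_undetected_fraction: float = 0.5,
    min_variance: float = 0.05,
) -> pd.DataFrame:
    """Drop lowly expressed and invariant miRNAs.

    Lowly expressed: undetected (Ct = 40) in more than the given fraction
    of samples.  Invariant: dCt variance below min_variance.  Control rows
    are always kept.  Idempotent and order-independent.
    """
    dct = delta_ct(ct, controls)
    undet = (ct.drop(index=controls) >= UNDETECTED_CT).mean(axis=1)
    var = dct.var(axis=1, ddof=1)
    keep = dct.index[(undet <= max_undetected_fraction) &
                     (var >= min_variance)]
    return ct.loc[list(controls) + list(keep)]


def differential_mirna(
    ct: pd.DataFrame,
    controls: list[str],
    sample_donor: dict[str, str],
    sample_condition: dict[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired t-test on per-donor dCt, vHMEC vs HMEC.

    Requires >= 2 donors with both conditions; reports raw p (the primary
    significance call) alongside BH-adjusted p and the ddCt fold change.
    """
    dct = delta_ct(ct, controls)
    donors = sorted({d for d in sample_donor.values()})
    pairs = []
    for donor in donors:
        ref = [s for s in dct.columns
               if sample_donor.get(s) == donor
               and sample_condition.get(s) == "HMEC"]
        tgt = [s for s in dct.columns
               if sample_donor.get(s) == donor
               and sample_condition.get(s) == "vHMEC"]
        if ref and tgt:
            pairs.append((donor, ref, tgt))
    if len(pairs) < 2:
        raise ValueError("paired test needs >= 2 donors with both conditions")
    ref_mat = np.column_stack([
        dct[ref].mean(axis=1).to_numpy() for _, ref, _ in pairs
    ])
    tgt_mat = np.column_stack([
        dct[tgt].mean(axis=1).to_numpy() for _, _, tgt in pairs
    ])
    diffs = tgt_mat - ref_mat
    stat, p = sps.ttest_rel(tgt_mat, ref_mat, axis=1)
    p = np.where(np.isfinite(p), p, 1.0)
    dd = diffs.mean(axis=1)
    from .stats import bh_adjust

    return pd.DataFrame({
        "statistic": np.where(np.isfinite(stat), stat, 0.0),
        "p": p,
        "padj": bh_adjust(p),
        "ddct": dd,
        "fold": np.power(2.0, -dd),
        "significant": p < alpha,
    }, index=dct.index)


def intersect_targets(
    silenced_mirnas: list[str],
    predictions: list[TargetPrediction],
    upregulated_genes: list[str],
    mirsvr_max: float = -0.5,
) -> tuple[list[tuple[str, str]], list[str]]:
    """Silenced-miRNA targets among up-regulated genes.

    Predicted entries require mirSVR strictly below the cut-off; validated
    entries pass regardless.  Returns the (miRNA, gene) interaction list
    and the unique-gene collapse, both deterministically ordered.
    """
    silenced = set(silenced_mirnas)
    up = set(upregulated_genes)
    interactions = []
    for pred in predictions:
        if pred.mirna not in silenced or pred.gene not in up:
            continue
        if pred.source == "predicted" and not pred.mirsvr < mirsvr_max:
            continue
        interactions.append((pred.mirna, pred.gene))
    interactions = sorted(set(interactions))
    genes = sorted({g for _, g in interactions})
    return interactions, genes


def read_predictions(path) -> list[TargetPrediction]:
    """Read a prediction TSV: mirna, gene, source, mirsvr (blank if n/a)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        score = row.get("mirsvr", math.nan)
        out.append(TargetPrediction(
            str(row["mirna"]), str(row["gene"]), str(row["source"]),
            float(score) if pd.notna(score) else math.nan,
        ))
    return out
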