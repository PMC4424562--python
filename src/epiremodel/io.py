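"""Readers and writers for the plain-text formats the pipeline touches.

BED intervals keep their native 0-based half-open coordinates; the
refFlat-like gene table is treated as 1-based inclusive in txStart and is
converted to the internal 0-based half-open convention on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .intervals import GenomicInterval, IntervalSet


class ParseError(ValueError):
    """A malformed line in an input file; carries the line number."""


@dataclass(frozen=True)
class GeneModel:
    """A gene with its span and transcription start site.

    tss == interval.start on the + strand, interval.end - 1 on the - strand.
    """

    gene_id: str
    interval: GenomicInterval
    strand: str

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1


@dataclass
class SampleSheet:
    """Sample metadata: donor, condition, time point and tumour labels.

    Columns: sample_id, donor, condition (HMEC/vHMEC), timepoint
    (NA/early/late), group (tumour/normal/NA), subtype (basal/other/NA).
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id",)
    OPTIONAL = ("donor", "condition", "timepoint", "group", "subtype")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"sample sheet missing column {col!r}")
        if self.table["sample_id"].duplicated().any():
            dup = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample ids: {sorted(set(dup))}")
        for col in self.OPTIONAL:
            if col not in self.table.columns:
                self.table[col] = "NA"
        self.table = self.table.reset_index(drop=True)

    def ids(self, **where: str) -> list[str]:
        """Sample ids matching all given column=value filters."""
        mask = pd.Series(True, index=self.table.index)
        for col, val in where.items():
            mask &= self.table[col] == val
        return list(self.table.loc[mask, "sample_id"])

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def read(cls, path: str | Path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def read_bed(path: str | Path) -> IntervalSet:
    """Read a BED file into a sorted IntervalSet (labels from column 4)."""
    intervals: list[GenomicInterval] = []
    labels: list[str] = []
    any_label = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields"
                )
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            try:
                strand = parts[5] if len(parts) > 5 else "."
                intervals.append(GenomicInterval(parts[0], start, end, strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if len(parts) > 3:
                any_label = True
                labels.append(parts[3])
            else:
                labels.append("")
    return IntervalSet(intervals, labels if any_label else None)


def write_bed(ivset: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(ivset):
            name = ivset.labels[i] if ivset.labels is not None else None
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if name is not None:
                fields += [name, "0", iv.strand]
            fh.write("\t".join(fields) + "\n")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read a refFlat-like TSV: gene_id, chrom, strand, txStart, txEnd.

    txStart/txEnd are 1-based inclusive in the file and converted to 0-based
    half-open here.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene_id"):
            raise ParseError(f"{path}:1: expected header starting with gene_id")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ParseError(f"{path}:{lineno}: expected 5 fields")
            gene_id, chrom, strand, tx_start, tx_end = parts[:5]
            try:
                iv = GenomicInterval(chrom, int(tx_start) - 1, int(tx_end), strand)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            genes.append(GeneModel(gene_id, iv, strand))
    return genes


def write_gene_models(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttxStart\ttxEnd\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.interval.chrom}\t{g.strand}\t"
                f"{g.interval.start + 1}\t{g.interval.end}\n"
            )


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature-by-sample TSV matrix (first column = feature id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name, description, genes...; sets keep order."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 fields")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def write_json_report(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
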