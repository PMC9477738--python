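"""Readers and writers for the interval, sequence and table formats the pipeline touches.

Every record is normalized at the boundary to one internal coordinate
convention: 0-based, half-open intervals on named chromosomes.  GFF3 (1-based,
closed) is converted on read; BED-family coordinates pass through verbatim.
Sequences are uppercased on read so downstream motif scanning is
case-insensitive by construction.  Chromosome names are taken verbatim — no
"chr" normalization is attempted.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "ParseError",
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "CountMatrix",
    "DEGTable",
    "read_peaks",
    "write_peaks",
    "read_genes",
    "write_genes",
    "read_fasta",
    "write_fasta",
    "read_count_matrix",
    "write_count_matrix",
    "read_deg_table",
    "write_deg_table",
]


class ParseError(ValueError):
    """A malformed record; carries the offending file and line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        where = ""
        if path is not None:
            where += f"{path}"
        if line is not None:
            where += f":{line}"
        super().__init__(f"{where}: {message}" if where else message)
        self.path = path
        self.line = line


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with an optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Peak:
    """A binding-evidence interval with an occupancy score.

    ``score`` is the binding-strength axis used when stratifying peaks by
    motif content; ``summit_offset``, when present, is measured from
    ``interval.start``.
    """

    id: str
    interval: GenomicInterval
    summit_offset: int | None = None
    score: float = 0.0

    def __post_init__(self):
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < len(self.interval)
        ):
            raise ValueError(
                f"summit_offset {self.summit_offset} outside [0, {len(self.interval)})"
            )
        if self.score < 0:
            raise ValueError("score must be >= 0")

    @property
    def length(self) -> int:
        return len(self.interval)

    @property
    def center(self) -> int:
        return self.interval.start + self.length // 2

    def anchor(self, kind: str = "center") -> int:
        """Single-point position used for gene assignment and profiles."""
        if kind == "summit" and self.summit_offset is not None:
            return self.interval.start + self.summit_offset
        return self.center


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene interval anchoring TSS/TES-relative coordinates."""

    id: str
    interval: GenomicInterval

    def __post_init__(self):
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be + or -")

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1

    @property
    def tes(self) -> int:
        iv = self.interval
        return iv.end - 1 if iv.strand == "+" else iv.start


@dataclass
class CountMatrix:
    """Integer counts of rows (peaks or genes) across samples.

    ``condition_of`` maps every sample id to its condition label.
    """

    counts: pd.DataFrame  # index: row ids, columns: sample ids
    condition_of: dict[str, str]

    def __post_init__(self):
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate row ids")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        missing = [s for s in self.counts.columns if s not in self.condition_of]
        if missing:
            raise ValueError(f"samples without condition: {missing}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(np.equal(np.mod(vals, 1), 0)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be >= 0")

    @property
    def row_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.col_ids if self.condition_of[s] == condition]

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.col_ids:
            seen.setdefault(self.condition_of[s])
        return list(seen)


@dataclass
class DEGTable:
    """Per-gene differential-expression records (gene_id, log2fc, padj)."""

    records: pd.DataFrame

    def __post_init__(self):
        need = {"gene_id", "log2fc", "padj"}
        if not need.issubset(self.records.columns):
            raise ValueError(f"DEG table must have columns {sorted(need)}")
        if self.records["gene_id"].duplicated().any():
            raise ValueError("duplicate gene_id in DEG table")
        padj = self.records["padj"].to_numpy(dtype=float)
        if ((padj < 0) | (padj > 1)).any() or np.isnan(padj).any():
            raise ValueError("padj must lie in [0, 1]")


# ---------------------------------------------------------------------------
# BED6 / narrowPeak


def _parse_coords(fields, path, lineno):
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ParseError(f"non-integer coordinate: {exc}", path, lineno) from None
    if start < 0 or start >= end:
        raise ParseError(f"require 0 <= start < end, got {start}..{end}", path, lineno)
    return start, end


def read_peaks(path, dialect: str = "bed6") -> list[Peak]:
    """Read peaks from a BED6 or ENCODE narrowPeak (10-column) file.

    Coordinates are taken verbatim (BED is already 0-based half-open).  For
    narrowPeak, column 7 (signalValue) maps to the score and column 10 to the
    summit offset (-1 means absent); for BED6 column 5 is the score.  Peaks
    named "." get auto-generated ids ``peak_<n>``.
    """
    if dialect not in ("bed6", "narrowPeak"):
        raise ValueError(f"unknown dialect {dialect!r}")
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("fewer than 3 tab-separated fields", path, lineno)
            chrom = fields[0]
            start, end = _parse_coords(fields, path, lineno)
            name = fields[3] if len(fields) > 3 else "."
            if name == "." or name == "":
                name = f"peak_{len(peaks) + 1}"
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-", ".") else "."
            summit = None
            if dialect == "narrowPeak":
                if len(fields) < 10:
                    raise ParseError("narrowPeak needs 10 columns", path, lineno)
                try:
                    score = float(fields[6])
                    summit_raw = int(fields[9])
                except ValueError as exc:
                    raise ParseError(f"bad narrowPeak field: {exc}", path, lineno) from None
                summit = None if summit_raw == -1 else summit_raw
                if summit is not None and not (0 <= summit < end - start):
                    raise ParseError(
                        f"summit {summit} outside peak of length {end - start}",
                        path,
                        lineno,
                    )
            else:
                try:
                    score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
                except ValueError as exc:
                    raise ParseError(f"bad score: {exc}", path, lineno) from None
            if score < 0:
                raise ParseError(f"negative score {score}", path, lineno)
            peaks.append(
                Peak(
                    id=name,
                    interval=GenomicInterval(chrom, start, end, strand),
                    summit_offset=summit,
                    score=score,
                )
            )
    return peaks


def write_peaks(peaks: Iterable[Peak], path, dialect: str = "bed6") -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            if dialect == "bed6":
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.id}\t{p.score:g}\t{iv.strand}\n"
                )
            elif dialect == "narrowPeak":
                summit = -1 if p.summit_offset is None else p.summit_offset
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.id}\t0\t{iv.strand}"
                    f"\t{p.score:g}\t-1\t-1\t{summit}\n"
                )
            else:
                raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# GFF3 (gene features only)


def _gff_attributes(raw: str) -> dict[str, str]:
    out = {}
    for item in raw.split(";"):
        item = item.strip()
        if item and "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


def read_genes(path) -> list[GeneModel]:
    """Read gene features from GFF3; 1-based closed coordinates become
    0-based half-open.  Non-gene feature types are ignored."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError("GFF3 line with fewer than 9 columns", path, lineno)
            if fields[2] != "gene":
                continue
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(f"non-integer coordinate: {exc}", path, lineno) from None
            strand = fields[6]
            if strand not in ("+", "-"):
                raise ParseError(f"gene without usable strand ({strand!r})", path, lineno)
            attrs = _gff_attributes(fields[8])
            if "ID" not in attrs:
                raise ParseError("gene feature without ID attribute", path, lineno)
            if start1 < 1 or end1 < start1:
                raise ParseError(f"bad GFF coordinates {start1}..{end1}", path, lineno)
            genes.append(
                GeneModel(
                    id=attrs["ID"],
                    interval=GenomicInterval(fields[0], start1 - 1, end1, strand),
                )
            )
    return genes


def write_genes(genes: Iterable[GeneModel], path, source: str = "cobind") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}"
                f"\t.\tID={g.id}\n"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into a name -> uppercase-sequence map; duplicate headers error."""
    seqs: dict[str, str] = {}
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            name = header.split()[0]
            if name in seqs:
                raise ParseError(f"duplicate FASTA header {name!r}", path)
            seqs[name] = seq.upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# TSV tables

_CONDITION_PREFIX = "#conditions\t"


def read_count_matrix(path) -> CountMatrix:
    """Read a TSV count matrix whose first line is a ``#conditions`` map.

    Layout::

        #conditions<TAB>cond_a<TAB>cond_a<TAB>cond_b<TAB>cond_b
        peak_id<TAB>s1<TAB>s2<TAB>s3<TAB>s4
        peak_1<TAB>10<TAB>12<TAB>9<TAB>11
    """
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith(_CONDITION_PREFIX):
            raise ParseError("count matrix must start with a '#conditions' line", path, 1)
        conditions = first.split("\t")[1:]
        df = pd.read_csv(fh, sep="\t", index_col=0)
    if len(conditions) != df.shape[1]:
        raise ParseError(
            f"{len(conditions)} conditions for {df.shape[1]} sample columns", path, 1
        )
    if not all(np.issubdtype(dt, np.integer) for dt in df.dtypes):
        raise ParseError("counts must be integers", path)
    if (df.to_numpy() < 0).any():
        raise ParseError("counts must be >= 0", path)
    cond_of = dict(zip(df.columns, conditions))
    return CountMatrix(counts=df, condition_of=cond_of)


def write_count_matrix(cm: CountMatrix, path) -> None:
    with open(path, "w") as fh:
        conds = "\t".join(cm.condition_of[s] for s in cm.col_ids)
        fh.write(f"#conditions\t{conds}\n")
        buf = io.StringIO()
        cm.counts.to_csv(buf, sep="\t", index_label="id")
        fh.write(buf.getvalue())


def read_deg_table(path) -> DEGTable:
    df = pd.read_csv(path, sep="\t")
    need = {"gene_id", "log2fc", "padj"}
    if not need.issubset(df.columns):
        raise ParseError(f"DEG table must have columns {sorted(need)}", path, 1)
    try:
        return DEGTable(records=df[["gene_id", "log2fc", "padj"]].copy())
    except ValueError as exc:
        raise ParseError(str(exc), path) from None


def write_deg_table(table: DEGTable, path) -> None:
    table.records.to_csv(path, sep="\t", index=False)
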