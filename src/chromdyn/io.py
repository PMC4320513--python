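"""Readers and writers for the on-disk formats the pipeline touches.

Internally everything is 0-based half-open; 1-based closed conventions
(GTF) are converted at the parse/serialize boundary and nowhere else.
All writers emit rows ordered by (chromosome, start) so output files are
deterministic.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .bins import GenomeBins

__all__ = [
    "read_bedgraph_to_bins",
    "read_gene_annotation",
    "write_gene_annotation_bed",
    "write_gene_annotation_gtf",
    "write_segmentation_bed",
    "read_segmentation_bed",
    "read_expression",
    "write_expression",
    "validate_annotation",
    "validate_expression",
]

ANNOTATION_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]
DEFAULT_TIME_POINTS = ("D-2", "D0", "D3", "D9")


# ----------------------------------------------------------------------
# bedGraph
# ----------------------------------------------------------------------

def read_bedgraph_to_bins(
    path: str | Path,
    bins: GenomeBins,
    aggregation: str = "mean",
) -> np.ndarray:
    """Project a bedGraph track onto fixed-width genome bins.

    Parameters
    ----------
    path
        bedGraph file (``chrom  start  end  value``); ``track``/``#``
        lines are ignored. Intervals need not be sorted.
    bins
        Target binning.
    aggregation
        ``"sum"``   — each interval's value is apportioned to bins
        pro-rata by the fraction of the interval falling in the bin;
        ``"mean"``  — per-base mean signal over the bin (uncovered bases
        contribute 0);
        ``"max"``   — maximum value of any interval overlapping the bin.

    Returns
    -------
    numpy.ndarray
        Length ``bins.total_bins`` float array; bins with no coverage
        are 0.
    """
    if aggregation not in {"sum", "mean", "max"}:
        raise ValueError(f"aggregation must be sum, mean or max, got {aggregation!r}")
    values = np.zeros(bins.total_bins, dtype=float)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start_s, end_s, value_s = fields[:4]
            start, end, value = int(start_s), int(end_s), float(value_s)
            if chrom not in bins.chrom_names:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if end > bins.chrom_length(chrom):
                raise ValueError(
                    f"{path}:{lineno}: interval end {end} beyond {chrom} "
                    f"length {bins.chrom_length(chrom)}"
                )
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start must be < end")
            sl = bins.chrom_slice(chrom)
            first, last = bins.overlapping_bins(chrom, start, end)
            bw = bins.bin_width
            for b in range(first, last):
                lo, hi = b * bw, (b + 1) * bw
                overlap = min(end, hi) - max(start, lo)
                if overlap <= 0:
                    continue
                g = sl.start + b
                if aggregation == "sum":
                    values[g] += value * overlap / (end - start)
                elif aggregation == "mean":
                    values[g] += value * overlap / bw
                else:  # max
                    values[g] = max(values[g], value)
    return values


# ----------------------------------------------------------------------
# Gene annotation
# ----------------------------------------------------------------------

def read_gene_annotation(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read gene records from BED6 or GTF into the internal annotation frame.

    GTF coordinates (1-based, closed) are converted to 0-based half-open;
    only features of type ``gene`` are used. Returns a DataFrame with
    columns ``gene_id, chrom, start, end, strand`` sorted by
    (chrom, start, gene_id).
    """
    path = Path(path)
    if format is None:
        format = "gtf" if path.suffix.lower() in {".gtf", ".gff"} else "bed"
    format = format.lower()
    if format not in {"bed", "gtf"}:
        raise ValueError(f"format must be 'bed' or 'gtf', got {format!r}")
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                if format == "bed":
                    chrom, start_s, end_s, name = fields[:4]
                    strand = fields[5] if len(fields) > 5 else "+"
                    start, end = int(start_s), int(end_s)
                else:
                    if len(fields) < 9:
                        raise ValueError("fewer than 9 GTF columns")
                    chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields[:9]
                    if feature != "gene":
                        continue
                    # GTF is 1-based closed -> 0-based half-open
                    start, end = int(start_s) - 1, int(end_s)
                    name = _gtf_attribute(attrs, "gene_id")
                    if name is None:
                        raise ValueError("missing gene_id attribute")
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed line ({exc})") from None
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start must be < end")
            if strand not in {"+", "-"}:
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            records.append((name, chrom, start, end, strand))
    df = pd.DataFrame(records, columns=ANNOTATION_COLUMNS)
    return df.sort_values(["chrom", "start", "gene_id"], kind="stable").reset_index(drop=True)


def _gtf_attribute(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + " ") or part.startswith(key + "="):
            return part.split(None, 1)[1].strip().strip('"')
    return None


def write_gene_annotation_bed(annotation: pd.DataFrame, path: str | Path) -> None:
    """Write genes as BED6 (0-based half-open), sorted by (chrom, start)."""
    df = annotation.sort_values(["chrom", "start", "gene_id"], kind="stable")
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.gene_id}\t0\t{row.strand}\n")


def write_gene_annotation_gtf(annotation: pd.DataFrame, path: str | Path, source: str = "chromdyn") -> None:
    """Write genes as minimal GTF ``gene`` features (1-based closed)."""
    df = annotation.sort_values(["chrom", "start", "gene_id"], kind="stable")
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{source}\tgene\t{row.start + 1}\t{row.end}\t.\t{row.strand}\t.\t"
                f'gene_id "{row.gene_id}";\n'
            )


def validate_annotation(annotation: pd.DataFrame, bins: GenomeBins | None = None) -> None:
    """Raise ValueError on malformed annotation frames."""
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotation.columns]
    if missing:
        raise ValueError(f"annotation missing columns {missing}")
    if (annotation["start"] >= annotation["end"]).any():
        bad = annotation.loc[annotation["start"] >= annotation["end"], "gene_id"].tolist()
        raise ValueError(f"genes with start >= end: {bad}")
    if bins is not None:
        unknown = sorted(set(annotation["chrom"]) - set(bins.chrom_names))
        if unknown:
            raise ValueError(f"annotation references unknown chromosomes {unknown}")


# ----------------------------------------------------------------------
# Segmentation BED
# ----------------------------------------------------------------------

def write_segmentation_bed(bins: GenomeBins, labels: np.ndarray, path: str | Path) -> None:
    """Write a per-bin state labelling as a dense BED of merged state runs.

    Maximal runs of identical state become one BED line with name
    ``cs<state>``; coordinates cover exactly the binned extent of each
    chromosome.
    """
    labels = np.asarray(labels)
    if labels.shape != (bins.total_bins,):
        raise ValueError(
            f"labels shape {labels.shape} does not match total bins {bins.total_bins}"
        )
    try:
        with open(path, "w") as fh:
            for chrom in bins.chrom_names:
                sl = bins.chrom_slice(chrom)
                for start_bin, end_bin, state in _runs(labels[sl]):
                    fh.write(
                        f"{chrom}\t{start_bin * bins.bin_width}\t{end_bin * bins.bin_width}\tcs{state}\n"
                    )
    except OSError as exc:
        raise OSError(f"failed writing segmentation to {path}: {exc}") from exc


def _runs(arr: np.ndarray) -> Iterable[tuple[int, int, int]]:
    """Yield (start_bin, end_bin, value) for maximal constant runs."""
    if arr.size == 0:
        return
    change = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [arr.size]])
    for s, e in zip(starts, ends):
        yield int(s), int(e), int(arr[s])


def read_segmentation_bed(path: str | Path, bins: GenomeBins) -> np.ndarray:
    """Inverse of :func:`write_segmentation_bed`; returns per-bin labels."""
    labels = np.zeros(bins.total_bins, dtype=np.int64)
    seen = np.zeros(bins.total_bins, dtype=bool)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
                state = int(name.removeprefix("cs"))
            except (IndexError, ValueError):
                raise ValueError(f"{path}:{lineno}: malformed segmentation line") from None
            sl = bins.chrom_slice(chrom)
            first, last = bins.overlapping_bins(chrom, start, end)
            labels[sl.start + first : sl.start + last] = state
            seen[sl.start + first : sl.start + last] = True
    if not seen.all():
        raise ValueError(f"{path}: segmentation does not cover every bin")
    return labels


# ----------------------------------------------------------------------
# Expression tables
# ----------------------------------------------------------------------

def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a gene x time-point FPKM table (TSV, first column gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    validate_expression(df)
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


def validate_expression(expr: pd.DataFrame) -> None:
    if expr.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    if (expr.values < 0).any():
        raise ValueError("FPKM values must be non-negative")
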