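"""Readers and writers for the plain-text formats the pipeline touches.

Formats: tab-separated expression matrices (genes in rows), SEG segmented
copy number, BED gene coordinates, a TSV clinical table, and GMT gene-set
collections.  All readers preserve input order; writers round-trip through
the matching reader.

Coordinate conventions: SEG is read as 1-based inclusive (UCSC dialect);
BED is read as 0-based half-open and converted to 1-based inclusive
internally.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .types import (GeneModel, GeneSetCollection, OmicsMatrix, SegmentedCNA,
                    SurvivalTable)

logger = logging.getLogger(__name__)


# -- expression matrices -----------------------------------------------------

def read_expression_matrix(path, omics_kind: str = "expression",
                           normalized: str = "raw") -> OmicsMatrix:
    """Read a genes-in-rows TSV matrix: first column feature ids, header
    row of sample ids."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
    if not header.strip():
        raise FormatError(f"{path}: empty file or missing header")
    fields = header.rstrip("\n").split("\t")
    if len(fields) < 2:
        raise FormatError(f"{path}: header has no sample columns")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate feature ids {dups[:10]}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        values = np.empty(df.shape)
        for j, col in enumerate(df.columns):
            for i, cell in enumerate(df[col]):
                try:
                    values[i, j] = float(cell)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"{path}: non-numeric value {cell!r} at "
                        f"row {df.index[i]!r}, column {col!r}") from None
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValidationError(
            f"{path}: missing value at row {df.index[i]!r}, column {df.columns[j]!r}; "
            "missing expression values are rejected, not imputed")
    return OmicsMatrix(list(df.index.astype(str)), list(df.columns.astype(str)),
                       values, omics_kind=omics_kind, normalized=normalized)


def write_expression_matrix(m: OmicsMatrix, path) -> None:
    m.to_frame().to_csv(path, sep="\t", index_label="feature_id",
                        float_format="%.17g")


# -- SEG ---------------------------------------------------------------------

_SEG_MIN_COLS = 5


def read_seg(path, scale: str = "log2ratio") -> list[SegmentedCNA]:
    """Read a SEG file (sample, chrom, start, end, [num_probes,] seg_mean).

    ``scale="absolute"`` converts absolute copy numbers to the
    log2(CN) − 1 scale; the default assumes means are already on it.
    """
    if scale not in ("log2ratio", "absolute"):
        raise ValueError("scale must be 'log2ratio' or 'absolute'")
    path = Path(path)
    records: list[SegmentedCNA] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and not _is_number(fields[2] if len(fields) > 2 else ""):
                continue  # header line
            if len(fields) < _SEG_MIN_COLS:
                raise FormatError(f"{path}:{lineno}: expected >= {_SEG_MIN_COLS} columns")
            sample, chrom, start_s, end_s = fields[0], fields[1], fields[2], fields[3]
            mean_s = fields[5] if len(fields) >= 6 else fields[4]
            try:
                start, end = int(float(start_s)), int(float(end_s))
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            try:
                mean = float(mean_s)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric segment mean {mean_s!r}") from None
            if scale == "absolute":
                if mean <= 0:
                    raise ValidationError(f"{path}:{lineno}: absolute copy number must be > 0")
                mean = float(np.log2(mean) - 1.0)
            records.append(SegmentedCNA(sample, chrom, start, end, mean))
    return records


def write_seg(records: Iterable[SegmentedCNA], path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample\tchrom\tstart\tend\tnum_probes\tseg_mean\n")
        for r in records:
            fh.write(f"{r.sample_id}\t{r.chrom}\t{r.start}\t{r.end}\t"
                     f"{max(1, (r.end - r.start + 1) // 1000)}\t{r.segment_mean:.17g}\n")


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


# -- clinical ----------------------------------------------------------------

def read_clinical(path) -> SurvivalTable:
    """Read a TSV clinical table with columns
    sample_id, efs_time, efs_event, os_time, os_event."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", *SurvivalTable.COLUMNS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if df.empty:
        logger.warning("%s: clinical table has a header but no rows", path)
        return SurvivalTable(pd.DataFrame(
            columns=list(SurvivalTable.COLUMNS),
            index=pd.Index([], name="sample_id", dtype=str)))
    try:
        num = df[list(SurvivalTable.COLUMNS)].astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric clinical value ({exc})") from None
    num.index = df["sample_id"].astype(str)
    return SurvivalTable(num)


def write_clinical(surv: SurvivalTable, path) -> None:
    out = surv.data.copy()
    out[["efs_event", "os_event"]] = out[["efs_event", "os_event"]].astype(int)
    out.to_csv(path, sep="\t", index_label="sample_id", float_format="%.17g")


# -- BED gene models ---------------------------------------------------------

def read_gene_bed(path) -> list[GeneModel]:
    """Read gene coordinates from BED (0-based half-open); converted to
    1-based inclusive.  Columns: chrom, start, end, name[, score, strand]."""
    path = Path(path)
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: BED needs >= 4 columns (incl. name)")
            chrom, start_s, end_s, name = fields[:4]
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                start0, end0 = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if name in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate gene id {name!r}")
            seen.add(name)
            genes.append(GeneModel(name, chrom, start0 + 1, end0, strand))
    return genes


def write_gene_bed(genes: Iterable[GeneModel], path) -> None:
    with Path(path).open("w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# -- GMT ---------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file: name, description, then gene ids.
    Duplicate genes within a set are dropped (first occurrence kept)."""
    path = Path(path)
    sets: dict[str, tuple[str, list[str]]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            sets[name] = (desc, genes)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with Path(path).open("w") as fh:
        for name, (desc, genes) in collection.sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


# -- labels ------------------------------------------------------------------

def read_labels(path) -> pd.Series:
    """Read a two-column TSV (sample_id, subtype) into a Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or "subtype" not in df.columns:
        raise FormatError(f"{path}: expected columns sample_id, subtype")
    return df.set_index("sample_id")["subtype"]


def write_labels(sample_ids, labels, path) -> None:
    pd.DataFrame({"sample_id": list(sample_ids), "subtype": list(labels)}).to_csv(
        path, sep="\t", index=False)
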