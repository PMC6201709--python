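"""Core in-memory containers for the pipeline.

The pipeline moves three kinds of data around: feature-by-sample omics
matrices (:class:`OmicsMatrix`), right-censored survival endpoints
(:class:`SurvivalTable`), and genomic interval records (segmented copy
number and gene models).  Everything downstream — normalisation,
autoencoder integration, clustering, classification — consumes these.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

OMICS_KINDS = ("expression", "cna")
#: ``raw`` — as read; ``log2`` — floored/log2 FPKM; ``zscore`` — per-gene
#: standardised; ``log2cn`` — log2(copy number) − 1 (0 = diploid).
NORMALIZATION_STATES = ("raw", "log2", "zscore", "log2cn")


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({i for i in ids if i in seen or seen.add(i)})
        raise ValidationError(f"duplicate {what}: {dups[:10]}")


@dataclass
class OmicsMatrix:
    """A features-by-samples real matrix for one omics layer.

    Parameters
    ----------
    feature_ids
        Row labels (genes); must be unique.
    sample_ids
        Column labels; must be unique.
    values
        Real matrix of shape ``(len(feature_ids), len(sample_ids))``.
    omics_kind
        ``"expression"`` or ``"cna"``.
    normalized
        One of :data:`NORMALIZATION_STATES`.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    omics_kind: str = "expression"
    normalized: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        _check_unique(self.feature_ids, "feature ids")
        _check_unique(self.sample_ids, "sample ids")
        if self.omics_kind not in OMICS_KINDS:
            raise ValidationError(f"unknown omics_kind {self.omics_kind!r}")
        if self.normalized not in NORMALIZATION_STATES:
            raise ValidationError(f"unknown normalization state {self.normalized!r}")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, omics_kind: str = "expression",
                   normalized: str = "raw", **meta) -> "OmicsMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float),
                   omics_kind=omics_kind, normalized=normalized, meta=dict(meta))

    def subset_features(self, feature_ids: Sequence[str]) -> "OmicsMatrix":
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in idx]
        if missing:
            raise ValidationError(f"unknown features: {missing[:10]}")
        rows = [idx[f] for f in feature_ids]
        return dataclasses.replace(self, feature_ids=list(feature_ids),
                                   values=self.values[rows, :])

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise ValidationError(f"unknown samples: {missing[:10]}")
        cols = [idx[s] for s in sample_ids]
        return dataclasses.replace(self, sample_ids=list(sample_ids),
                                   values=self.values[:, cols])


@dataclass
class SurvivalTable:
    """Per-sample event-free (EFS) and overall (OS) survival endpoints.

    Times are in days; event indicators are 1 = event observed,
    0 = right-censored.
    """

    data: pd.DataFrame  # index sample_id; columns efs_time, efs_event, os_time, os_event

    COLUMNS = ("efs_time", "efs_event", "os_time", "os_event")

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"clinical table missing columns: {missing}")
        df = df.loc[:, list(self.COLUMNS)].astype(float)
        df.index = df.index.astype(str)
        if df.index.has_duplicates:
            raise ValidationError("duplicate sample ids in clinical table")
        if (df[["efs_time", "os_time"]] < 0).any().any():
            raise ValidationError("negative survival time")
        for c in ("efs_event", "os_event"):
            if not df[c].isin([0.0, 1.0]).all():
                raise ValidationError(f"{c} values must be in {{0,1}}")
        self.data = df

    @classmethod
    def from_records(cls, sample_ids: Sequence[str], efs_time, efs_event,
                     os_time, os_event) -> "SurvivalTable":
        return cls(pd.DataFrame(
            {"efs_time": efs_time, "efs_event": efs_event,
             "os_time": os_time, "os_event": os_event},
            index=[str(s) for s in sample_ids]))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)

    def endpoint(self, name: str, sample_ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Return (time, event) arrays for endpoint ``"efs"`` or ``"os"``
        aligned to ``sample_ids``; raises if any sample is missing."""
        if name not in ("efs", "os"):
            raise ValueError("endpoint must be 'efs' or 'os'")
        ids = [str(s) for s in sample_ids]
        missing = [s for s in ids if s not in self.data.index]
        if missing:
            raise ValidationError(f"samples without clinical data: {missing[:10]}")
        sub = self.data.loc[ids]
        return sub[f"{name}_time"].to_numpy(), sub[f"{name}_event"].to_numpy().astype(int)


@dataclass
class SegmentedCNA:
    """One segmented copy-number call (SEG line), 1-based inclusive,
    segment mean on the log2(copy number) − 1 scale."""

    sample_id: str
    chrom: str
    start: int
    end: int
    segment_mean: float

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("empty chromosome name")
        if self.start > self.end:
            raise ValidationError(
                f"segment start {self.start} > end {self.end} ({self.sample_id} {self.chrom})")


@dataclass
class GeneModel:
    """Gene body coordinates, 1-based inclusive."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"gene {self.gene_id}: start > end")
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. the 50 hallmark sets) for enrichment."""

    sets: dict[str, tuple[str, list[str]]]

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def genes(self, name: str) -> set[str]:
        return set(self.sets[name][1])

    def names(self) -> list[str]:
        return list(self.sets)
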