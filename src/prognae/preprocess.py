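"""Per-layer normalisation, segment-to-gene mapping, univariate Cox
screening, and stacking of omics layers into the integration input.

FPKM handling follows a floor-then-log rule: the smallest nonzero value is
found per sample; everything below the largest of those per-sample minima
is replaced by the smallest of them, after which values are log2
transformed.  This removes zeros without adding an arbitrary pseudocount.
Expression is then standardised per gene (population SD).  CNA segments
are summarised per gene as the overlap-length-weighted mean of segment
means on the log2(copy number) - 1 scale.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import defaultdict
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .survival import cox_score_screen
from .types import GeneModel, OmicsMatrix, SegmentedCNA, SurvivalTable

logger = logging.getLogger(__name__)


def fpkm_floor_bounds(m: OmicsMatrix) -> tuple[float, float]:
    """Return (L, U): the min and max over samples of each sample's
    smallest nonzero value.  Recomputed from the data, never assumed."""
    if (m.values < 0).any():
        raise ValidationError("FPKM values must be nonnegative")
    mins = []
    for j, sid in enumerate(m.sample_ids):
        col = m.values[:, j]
        nz = col[col > 0]
        if nz.size == 0:
            raise ValidationError(f"sample {sid!r} is all zero; nonzero minimum undefined")
        mins.append(nz.min())
    return float(min(mins)), float(max(mins))


def floor_log_fpkm(m: OmicsMatrix) -> OmicsMatrix:
    """Floor sub-threshold FPKM values and log2-transform.

    Every value below U (the largest per-sample nonzero minimum) is set to
    L (the smallest), so no zeros survive the log.  The bounds used are
    recorded in ``meta["fpkm_floor"]``.
    """
    if m.omics_kind != "expression" or m.normalized != "raw":
        raise ValidationError("floor_log_fpkm expects a raw expression matrix")
    low, high = fpkm_floor_bounds(m)
    values = m.values.copy()
    values[values < high] = low
    values = np.log2(values)
    meta = dict(m.meta, fpkm_floor={"L": low, "U": high})
    return dataclasses.replace(m, values=values, normalized="log2", meta=meta)


def zscore_by_gene(m: OmicsMatrix) -> OmicsMatrix:
    """Standardise each feature to mean 0, SD 1 (population SD, n
    denominator).  Constant features become all-zero with a warning."""
    if m.normalized == "zscore":
        raise ValidationError("matrix is already z-scored")
    mean = m.values.mean(axis=1, keepdims=True)
    sd = m.values.std(axis=1, keepdims=True)  # population SD
    constant = (sd[:, 0] == 0)
    if constant.any():
        logger.warning("%d constant feature(s) set to all-zero during z-scoring",
                       int(constant.sum()))
    safe_sd = np.where(sd == 0, 1.0, sd)
    values = (m.values - mean) / safe_sd
    values[constant, :] = 0.0
    meta = dict(m.meta, zscore_sd="population")
    return dataclasses.replace(m, values=values, normalized="zscore", meta=meta)


def cna_gene_matrix(segments: Sequence[SegmentedCNA], genes: Sequence[GeneModel],
                    samples: Sequence[str]) -> OmicsMatrix:
    """Summarise segmented copy number per gene and sample.

    A gene's value is the mean of the segment means of every segment
    overlapping the gene body, weighted by overlap length in bp.  Genes
    with no overlapping segment are 0 (diploid on the log2(CN) - 1 scale).
    Segments on chromosomes absent from the gene annotation are skipped
    with a warning.
    """
    if not genes:
        raise ValidationError("empty gene list")
    samples = [str(s) for s in samples]
    sample_idx = {s: j for j, s in enumerate(samples)}
    gene_ids = [g.gene_id for g in genes]
    if len(set(gene_ids)) != len(gene_ids):
        raise ValidationError("duplicate gene ids in annotation")
    by_chrom: dict[str, list[tuple[int, GeneModel]]] = defaultdict(list)
    for i, g in enumerate(genes):
        by_chrom[g.chrom].append((i, g))
    known_chroms = set(by_chrom)

    weight = np.zeros((len(genes), len(samples)))
    wsum = np.zeros_like(weight)
    skipped_chroms: set[str] = set()
    for seg in segments:
        if seg.sample_id not in sample_idx:
            continue
        if seg.chrom not in known_chroms:
            skipped_chroms.add(seg.chrom)
            continue
        j = sample_idx[seg.sample_id]
        for i, g in by_chrom[seg.chrom]:
            ov = min(seg.end, g.end) - max(seg.start, g.start) + 1
            if ov > 0:
                weight[i, j] += ov
                wsum[i, j] += ov * seg.segment_mean
    if skipped_chroms:
        logger.warning("segments on unknown chromosome(s) skipped: %s",
                       sorted(skipped_chroms))
    with np.errstate(invalid="ignore"):
        values = np.where(weight > 0, wsum / np.where(weight > 0, weight, 1.0), 0.0)
    return OmicsMatrix(gene_ids, samples, values, omics_kind="cna",
                       normalized="log2cn")


def cox_screen_features(m: OmicsMatrix, surv: SurvivalTable,
                        alpha: float = 0.05) -> tuple[OmicsMatrix, pd.DataFrame]:
    """Keep features whose univariate Cox score test has p < alpha for
    event-free OR overall survival.

    Returns the restricted matrix and a per-feature report with both
    p-values and the kept flag.  An endpoint with fewer than two events is
    skipped with a warning (its p-values become NaN).
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    report = pd.DataFrame(index=pd.Index(m.feature_ids, name="feature_id"))
    any_endpoint = False
    for endpoint in ("efs", "os"):
        time, event = surv.endpoint(endpoint, m.sample_ids)
        if event.sum() < 2:
            logger.warning("endpoint %s has < 2 events; skipped in screening", endpoint)
            report[f"p_{endpoint}"] = np.nan
            continue
        _, p = cox_score_screen(m.values, time, event)
        report[f"p_{endpoint}"] = p
        any_endpoint = True
    if not any_endpoint:
        raise ValidationError("no endpoint with >= 2 events; cannot screen")
    kept = ((report["p_efs"] < alpha) | (report["p_os"] < alpha)).fillna(False)
    report["kept"] = kept.to_numpy()
    selected = [f for f, k in zip(m.feature_ids, report["kept"]) if k]
    return m.subset_features(selected), report


def stack_omics(expr: OmicsMatrix, cna: OmicsMatrix) -> OmicsMatrix:
    """Stack expression over CNA on the samples both layers share.

    Feature ids are prefixed ``GE:`` / ``CNA:`` so a gene present in both
    layers stays unique; expression sample order is preserved.
    """
    shared = [s for s in expr.sample_ids if s in set(cna.sample_ids)]
    if len(shared) < 2:
        raise ValidationError(
            f"layers share only {len(shared)} sample(s); need >= 2")
    e = expr.subset_samples(shared)
    c = cna.subset_samples(shared)
    feature_ids = [f"GE:{f}" for f in e.feature_ids] + [f"CNA:{f}" for f in c.feature_ids]
    values = np.vstack([e.values, c.values])
    meta = {"n_expression": e.n_features, "n_cna": c.n_features,
            "row_provenance": ["expression"] * e.n_features + ["cna"] * c.n_features}
    return OmicsMatrix(feature_ids, shared, values, omics_kind="expression",
                       normalized="zscore", meta=meta)
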