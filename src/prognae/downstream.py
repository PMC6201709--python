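"""Differential expression between subtypes and gene-set
overrepresentation analysis.

Differential expression uses the two-sided equal-variance Student t-test
per gene with Benjamini–Hochberg FDR; genes called in two cohorts are
intersected requiring a consistent direction.  Overrepresentation is an
exact hypergeometric tail test of a hit list against each gene set,
restricted to the tested universe.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .subtype import SubtypeAssignment
from .survival import bh_fdr
from .types import GeneSetCollection, OmicsMatrix

logger = logging.getLogger(__name__)


def ttest_de(m: OmicsMatrix, labels: SubtypeAssignment,
             fdr_cut: float = 0.05) -> pd.DataFrame:
    """Per-gene Student t-test (equal variance) between G1 and G2.

    Returns a table with columns t, p, fdr, direction (sign of
    mean(G1) - mean(G2); +1 = up in G1) and significant (fdr < fdr_cut).
    Genes with zero pooled variance get t = 0, p = 1 and are flagged.
    """
    lab = labels.as_series().reindex(m.sample_ids)
    if lab.isna().any():
        raise ValidationError("matrix contains samples without subtype labels")
    g1 = (lab == "G1").to_numpy()
    g2 = (lab == "G2").to_numpy()
    if g1.sum() < 2 or g2.sum() < 2:
        raise ValidationError("each subtype needs >= 2 samples for the t-test")
    a, b = m.values[:, g1], m.values[:, g2]
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    if degenerate.any():
        logger.warning("%d gene(s) with zero pooled variance: p set to 1",
                       int(degenerate.sum()))
    fdr = bh_fdr(p)
    direction = np.sign(a.mean(axis=1) - b.mean(axis=1)).astype(int)
    return pd.DataFrame(
        {"t": t, "p": p, "fdr": fdr, "direction": direction,
         "degenerate": degenerate, "significant": fdr < fdr_cut},
        index=pd.Index(m.feature_ids, name="gene"))


def intersect_de(de_train: pd.DataFrame, de_valid: pd.DataFrame,
                 fdr_cut: float = 0.05) -> tuple[set[str], set[str]]:
    """Genes significant in BOTH cohorts with the SAME direction,
    returned as (up-in-G1 set, down-in-G1 set)."""
    shared = de_train.index.intersection(de_valid.index)
    if shared.empty:
        raise ValidationError("the two DE tables share no genes")
    a = de_train.loc[shared]
    b = de_valid.loc[shared]
    sig = (a["fdr"] < fdr_cut) & (b["fdr"] < fdr_cut) & \
        (a["direction"] == b["direction"]) & (a["direction"] != 0)
    up = set(shared[sig & (a["direction"] > 0)])
    down = set(shared[sig & (a["direction"] < 0)])
    return up, down


def ora_hypergeometric(gene_set: set[str], hits: set[str],
                       universe: set[str]) -> tuple[int, float, float]:
    """Exact hypergeometric overrepresentation test.

    Returns (overlap count, one-sided p = P(X >= overlap), enrichment
    ratio observed/expected).  The gene set is intersected with the
    universe before testing; hits must be a subset of the universe.
    """
    if not hits:
        raise ValidationError("empty hit list")
    universe = set(universe)
    hits = set(hits)
    if not hits <= universe:
        raise ValidationError("hits must be a subset of the universe")
    in_universe = set(gene_set) & universe
    overlap = len(in_universe & hits)
    M, n, N = len(universe), len(in_universe), len(hits)
    if n == 0:
        return 0, 1.0, 0.0
    p = float(stats.hypergeom.sf(overlap - 1, M, n, N))
    expected = n * N / M
    ratio = overlap / expected if expected > 0 else 0.0
    return overlap, p, float(ratio)


def ora_collection(collection: GeneSetCollection, hits: set[str],
                   universe: set[str]) -> pd.DataFrame:
    """Run the hypergeometric test for every set in a collection and
    adjust across sets with Benjamini–Hochberg."""
    rows = []
    for name in collection.names():
        desc = collection.sets[name][0]
        overlap, p, ratio = ora_hypergeometric(collection.genes(name), hits, universe)
        rows.append({"set": name, "description": desc, "overlap": overlap,
                     "p": p, "enrichment_ratio": ratio})
    table = pd.DataFrame(rows).set_index("set")
    table["fdr"] = bh_fdr(table["p"].to_numpy())
    return table.sort_values("p")
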