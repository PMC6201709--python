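"""K-means subtyping of the selected latent features.

The number of clusters is chosen over a candidate range by three
criteria — Harrell's C-index of the cluster-derived risk ranking against
event-free survival, mean silhouette width, and the Calinski–Harabasz
score — combined by majority vote with the C-index criterion breaking
ties.  For k = 2 the worse-prognosis cluster (lower restricted-mean
event-free survival) is relabelled G1, the other G2.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from .autoencoder import LatentMatrix
from .errors import ValidationError
from .survival import concordance_index, logrank_two_group, restricted_mean_survival
from .types import SurvivalTable

logger = logging.getLogger(__name__)


@dataclass
class SubtypeAssignment:
    """Per-sample subtype labels with the k-selection metrics."""

    sample_ids: list[str]
    labels: np.ndarray  # strings "G1".."Gk"
    k: int
    seed: int
    metrics: pd.DataFrame | None = None  # one row per candidate k

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.labels) != len(self.sample_ids):
            raise ValidationError("labels must cover all samples")
        if self.k < 2:
            raise ValidationError("k must be >= 2")

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.sample_ids, name="subtype")

    def binary(self, positive: str = "G1") -> np.ndarray:
        return (self.labels == positive).astype(int)


def _features(latent: LatentMatrix) -> np.ndarray:
    X = latent.selected_values() if latent.selected.any() else latent.values
    if X.shape[1] == 0:
        raise ValidationError("no latent features to cluster")
    return X


def kmeans_cluster(latent: LatentMatrix, k: int, seed: int = 0,
                   n_restarts: int = 50) -> SubtypeAssignment:
    """Lloyd's algorithm with k-means++ seeding, best of ``n_restarts``
    by within-cluster sum of squares; deterministic given the seed."""
    X = _features(latent)
    n = X.shape[0]
    if not 2 <= k <= n:
        raise ValidationError(f"k must be in [2, {n}]")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(X)
    labels = np.array([f"G{c + 1}" for c in km.labels_], dtype=object)
    return SubtypeAssignment(list(latent.sample_ids), labels, k, seed)


def cluster_risk_scores(assign: SubtypeAssignment, surv: SurvivalTable) -> np.ndarray:
    """Risk score per sample: clusters ranked by restricted-mean
    event-free survival, worst prognosis = highest risk.  For k = 2 this
    is the G1 = 1 / G2 = 0 coding once labels are oriented."""
    time, event = surv.endpoint("efs", assign.sample_ids)
    tau = float(time.max())
    rmst = {}
    for lab in np.unique(assign.labels):
        mask = assign.labels == lab
        rmst[lab] = restricted_mean_survival(time[mask], event[mask], tau)
    order = sorted(rmst, key=lambda L: rmst[L])  # worst first
    rank = {lab: len(order) - 1 - i for i, lab in enumerate(order)}  # worst = max
    return np.array([rank[lab] for lab in assign.labels], dtype=float)


def select_k(latent: LatentMatrix, surv: SurvivalTable,
             k_range=range(2, 7), seed: int = 0,
             n_restarts: int = 50) -> tuple[int, pd.DataFrame]:
    """Evaluate each candidate k and choose by majority vote of the three
    criteria (EFS C-index, silhouette, Calinski–Harabasz); ties are broken
    by the C-index criterion.  Returns (chosen k, metric table)."""
    X = _features(latent)
    rows = []
    assignments = {}
    for k in k_range:
        try:
            assign = kmeans_cluster(latent, k, seed=seed, n_restarts=n_restarts)
        except ValidationError as exc:
            logger.warning("k=%d infeasible: %s", k, exc)
            continue
        risk = cluster_risk_scores(assign, surv)
        row = {"k": k}
        for endpoint in ("efs", "os"):
            time, event = surv.endpoint(endpoint, assign.sample_ids)
            row[f"c_index_{endpoint}"] = concordance_index(risk, time, event).c_index
        codes = pd.factorize(assign.labels)[0]
        row["silhouette"] = float(silhouette_score(X, codes)) if len(set(codes)) > 1 else np.nan
        row["calinski_harabasz"] = float(calinski_harabasz_score(X, codes))
        rows.append(row)
        assignments[k] = assign
    if not rows:
        raise ValidationError("no feasible k in range")
    table = pd.DataFrame(rows).set_index("k")
    votes = [int(table["c_index_efs"].idxmax()),
             int(table["silhouette"].idxmax()),
             int(table["calinski_harabasz"].idxmax())]
    counts = pd.Series(votes).value_counts()
    if counts.iloc[0] > 1:
        chosen = int(counts.index[0])
    else:
        chosen = votes[0]  # C-index criterion breaks the tie
    return chosen, table


def orient_labels(assign: SubtypeAssignment, surv: SurvivalTable) -> SubtypeAssignment:
    """For k = 2, relabel so that G1 is the worse-prognosis cluster
    (lower restricted-mean event-free survival).  Exactly equal prognosis
    falls back deterministically (first cluster label = G1) with a warning."""
    if assign.k != 2:
        raise ValidationError("orientation is defined for k = 2")
    time, event = surv.endpoint("efs", assign.sample_ids)
    tau = float(time.max())
    labs = sorted(set(assign.labels))
    rmst = {lab: restricted_mean_survival(time[assign.labels == lab],
                                          event[assign.labels == lab], tau)
            for lab in labs}
    if rmst[labs[0]] == rmst[labs[1]]:
        logger.warning("clusters have identical restricted-mean survival; "
                       "labelling the first cluster G1 by convention")
        worse = labs[0]
    else:
        worse = min(labs, key=lambda L: rmst[L])
    mapping = {worse: "G1", [L for L in labs if L != worse][0]: "G2"}
    new_labels = np.array([mapping[L] for L in assign.labels], dtype=object)
    return dataclasses.replace(assign, labels=new_labels)


def subtype_logrank(assign: SubtypeAssignment, surv: SurvivalTable,
                    endpoint: str = "efs"):
    """Two-group log-rank between G1 and G2 on the requested endpoint."""
    time, event = surv.endpoint(endpoint, assign.sample_ids)
    return logrank_two_group(assign.binary(), time, event)
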