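"""Synthetic multi-omics cohorts with planted prognostic subtypes.

The generator mirrors the study topology the pipeline expects: a training
cohort with paired expression and copy-number data, an internal
validation cohort with copy number only, an external validation cohort
with expression only, two latent subtypes with divergent survival, and
independent right-censoring.

Generative model: each sample belongs to subtype G1 (high risk) or G2.
Expression is unit Gaussian noise; a fraction of genes is informative and
shifted by +/- ``latent_separation`` SD in G1.  Copy-number features live
on the log2(copy number) - 1 scale with the same construction scaled by
``cna_signal_scale``.  EFS and OS times are exponential with the G1
hazard multiplied by ``hazard_ratio_g1``; censoring times are independent
exponentials with the rate calibrated so the expected censored fraction
equals ``censor_rate``.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import ValidationError
from .types import GeneModel, OmicsMatrix, SegmentedCNA, SurvivalTable


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic cohorts.

    Defaults mirror the cohort sizes of the motivating study design
    (190 paired training samples, 190 CNA-only internal validation
    samples, 176 expression-only external validation samples).
    """

    n_train: int = 190
    n_internal_cna: int = 190
    n_external_expr: int = 176
    n_genes_expr: int = 2000
    n_genes_cna: int = 500
    frac_informative: float = 0.05
    #: fraction of informative CNA genes that are also informative in expression
    informative_overlap: float = 0.5
    subtype_prevalence: float = 0.5
    latent_separation: float = 3.0  # SD units, expression
    cna_signal_scale: float = 0.5   # relative to expression signal
    hazard_ratio_g1: float = 4.0
    baseline_median_survival: float = 1500.0  # days, G2
    censor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_train", "n_internal_cna", "n_external_expr",
                     "n_genes_expr", "n_genes_cna"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        for name in ("frac_informative", "subtype_prevalence", "censor_rate"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must be in (0, 1)")
        if self.hazard_ratio_g1 <= 0:
            raise ValidationError("hazard_ratio_g1 must be > 0")


@dataclass
class SimulatedStudy:
    """All cohorts produced by :func:`simulate_cohorts`."""

    train_expr: OmicsMatrix
    train_cna: OmicsMatrix
    internal_cna: OmicsMatrix
    external_expr: OmicsMatrix
    clinical: SurvivalTable
    true_labels: dict[str, str]  # sample id -> "G1"/"G2"
    config: SimulationConfig
    informative_expr: list[str] = field(default_factory=list)
    informative_cna: list[str] = field(default_factory=list)
    effect_expr: dict[str, float] = field(default_factory=dict)
    effect_cna: dict[str, float] = field(default_factory=dict)

    def labels_for(self, sample_ids) -> np.ndarray:
        return np.array([self.true_labels[s] for s in sample_ids], dtype=object)


def censoring_rate_for(config: SimulationConfig) -> float:
    """Exponential censoring rate c solving
    sum_g P(g) * c / (lambda_g + c) = censor_rate."""
    lam2 = np.log(2.0) / config.baseline_median_survival
    lam1 = lam2 * config.hazard_ratio_g1
    w1 = config.subtype_prevalence
    target = config.censor_rate

    def censored_fraction(c):
        return w1 * c / (lam1 + c) + (1 - w1) * c / (lam2 + c) - target

    lo, hi = 1e-12 * lam2, 1e12 * lam2
    if censored_fraction(lo) > 0 or censored_fraction(hi) < 0:
        raise ValidationError("censoring calibration infeasible for this config")
    return float(brentq(censored_fraction, lo, hi))


def _draw_survival(rng, is_g1, config):
    lam2 = np.log(2.0) / config.baseline_median_survival
    rates = np.where(is_g1, lam2 * config.hazard_ratio_g1, lam2)
    c = censoring_rate_for(config)
    out = {}
    for endpoint in ("efs", "os"):
        t_event = rng.exponential(1.0 / rates)
        t_cens = rng.exponential(1.0 / c, size=len(rates))
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        out[f"{endpoint}_time"] = time
        out[f"{endpoint}_event"] = event
    return out


def _gene_ids(n: int, prefix: str = "G") -> list[str]:
    return [f"{prefix}{i:05d}" for i in range(1, n + 1)]


def _layer(rng, sample_ids, gene_ids, is_g1, effects: dict[str, float],
           omics_kind: str, normalized: str) -> OmicsMatrix:
    values = rng.normal(size=(len(gene_ids), len(sample_ids)))
    for g, eff in effects.items():
        i = gene_ids.index(g)
        values[i, is_g1] += eff
    return OmicsMatrix(list(gene_ids), list(sample_ids), values,
                       omics_kind=omics_kind, normalized=normalized)


def simulate_cohorts(config: SimulationConfig | None = None) -> SimulatedStudy:
    """Draw the four cohorts, clinical endpoints, and ground-truth labels.

    All cohorts share one set of generative parameters (gene effects,
    hazards), so labels learned on the training cohort are transferable
    to the validation cohorts by construction.
    """
    if config is None:
        config = SimulationConfig()
    rng = np.random.default_rng(config.seed)

    expr_genes = _gene_ids(config.n_genes_expr)
    # CNA genes are a subset of the expression namespace so layers overlap
    cna_genes = expr_genes[:config.n_genes_cna]

    n_inf_expr = max(1, round(config.frac_informative * config.n_genes_expr))
    n_inf_cna = max(1, round(config.frac_informative * config.n_genes_cna))
    n_shared = round(config.informative_overlap * n_inf_cna)
    # shared informative genes come from the CNA subset; the rest of the
    # expression signal lives outside it
    inf_cna = list(rng.choice(cna_genes, size=n_inf_cna, replace=False))
    shared = inf_cna[:n_shared]
    # remaining expression signal prefers genes outside the CNA subset;
    # tiny gene panels fall back to any unused gene id
    extra_pool = expr_genes[config.n_genes_cna:]
    if len(extra_pool) < n_inf_expr - n_shared:
        extra_pool = [g for g in expr_genes if g not in set(shared)]
    inf_expr = shared + list(
        rng.choice(extra_pool, size=n_inf_expr - n_shared, replace=False))

    sign_expr = rng.choice([-1.0, 1.0], size=len(inf_expr))
    sign_cna = rng.choice([-1.0, 1.0], size=len(inf_cna))
    effect_expr = {g: s * config.latent_separation for g, s in zip(inf_expr, sign_expr)}
    effect_cna = {g: s * config.latent_separation * config.cna_signal_scale
                  for g, s in zip(inf_cna, sign_cna)}

    cohorts = {
        "TR": config.n_train,
        "IV": config.n_internal_cna,
        "EV": config.n_external_expr,
    }
    sample_ids: dict[str, list[str]] = {}
    is_g1: dict[str, np.ndarray] = {}
    for code, n in cohorts.items():
        sample_ids[code] = [f"{code}{i:04d}" for i in range(1, n + 1)]
        is_g1[code] = rng.random(n) < config.subtype_prevalence

    # expression emulates already log-scale (RMA-like) data, so it is
    # marked "log2": it goes straight to per-gene z-scoring downstream
    train_expr = _layer(rng, sample_ids["TR"], expr_genes, is_g1["TR"],
                        effect_expr, "expression", "log2")
    train_cna = _layer(rng, sample_ids["TR"], cna_genes, is_g1["TR"],
                       effect_cna, "cna", "log2cn")
    internal_cna = _layer(rng, sample_ids["IV"], cna_genes, is_g1["IV"],
                          effect_cna, "cna", "log2cn")
    external_expr = _layer(rng, sample_ids["EV"], expr_genes, is_g1["EV"],
                           effect_expr, "expression", "log2")

    all_ids: list[str] = []
    all_g1: list[bool] = []
    for code in cohorts:
        all_ids.extend(sample_ids[code])
        all_g1.extend(bool(v) for v in is_g1[code])
    surv = _draw_survival(rng, np.array(all_g1), config)
    clinical = SurvivalTable.from_records(all_ids, surv["efs_time"],
                                          surv["efs_event"], surv["os_time"],
                                          surv["os_event"])
    true_labels = {s: ("G1" if g else "G2") for s, g in zip(all_ids, all_g1)}
    return SimulatedStudy(train_expr, train_cna, internal_cna, external_expr,
                          clinical, true_labels, config,
                          informative_expr=list(inf_expr),
                          informative_cna=list(inf_cna),
                          effect_expr=effect_expr, effect_cna=effect_cna)


def make_gene_models(gene_ids, genes_per_chrom: int = 100,
                     gene_length: int = 1000, gap: int = 1000) -> list[GeneModel]:
    """Lay genes out on synthetic chromosomes, non-overlapping, 1-based
    inclusive, ``gene_length`` bp each with ``gap`` bp between."""
    genes = []
    for i, gid in enumerate(gene_ids):
        chrom = f"chr{i // genes_per_chrom + 1}"
        offset = (i % genes_per_chrom) * (gene_length + gap)
        genes.append(GeneModel(gid, chrom, offset + 1, offset + gene_length, "+"))
    return genes


def segments_from_cna_matrix(cna: OmicsMatrix, genes: list[GeneModel]
                             ) -> list[SegmentedCNA]:
    """Emit SEG records that reconstruct ``cna`` exactly through the
    gene-level summarisation: one segment per (sample, gene), covering
    the gene body with the gene's value.  Requires every matrix gene to
    have a (non-overlapping) gene model."""
    by_id = {g.gene_id: g for g in genes}
    missing = [g for g in cna.feature_ids if g not in by_id]
    if missing:
        raise ValidationError(f"no gene model for: {missing[:10]}")
    records = []
    for j, sid in enumerate(cna.sample_ids):
        for i, gid in enumerate(cna.feature_ids):
            g = by_id[gid]
            records.append(SegmentedCNA(sid, g.chrom, g.start, g.end,
                                        float(cna.values[i, j])))
    return records
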