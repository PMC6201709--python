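"""Survival-analysis primitives: univariate Cox proportional hazards,
two-group log-rank test, Harrell's concordance index, the Kaplan–Meier
estimator, restricted-mean survival, and Benjamini–Hochberg FDR.

The Cox partial likelihood uses Breslow tie handling throughout; the
screening p-value is the score test at beta = 0, which for a dichotomous
covariate coincides with the log-rank chi-square when event times are
untied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

logger = logging.getLogger(__name__)

_COEF_CAP = 20.0  # |log HR| cap under monotone likelihood


@dataclass
class CoxFitResult:
    """Univariate proportional-hazards fit.

    ``coefficient`` is the log hazard ratio at the Breslow partial-likelihood
    maximum; ``p_value`` comes from the score test at beta = 0.
    """

    coefficient: float
    score_statistic: float
    p_value: float
    n_events: int
    converged: bool = True


@dataclass
class LogRankResult:
    chi_square: float
    p_value: float
    group_sizes: tuple[int, int]


@dataclass
class ConcordanceResult:
    c_index: float
    comparable_pairs: int
    concordant: float  # ties credited 0.5
    se: float


def _as_surv_arrays(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.shape != event.shape or time.ndim != 1:
        raise ValidationError("time and event must be 1-D arrays of equal length")
    if (time < 0).any():
        raise ValidationError("negative survival time")
    if not np.isin(event, [0, 1]).all():
        raise ValidationError("event indicators must be 0/1")
    return time, event


def _risk_suffix_sums(order_time, *arrays):
    """Suffix (reverse cumulative) sums over samples sorted by time
    ascending; index i gives the sum over the risk set {j : t_j >= t_i}
    when evaluated at the first index of each tied block."""
    return [np.cumsum(a[::-1])[::-1] for a in arrays]


def _cox_score_info(x_sorted, time_sorted, event_idx, block_start, beta):
    """Score U(beta) and information I(beta) of the Breslow partial
    likelihood, with risk sets shared across tied event times."""
    w = np.exp(beta * x_sorted)
    s0, s1, s2 = _risk_suffix_sums(time_sorted, w, w * x_sorted,
                                   w * x_sorted ** 2)
    pos = block_start[event_idx]
    mean = s1[pos] / s0[pos]
    var = s2[pos] / s0[pos] - mean ** 2
    loglik = float(np.sum(beta * x_sorted[event_idx] - np.log(s0[pos])))
    return float(np.sum(x_sorted[event_idx] - mean)), float(np.sum(var)), loglik


def _sorted_blocks(time):
    """Sort order by time ascending plus, per position, the first index of
    its tied-time block (so suffix sums give true >= risk sets)."""
    order = np.argsort(time, kind="stable")
    t = time[order]
    block_start = np.zeros(len(t), dtype=int)
    for i in range(1, len(t)):
        block_start[i] = block_start[i - 1] if t[i] == t[i - 1] else i
    return order, t, block_start


def cox_univariate(x, time, event, tol: float = 1e-8, max_iter: int = 50) -> CoxFitResult:
    """Fit a univariate Cox model by Newton–Raphson on the Breslow partial
    likelihood and report the score-test p-value.

    A covariate with no variation yields coefficient 0 and p = 1.  Monotone
    likelihood (perfect separation) caps the coefficient with a warning;
    non-convergence is flagged and p is set to 1.
    """
    x = np.asarray(x, dtype=float)
    time, event = _as_surv_arrays(time, event)
    if x.shape != time.shape:
        raise ValidationError("covariate length mismatch")
    n_events = int(event.sum())
    if n_events < 1:
        raise ValidationError("need at least one event")
    if np.ptp(x) == 0:
        return CoxFitResult(0.0, 0.0, 1.0, n_events)

    order, t_sorted, block_start = _sorted_blocks(time)
    x_sorted = x[order]
    event_idx = np.flatnonzero(event[order] == 1)

    u0, i0, _ = _cox_score_info(x_sorted, t_sorted, event_idx, block_start, 0.0)
    if i0 <= 0:
        return CoxFitResult(0.0, 0.0, 1.0, n_events)
    score_stat = u0 ** 2 / i0
    p = float(stats.chi2.sf(score_stat, df=1))

    beta, converged, capped = 0.0, False, False
    for _ in range(max_iter):
        u, info, _ = _cox_score_info(x_sorted, t_sorted, event_idx, block_start, beta)
        if info <= 0:
            break
        step = u / info
        beta += step
        if abs(beta) > _COEF_CAP:
            beta = float(np.sign(beta) * _COEF_CAP)
            capped = True
            converged = True
            break
        if abs(step) < tol:
            converged = True
            break
    if capped:
        warnings.warn("monotone partial likelihood: coefficient capped", stacklevel=2)
    if not converged:
        warnings.warn("Cox Newton-Raphson did not converge; p set to 1", stacklevel=2)
        return CoxFitResult(float(beta), score_stat, 1.0, n_events, converged=False)
    return CoxFitResult(float(beta), score_stat, p, n_events)


def cox_score_screen(X, time, event):
    """Vectorised Cox score test at beta = 0 for every row of ``X``
    (features x samples).  Returns (chi-square statistics, p-values).

    This is the screening workhorse: only the score statistic is needed,
    which requires no iteration and one pass of suffix sums per call.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    time, event = _as_surv_arrays(time, event)
    if X.shape[1] != len(time):
        raise ValidationError("matrix columns must match sample count")
    order, t_sorted, block_start = _sorted_blocks(time)
    Xs = X[:, order]
    event_idx = np.flatnonzero(event[order] == 1)
    pos = block_start[event_idx]
    # at beta=0 the risk weights are 1: suffix counts and sums of x, x^2
    n = Xs.shape[1]
    s0 = np.arange(n, 0, -1.0)                       # |{j: t_j >= t_i}|
    s1 = np.cumsum(Xs[:, ::-1], axis=1)[:, ::-1]
    s2 = np.cumsum((Xs ** 2)[:, ::-1], axis=1)[:, ::-1]
    mean = s1[:, pos] / s0[pos]
    var = s2[:, pos] / s0[pos] - mean ** 2
    u = np.sum(Xs[:, event_idx] - mean, axis=1)
    info = np.sum(var, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(info > 1e-12, u ** 2 / info, 0.0)
    p = stats.chi2.sf(chi2, df=1)
    p = np.where(info > 1e-12, p, 1.0)
    return chi2, p


def logrank_two_group(labels, time, event) -> LogRankResult:
    """Mantel–Haenszel two-group log-rank test (1 df).

    ``labels`` is any binary grouping; the chi-square uses the standard
    hypergeometric variance at each distinct event time.
    """
    labels = np.asarray(labels)
    time, event = _as_surv_arrays(time, event)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValidationError(f"need exactly 2 non-empty groups, got {len(groups)}")
    g1 = labels == groups[1]
    n1_total, n0_total = int(g1.sum()), int((~g1).sum())

    event_times = np.unique(time[event == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = time >= t
        n_j = at_risk.sum()
        n1_j = (at_risk & g1).sum()
        d_j = ((time == t) & (event == 1)).sum()
        d1_j = ((time == t) & (event == 1) & g1).sum()
        o_minus_e += d1_j - d_j * n1_j / n_j
        if n_j > 1:
            var += d_j * (n1_j / n_j) * (1 - n1_j / n_j) * (n_j - d_j) / (n_j - 1)
    if var <= 0:
        return LogRankResult(0.0, 1.0, (n0_total, n1_total))
    chi2 = o_minus_e ** 2 / var
    return LogRankResult(float(chi2), float(stats.chi2.sf(chi2, df=1)),
                         (n0_total, n1_total))


def concordance_index(risk_score, time, event) -> ConcordanceResult:
    """Harrell's C over comparable pairs.

    A pair is comparable iff the member with the smaller time has an
    event; tied risk scores earn 0.5.  The standard error is the Noether
    approximation sqrt(C(1-C)/N_comparable).
    """
    risk = np.asarray(risk_score, dtype=float)
    time, event = _as_surv_arrays(time, event)
    if risk.shape != time.shape:
        raise ValidationError("risk score length mismatch")
    # pair (i,j) ordered so that t_i < t_j and e_i == 1
    ti, tj = time[:, None], time[None, :]
    ei = event[:, None]
    comparable = (ti < tj) & (ei == 1)
    ri, rj = risk[:, None], risk[None, :]
    concordant = np.where(ri > rj, 1.0, np.where(ri == rj, 0.5, 0.0))
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise ValidationError("no comparable pairs")
    n_conc = float(concordant[comparable].sum())
    c = n_conc / n_comp
    se = float(np.sqrt(max(c * (1 - c), 0.0) / n_comp))
    return ConcordanceResult(float(c), n_comp, n_conc, se)


def km_curve(time, event):
    """Kaplan–Meier product-limit estimate.

    Returns an array of shape (k, 2): distinct event times and the
    survival probability just after each, beginning at S(0) = 1.
    """
    time, event = _as_surv_arrays(time, event)
    if len(time) == 0:
        raise ValidationError("empty sample")
    event_times = np.unique(time[event == 1])
    surv = 1.0
    rows = [(0.0, 1.0)]
    for t in event_times:
        n_at_risk = (time >= t).sum()
        d = ((time == t) & (event == 1)).sum()
        surv *= 1.0 - d / n_at_risk
        rows.append((float(t), float(surv)))
    return np.array(rows)


def restricted_mean_survival(time, event, tau: float | None = None) -> float:
    """Area under the KM curve up to ``tau`` (default: last observed time)."""
    time, event = _as_surv_arrays(time, event)
    if tau is None:
        tau = float(time.max())
    curve = km_curve(time, event)
    ts = np.append(curve[:, 0], tau)
    area = 0.0
    for i in range(len(curve)):
        left, right = ts[i], min(ts[i + 1], tau)
        if right > left:
            area += curve[i, 1] * (right - left)
        if ts[i + 1] >= tau:
            break
    return float(area)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
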