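"""Predictive-accuracy model comparison: WAIC and PSIS-LOO.

Both criteria operate on a draws x observations matrix of pointwise
log-likelihoods (one observation = one consumer, both tracers jointly) and
are reported on the deviance scale (lower is better). PSIS-LOO smooths the
upper tail of the importance ratios with a generalized Pareto distribution
fitted by the Zhang-Stephens empirical-Bayes method.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from isomix.isodata import InvalidInputError, Period

logger = logging.getLogger(__name__)

PARETO_K_WARN = 0.7


@dataclass(frozen=True)
class ModelScore:
    model_label: str
    period: Period
    looic: float
    looic_se: float
    waic: float
    waic_se: float
    delta_looic: float = math.nan
    delta_waic: float = math.nan
    pareto_k_warnings: int = 0
    error_term: str = ""


def _check_loglik(loglik: np.ndarray) -> np.ndarray:
    ll = np.asarray(loglik, dtype=float)
    if ll.ndim != 2:
        raise InvalidInputError("pointwise log-likelihood must be draws x consumers")
    bad = np.flatnonzero(~np.all(np.isfinite(ll), axis=0))
    if bad.size:
        raise InvalidInputError(
            f"non-finite log-likelihood for consumer index(es) {bad.tolist()}"
        )
    return ll


def waic(loglik_pointwise: np.ndarray) -> tuple[float, float, float]:
    """Widely applicable information criterion.

    Returns (waic, se, p_waic) with waic = -2 (lppd - p_waic); the pointwise
    variance penalty uses the n-1 denominator; se is on the deviance scale,
    sqrt(n * var_i) of the pointwise -2(lppd_i - p_i) contributions.
    """
    ll = _check_loglik(loglik_pointwise)
    s, n = ll.shape
    if s < 2:
        raise InvalidInputError("need at least 2 draws")
    lppd_i = logsumexp(ll, axis=0) - math.log(s)
    p_i = ll.var(axis=0, ddof=1)
    elpd_i = lppd_i - p_i
    pointwise = -2.0 * elpd_i
    value = float(pointwise.sum())
    se = float(math.sqrt(n * pointwise.var(ddof=1))) if n > 1 else 0.0
    return value, se, float(p_i.sum())


def gpd_fit(x: np.ndarray) -> tuple[float, float]:
    """Zhang-Stephens empirical-Bayes fit of a generalized Pareto shape/scale
    to exceedances ``x`` (> 0). Returns (k, sigma) in the scipy ``genpareto``
    shape convention, with the weak shape-regularizing prior used by common
    reference implementations."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n < 5 or x[-1] <= 0:
        raise InvalidInputError("need >= 5 positive exceedances")
    prior_bs = 3.0
    m = 30 + int(math.sqrt(n))
    j = np.arange(1, m + 1)
    b = 1.0 / x[-1] + (1.0 - np.sqrt(m / (j - 0.5))) / (
        prior_bs * x[int(n / 4 + 0.5) - 1]
    )
    # profile log-likelihood over the reparameterized b = -xi/sigma;
    # xi_hat(b) = mean(log1p(-b x)) is the scipy genpareto shape
    xi_b = np.mean(np.log1p(-b[:, None] * x[None, :]), axis=1)
    log_lik = n * (np.log(-b / xi_b) - xi_b - 1.0)
    log_lik -= log_lik.max()
    weights = np.exp(log_lik)
    weights /= weights.sum()
    keep = weights > 10 * np.finfo(float).eps
    weights, b = weights[keep], b[keep]
    weights /= weights.sum()
    b_post = float(np.sum(b * weights))
    k = float(np.mean(np.log1p(-b_post * x)))  # scipy genpareto shape
    sigma = -k / b_post
    k = (n * k + 5.0) / (n + 10.0)  # shrink toward 0.5 (weak prior)
    return k, float(sigma)


def _gpd_quantile(p: np.ndarray, k: float, sigma: float) -> np.ndarray:
    if abs(k) < 1e-12:
        return -sigma * np.log1p(-p)
    return sigma / k * ((1.0 - p) ** (-k) - 1.0)


def smooth_log_weights(log_ratios: np.ndarray) -> tuple[np.ndarray, float]:
    """Pareto-smooth one observation's log importance ratios.

    Returns normalized log weights and the fitted Pareto k (inf when the
    tail could not be fitted, nan when too few draws for smoothing)."""
    lw = np.asarray(log_ratios, dtype=float)
    s = lw.size
    lw = lw - lw.max()
    tail_len = int(min(math.ceil(0.2 * s), 3 * math.sqrt(s)))
    khat = math.nan
    if tail_len >= 5:
        order = np.argsort(lw)
        tail_ids = order[s - tail_len :]
        cutoff = lw[order[s - tail_len - 1]]
        exceed = np.exp(lw[tail_ids]) - math.exp(cutoff)
        if np.ptp(exceed) <= 0:
            logger.info("degenerate equal tail weights: plain importance sampling used")
            khat = math.inf
        else:
            try:
                khat, sigma = gpd_fit(exceed)
            except InvalidInputError:
                khat = math.inf
            if math.isfinite(khat):
                probs = (np.arange(1, tail_len + 1) - 0.5) / tail_len
                smoothed = np.log(
                    _gpd_quantile(probs, khat, sigma) + math.exp(cutoff)
                )
                # ascending order of the original tail values
                lw[tail_ids[np.argsort(lw[tail_ids], kind="stable")]] = np.sort(smoothed)
    lw = np.minimum(lw, 0.0)
    return lw - logsumexp(lw), khat


def psis_loo(loglik_pointwise: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Pareto-smoothed importance-sampling leave-one-out cross-validation.

    Returns (looic, se, pareto_k per consumer); looic = -2 sum_i elpd_i with
    elpd_i the smoothed-importance-weighted leave-one-out log predictive
    density of consumer i.
    """
    ll = _check_loglik(loglik_pointwise)
    s, n = ll.shape
    if s < 100:
        logger.warning("only %d draws: PSIS-LOO is unreliable below ~100", s)
    elpd = np.empty(n)
    ks = np.empty(n)
    for i in range(n):
        logw, khat = smooth_log_weights(-ll[:, i])
        elpd[i] = logsumexp(logw + ll[:, i])
        ks[i] = khat
    pointwise = -2.0 * elpd
    looic = float(pointwise.sum())
    se = float(math.sqrt(n * pointwise.var(ddof=1))) if n > 1 else 0.0
    n_bad = int(np.sum(ks[np.isfinite(ks)] > PARETO_K_WARN))
    if n_bad:
        logger.warning("%d consumer(s) with Pareto k > %.1f", n_bad, PARETO_K_WARN)
    return looic, se, ks


def score_model(
    model_label: str,
    period: Period,
    loglik_pointwise: np.ndarray,
    error_term: str = "",
) -> ModelScore:
    """Convenience wrapper computing both criteria for one fitted model."""
    w, w_se, _ = waic(loglik_pointwise)
    l, l_se, ks = psis_loo(loglik_pointwise)
    return ModelScore(
        model_label=model_label,
        period=Period(period),
        looic=l,
        looic_se=l_se,
        waic=w,
        waic_se=w_se,
        pareto_k_warnings=int(np.sum(ks[np.isfinite(ks)] > PARETO_K_WARN)),
        error_term=error_term,
    )


def rank_models(scores: Sequence[ModelScore]) -> pd.DataFrame:
    """Per-period ranking with deltas relative to the best (lowest) criterion.

    Stable sort by looic then waic within period; input order does not
    affect the result beyond tie ordering by label.
    """
    if not scores:
        raise InvalidInputError("no model scores given")
    rows = []
    by_period: dict[Period, list[ModelScore]] = {}
    for sc in scores:
        by_period.setdefault(sc.period, []).append(sc)
    for period in sorted(by_period, key=lambda p: p.value):
        group = sorted(
            by_period[period], key=lambda sc: (sc.looic, sc.waic, sc.model_label)
        )
        best_loo = min(sc.looic for sc in group)
        best_waic = min(sc.waic for sc in group)
        for sc in group:
            rows.append(
                {
                    "model": sc.model_label,
                    "period": period.value,
                    "looic": sc.looic,
                    "looic_se": sc.looic_se,
                    "delta_looic": sc.looic - best_loo,
                    "waic": sc.waic,
                    "waic_se": sc.waic_se,
                    "delta_waic": sc.waic - best_waic,
                    "pareto_k_warnings": sc.pareto_k_warnings,
                    "error_term": sc.error_term,
                }
            )
    return pd.DataFrame(rows)
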