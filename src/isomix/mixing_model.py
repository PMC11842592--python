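"""Bayesian concentration-dependent stable-isotope mixing model.

Diet proportions live on the K-simplex and are given a Dirichlet prior;
covariate structure (fixed class/year effects with sum-to-zero coding and
an individual random effect) acts additively in isometric log-ratio (ILR)
coordinates. The tracer likelihood is Normal with a concentration-weighted
mixture mean and a process variance that may be scaled by a per-tracer
multiplicative error term.

Sampling uses adaptive random-walk Metropolis-within-Gibbs over the
unconstrained parameters (ILR coordinates, log random-effect SD, log error
multipliers) with several chains and split-chain R-hat diagnostics.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.spatial import Delaunay, QhullError

from isomix.isodata import (
    DEFAULT_TDF,
    InvalidInputError,
    IsotopeSample,
    SourceSummary,
    TDFSpec,
)

logger = logging.getLogger(__name__)

LOG_2PI = math.log(2.0 * math.pi)


class DesignError(ValueError):
    """Raised when consumers lack covariates required by the model."""


class FixedEffect(str, enum.Enum):
    CLASS = "class"
    YEAR = "year"
    CLASS_X_YEAR = "class_x_year"


class ErrorStructure(str, enum.Enum):
    RESIDUAL_X_PROCESS = "residual_x_process"
    PROCESS_ONLY = "process_only"


# ---------------------------------------------------------------------------
# ILR machinery


def ilr_basis(k: int) -> np.ndarray:
    """Orthonormal Helmert-type ILR basis as a (K-1, K) matrix of CLR
    coefficients: coordinate i contrasts the geometric mean of the first i
    parts against part i+1."""
    if k < 2:
        raise InvalidInputError("need at least 2 parts")
    basis = np.zeros((k - 1, k))
    for i in range(1, k):
        scale = math.sqrt(i / (i + 1.0))
        basis[i - 1, :i] = scale / i
        basis[i - 1, i] = -scale
    return basis


def ilr_transform(p: np.ndarray) -> np.ndarray:
    """Map simplex composition(s) to ILR coordinates. Accepts (K,) or (n, K)."""
    p = np.asarray(p, dtype=float)
    squeeze = p.ndim == 1
    p2 = np.atleast_2d(p)
    if np.any(p2 <= 0):
        raise InvalidInputError("composition must be strictly positive")
    if not np.allclose(p2.sum(axis=1), 1.0, atol=1e-8):
        raise InvalidInputError("composition must sum to 1")
    z = np.log(p2) @ ilr_basis(p2.shape[1]).T
    return z[0] if squeeze else z


def ilr_inverse(z: np.ndarray, k: int | None = None) -> np.ndarray:
    """Inverse ILR: coordinates back to the simplex. Accepts (K-1,) or (n, K-1)."""
    z = np.asarray(z, dtype=float)
    squeeze = z.ndim == 1
    z2 = np.atleast_2d(z)
    k = z2.shape[1] + 1 if k is None else k
    logp = z2 @ ilr_basis(k)
    logp -= logp.max(axis=1, keepdims=True)  # overflow guard
    p = np.exp(logp)
    p /= p.sum(axis=1, keepdims=True)
    return p[0] if squeeze else p


# ---------------------------------------------------------------------------
# Model specification


@dataclass(frozen=True)
class MixingModelSpec:
    """Sources, TDF, covariate structure, error structure and prior."""

    sources: tuple[SourceSummary, ...]
    tdf: TDFSpec = DEFAULT_TDF
    fixed_effect: FixedEffect | None = None
    random_individual: bool = False
    error_structure: ErrorStructure = ErrorStructure.RESIDUAL_X_PROCESS
    prior_alpha: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sources", tuple(self.sources))
        if len(self.sources) < 2:
            raise InvalidInputError("need at least 2 sources")
        alpha = (
            np.ones(len(self.sources))
            if self.prior_alpha is None
            else np.asarray(self.prior_alpha, dtype=float)
        )
        if alpha.shape != (len(self.sources),) or np.any(alpha <= 0):
            raise InvalidInputError("prior_alpha must be positive, length K")
        object.__setattr__(self, "prior_alpha", alpha)
        if (
            self.random_individual
            and self.fixed_effect is None
            and self.error_structure is not ErrorStructure.PROCESS_ONLY
        ):
            raise InvalidInputError(
                "individual-only model must use process_only error"
            )

    @property
    def k(self) -> int:
        return len(self.sources)

    @property
    def source_labels(self) -> tuple[str, ...]:
        return tuple(s.group_label for s in self.sources)


def _source_arrays(sources: Sequence[SourceSummary], tdf: TDFSpec):
    mean = np.array([s.mean for s in sources])  # (K, 2)
    var = np.array([s.sd for s in sources]) ** 2 + tdf.sd**2
    conc = np.array([s.conc for s in sources])
    shifted = mean + tdf.mean
    return shifted, var, conc


def mixture_moments(
    p: np.ndarray, sources: Sequence[SourceSummary], tdf: TDFSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Concentration-weighted mixture mean and process variance per tracer.

    For tracer j: w_k = p_k c_kj / sum_m p_m c_mj, mean = sum_k w_k
    (mu_kj + tdf_j), variance = sum_k w_k^2 (sd_kj^2 + tdf_sd_j^2).
    """
    shifted, var, conc = _source_arrays(sources, tdf)
    mu, v = _moments_batch(np.atleast_2d(np.asarray(p, dtype=float)), shifted, var, conc)
    if np.asarray(p).ndim == 1:
        return mu[0], v[0]
    return mu, v


def _moments_batch(p: np.ndarray, shifted: np.ndarray, var: np.ndarray, conc: np.ndarray):
    """Vectorized moments: p (n, K) -> mean (n, 2), variance (n, 2)."""
    w_num = p[:, :, None] * conc[None, :, :]  # (n, K, 2)
    denom = w_num.sum(axis=1, keepdims=True)
    if np.any(denom <= 0):
        raise InvalidInputError("zero total elemental concentration")
    w = w_num / denom
    mu = np.einsum("nkj,kj->nj", w, shifted)
    v = np.einsum("nkj,kj->nj", w**2, var)
    return mu, v


def log_likelihood(
    consumer: IsotopeSample,
    p: np.ndarray,
    spec: MixingModelSpec,
    error_mult: np.ndarray | None = None,
) -> float:
    """Log-density of one consumer's two tracers given its diet."""
    xi = np.ones(2) if error_mult is None else np.asarray(error_mult, dtype=float)
    if np.any(xi <= 0):
        raise InvalidInputError("error multipliers must be positive")
    if spec.error_structure is ErrorStructure.PROCESS_ONLY and not np.allclose(xi, 1.0):
        raise InvalidInputError("process_only error forces xi = 1")
    y = consumer.tracers
    if not np.all(np.isfinite(y)):
        raise InvalidInputError(f"non-finite tracer values for {consumer.sample_id!r}")
    mu, v = mixture_moments(p, spec.sources, spec.tdf)
    total_var = v * xi
    return float(np.sum(-0.5 * (LOG_2PI + np.log(total_var) + (y - mu) ** 2 / total_var)))


# ---------------------------------------------------------------------------
# Posterior container and diagnostics


@dataclass
class PosteriorDraws:
    """Pooled post-warmup MCMC output."""

    p: np.ndarray  # (draws, n_consumers, K)
    global_p: np.ndarray  # (draws, K)
    loglik_pointwise: np.ndarray  # (draws, n_consumers)
    chains: int
    rhat: dict[str, float]
    converged: bool
    consumer_ids: tuple[str, ...]
    source_labels: tuple[str, ...]
    random_sd: np.ndarray | None = None  # (draws,)
    error_mult: np.ndarray | None = None  # (draws, 2)
    fixed_levels: tuple | None = None
    level_p: np.ndarray | None = None  # (draws, L, K) composition per level

    def __post_init__(self) -> None:
        sums = self.p.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise InvalidInputError("posterior diet draws must lie on the simplex")


def rhat(chains_draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor (Gelman-Rubin)."""
    x = np.asarray(chains_draws, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 4:
        raise InvalidInputError("need >= 2 chains and >= 4 iterations")
    n_half = x.shape[1] // 2
    halves = np.concatenate([x[:, :n_half], x[:, n_half : 2 * n_half]], axis=0)
    m, n = halves.shape
    chain_means = halves.mean(axis=1)
    w = halves.var(axis=1, ddof=1).mean()
    if w <= 0:
        logger.warning("zero within-chain variance; R-hat undefined")
        return math.nan
    b = n * chain_means.var(ddof=1)
    var_hat = (n - 1) / n * w + b / n
    return float(math.sqrt(var_hat / w))


# ---------------------------------------------------------------------------
# Covariate design


def _fixed_levels(consumers: Sequence[IsotopeSample], effect: FixedEffect):
    if effect is FixedEffect.CLASS:
        vals = [c.sex_age_class for c in consumers]
        if any(v is None for v in vals):
            raise DesignError("consumers lack sex/age class required by the model")
        levels = sorted({v for v in vals}, key=lambda v: v.value)
    elif effect is FixedEffect.YEAR:
        vals = [c.year for c in consumers]
        levels = sorted(set(vals))
    else:
        vals = [(c.sex_age_class, c.year) for c in consumers]
        if any(v[0] is None for v in vals):
            raise DesignError("consumers lack sex/age class required by the model")
        levels = sorted(set(vals), key=lambda v: (v[0].value, v[1]))
    index = {lv: i for i, lv in enumerate(levels)}
    return tuple(levels), np.array([index[v] for v in vals])


# ---------------------------------------------------------------------------
# Sampler

_PRIOR_BETA_SD = 1.0  # weakly-informative Normal on fixed-effect ILR offsets
_PRIOR_SIGMA_SCALE = 2.0  # half-Normal scale for the random-effect SD
_TARGET_ACC = {"scalar": 0.44, "block": 0.30}


class _State:
    __slots__ = ("theta", "u", "log_sigma", "log_xi")


def fit(
    spec: MixingModelSpec,
    consumers: Sequence[IsotopeSample],
    chains: int = 3,
    iterations: int = 1000,
    warmup: int = 1000,
    seed: int = 0,
    polygon_check: bool = False,
    polygon_iter: int = 500,
    rhat_threshold: float = 1.05,
) -> PosteriorDraws:
    """Sample the posterior by adaptive Metropolis-within-Gibbs.

    Consumer-level ILR coordinates are global + sum-to-zero fixed-effect
    offset + Normal(0, sigma_ind) individual effect. Internally the fixed
    effect is sampled as per-level ILR coordinates (the likelihood then
    factorizes across levels, which mixes far better than updating the
    global mean and offsets separately); the global composition - the mean
    of the level coordinates - carries the Dirichlet prior and the centered
    offsets carry the Normal fixed-effect prior. sigma_ind is half-Normal,
    error multipliers half-Cauchy. Non-convergence (any split R-hat >=
    ``rhat_threshold``) is flagged, never silently accepted.
    """
    consumers = list(consumers)
    n = len(consumers)
    if n < 2:
        raise DesignError("need at least 2 consumers")
    if chains < 2:
        raise DesignError("need at least 2 chains for split R-hat")
    k = spec.k
    alpha = spec.prior_alpha
    y = np.array([c.tracers for c in consumers])  # (n, 2)
    shifted, svar, conc = _source_arrays(spec.sources, spec.tdf)

    if polygon_check:
        probs = mixing_polygon_check(
            consumers, spec.sources, spec.tdf, n_iter=polygon_iter, seed=seed
        )
        bad = [cid for cid, pr in probs.items() if pr < 0.05]
        if bad:
            logger.warning("consumers outside the mixing polygon (p < 0.05): %s", bad)

    has_fixed = spec.fixed_effect is not None
    if has_fixed:
        levels, level_idx = _fixed_levels(consumers, spec.fixed_effect)
        n_levels = len(levels)
        if n_levels < 2:
            raise DesignError("fixed effect has a single level")
    else:
        levels = None
        level_idx = np.zeros(n, dtype=int)
        n_levels = 1
    has_random = spec.random_individual
    has_xi = spec.error_structure is ErrorStructure.RESIDUAL_X_PROCESS
    level_members = [np.flatnonzero(level_idx == l) for l in range(n_levels)]

    def pointwise_loglik(zc: np.ndarray, xi: np.ndarray):
        """Per-consumer log-likelihood given consumer ILR matrix (n, K-1)."""
        p = ilr_inverse(zc, k)
        mu, v = _moments_batch(p, shifted, svar, conc)
        tv = v * xi
        ll = np.sum(-0.5 * (LOG_2PI + np.log(tv) + (y - mu) ** 2 / tv), axis=1)
        return ll, p, mu, v

    def consumer_ilr(theta, u):
        zc = theta[level_idx]
        if has_random:
            zc = zc + u
        return zc

    def log_prior_theta(theta: np.ndarray) -> float:
        # Dirichlet(alpha) on the global (level-mean) composition, including
        # the ILR Jacobian: up to a constant, sum_k alpha_k * log p_k; plus
        # Normal(0, sd) on the centered per-level offsets when present.
        z = theta.mean(axis=0)
        p = ilr_inverse(z, k)
        lp = float(np.sum(alpha * np.log(p)))
        if n_levels > 1:
            offsets = theta - z
            lp -= 0.5 * float(np.sum(offsets**2)) / _PRIOR_BETA_SD**2
        return lp

    draws_p = []
    draws_global = []
    draws_ll = []
    draws_sigma = []
    draws_xi = []
    draws_level_p = []
    monitor: dict[str, list[np.ndarray]] = {}

    for chain in range(chains):
        rng = np.random.default_rng(seed + 1000 * chain)
        st = _State()
        st.theta = 0.5 * rng.standard_normal(k - 1) + 0.2 * rng.standard_normal(
            (n_levels, k - 1)
        )
        st.u = np.zeros((n, k - 1)) if has_random else None
        st.log_sigma = math.log(0.5) + 0.2 * rng.standard_normal() if has_random else None
        st.log_xi = 0.1 * rng.standard_normal(2) if has_xi else None

        scales = {"theta": 0.2, "u": 0.3, "sigma": 0.5, "recenter": 0.2, "xi": 0.3}
        acc = {key: 0.0 for key in scales}
        att = {key: 0 for key in scales}

        xi_cur = np.exp(st.log_xi) if has_xi else np.ones(2)
        ll_vec, _, _, _ = pointwise_loglik(consumer_ilr(st.theta, st.u), xi_cur)
        lp_theta = log_prior_theta(st.theta)

        # warmup history for empirical-covariance proposals; the variance
        # block stacks log_xi (if any) and log_sigma (if any)
        n_aux = (2 if has_xi else 0) + (1 if has_random else 0)
        hist_theta: list[np.ndarray] = []
        hist_aux: list[np.ndarray] = []
        chol_theta: np.ndarray | None = None  # (L, K-1, K-1)
        chol_xi: np.ndarray | None = None  # (n_aux, n_aux)
        hist_start = warmup // 5

        def aux_vector() -> np.ndarray:
            parts = []
            if has_xi:
                parts.append(st.log_xi)
            if has_random:
                parts.append([st.log_sigma])
            return np.concatenate(parts) if parts else np.empty(0)

        chain_p = []
        chain_gp = []
        chain_ll = []
        chain_sigma = []
        chain_xi = []
        chain_lvl = []
        chain_monitor: dict[str, list[float]] = {}

        total_iter = warmup + iterations
        for it in range(total_iter):
            adapting = it < warmup

            # --- per-level ILR block (sequential accept, shared proposal draw;
            # the likelihood factorizes by level, the prior couples levels)
            att["theta"] += 1
            eps = rng.standard_normal(st.theta.shape)
            if chol_theta is not None:
                eps = np.einsum("lij,lj->li", chol_theta, eps)
            theta_prop = st.theta + scales["theta"] * eps
            ll_prop_vec, _, _, _ = pointwise_loglik(
                consumer_ilr(theta_prop, st.u), xi_cur
            )
            log_us = np.log(rng.random(n_levels))
            n_acc = 0
            for l in range(n_levels):
                cand = st.theta.copy()
                cand[l] = theta_prop[l]
                lp_cand = log_prior_theta(cand)
                members = level_members[l]
                d_ll = float(np.sum(ll_prop_vec[members] - ll_vec[members]))
                if log_us[l] < d_ll + lp_cand - lp_theta:
                    st.theta = cand
                    lp_theta = lp_cand
                    ll_vec = ll_vec.copy()
                    ll_vec[members] = ll_prop_vec[members]
                    n_acc += 1
            acc["theta"] += n_acc / n_levels

            # --- individual random effects (vectorized elementwise MH)
            if has_random:
                att["u"] += 1
                sigma = math.exp(st.log_sigma)
                u_prop = st.u + scales["u"] * rng.standard_normal(st.u.shape)
                ll_prop_vec, _, _, _ = pointwise_loglik(
                    consumer_ilr(st.theta, u_prop), xi_cur
                )
                dprior_i = -0.5 * (
                    np.sum(u_prop**2, axis=1) - np.sum(st.u**2, axis=1)
                ) / sigma**2
                accept = np.log(rng.random(n)) < ll_prop_vec - ll_vec + dprior_i
                st.u[accept] = u_prop[accept]
                ll_vec = np.where(accept, ll_prop_vec, ll_vec)
                acc["u"] += float(accept.mean())

                # --- random-effect SD, centered update (likelihood-free given u)
                att["sigma"] += 1
                ls_prop = st.log_sigma + scales["sigma"] * rng.standard_normal()
                def _lp_sigma(ls: float) -> float:
                    s = math.exp(ls)
                    return (
                        -0.5 * np.sum(st.u**2) / s**2
                        - n * (k - 1) * ls
                        - 0.5 * s**2 / _PRIOR_SIGMA_SCALE**2
                        + ls  # log-Jacobian of the log transform
                    )
                if math.log(rng.random()) < _lp_sigma(ls_prop) - _lp_sigma(st.log_sigma):
                    st.log_sigma = ls_prop
                    acc["sigma"] += 1

                # --- recentering move: shift a level mean into its members'
                # random effects; likelihood-invariant, prior-only accept
                att["recenter"] += 1
                sigma = math.exp(st.log_sigma)
                n_racc = 0
                for l in range(n_levels):
                    members = level_members[l]
                    if members.size == 0:
                        continue
                    delta = scales["recenter"] * rng.standard_normal(k - 1)
                    cand = st.theta.copy()
                    cand[l] = cand[l] + delta
                    lp_cand = log_prior_theta(cand)
                    du = (
                        -0.5
                        * float(
                            np.sum((st.u[members] - delta) ** 2 - st.u[members] ** 2)
                        )
                        / sigma**2
                    )
                    if math.log(rng.random()) < lp_cand - lp_theta + du:
                        st.theta = cand
                        lp_theta = lp_cand
                        st.u[members] -= delta
                        n_racc += 1
                acc["recenter"] += n_racc / n_levels

            # --- variance block: error multipliers and/or non-centered
            # random-effect SD (rescaling u with sigma breaks the funnel; a
            # joint covariance-adapted proposal handles the trade-off between
            # xi and sigma_ind, which both absorb overdispersion)
            if has_xi or has_random:
                att["xi"] += 1
                eps = rng.standard_normal(n_aux)
                if chol_xi is not None:
                    eps = chol_xi @ eps
                eps = scales["xi"] * eps

                def _lp_xi(lx: np.ndarray) -> float:
                    x = np.exp(lx)
                    return float(np.sum(-np.log1p(x**2) + lx))  # half-Cauchy + Jacobian

                def _lp_sigma_nc(ls: float) -> float:
                    s = math.exp(ls)
                    return -0.5 * s**2 / _PRIOR_SIGMA_SCALE**2 + ls

                d_logp = 0.0
                if has_xi:
                    lx_prop = st.log_xi + eps[:2]
                    xi_prop = np.exp(lx_prop)
                    d_logp += _lp_xi(lx_prop) - _lp_xi(st.log_xi)
                else:
                    lx_prop, xi_prop = st.log_xi, xi_cur
                if has_random:
                    ls_prop = st.log_sigma + eps[-1]
                    u_prop = st.u * math.exp(ls_prop - st.log_sigma)
                    d_logp += _lp_sigma_nc(ls_prop) - _lp_sigma_nc(st.log_sigma)
                else:
                    ls_prop, u_prop = st.log_sigma, st.u
                ll_prop_vec, _, _, _ = pointwise_loglik(
                    consumer_ilr(st.theta, u_prop), xi_prop
                )
                if math.log(rng.random()) < ll_prop_vec.sum() - ll_vec.sum() + d_logp:
                    st.log_xi, st.log_sigma, ll_vec = lx_prop, ls_prop, ll_prop_vec
                    if has_random:
                        st.u = u_prop
                    xi_cur = xi_prop
                    acc["xi"] += 1

            # --- proposal adaptation during warmup
            if adapting:
                if it >= hist_start:
                    hist_theta.append(st.theta.copy())
                    if n_aux:
                        hist_aux.append(aux_vector())
                if (it + 1) % 50 == 0:
                    for key in scales:
                        if att[key] == 0:
                            continue
                        rate = acc[key] / att[key]
                        target = (
                            _TARGET_ACC["scalar"] if key == "sigma"
                            else _TARGET_ACC["block"]
                        )
                        scales[key] *= math.exp(1.2 * (rate - target))
                        acc[key] = att[key] = 0
                    if len(hist_theta) >= 200:
                        # empirical-covariance proposals (Haario-style),
                        # 2.38^2/d scaling folded into the Cholesky factor
                        arr = np.array(hist_theta[len(hist_theta) // 2 :])
                        d_t = k - 1
                        new_chol = np.empty((n_levels, d_t, d_t))
                        ok = True
                        for l in range(n_levels):
                            cov = np.cov(arr[:, l, :].T).reshape(d_t, d_t)
                            cov = 2.38**2 / d_t * cov + 1e-8 * np.eye(d_t)
                            try:
                                new_chol[l] = np.linalg.cholesky(cov)
                            except np.linalg.LinAlgError:
                                ok = False
                                break
                        if ok:
                            if chol_theta is None:
                                scales["theta"] = 1.0
                            chol_theta = new_chol
                        if n_aux and len(hist_aux) >= 200:
                            arr_x = np.array(hist_aux[len(hist_aux) // 2 :])
                            cov = 2.38**2 / n_aux * np.cov(arr_x.T).reshape(n_aux, n_aux)
                            cov += 1e-8 * np.eye(n_aux)
                            try:
                                cx = np.linalg.cholesky(cov)
                            except np.linalg.LinAlgError:
                                cx = None
                            if cx is not None:
                                if chol_xi is None:
                                    scales["xi"] = 1.0
                                chol_xi = cx

            if not adapting:
                zc = consumer_ilr(st.theta, st.u)
                ll_vec, p_now, _, _ = pointwise_loglik(zc, xi_cur)
                z_global = st.theta.mean(axis=0)
                chain_p.append(p_now)
                chain_gp.append(ilr_inverse(z_global, k))
                chain_ll.append(ll_vec.copy())
                if has_random:
                    chain_sigma.append(math.exp(st.log_sigma))
                if has_xi:
                    chain_xi.append(xi_cur.copy())
                if has_fixed:
                    chain_lvl.append(ilr_inverse(st.theta, k))
                for j, val in enumerate(z_global):
                    chain_monitor.setdefault(f"z[{j}]", []).append(val)
                if has_fixed:
                    for idx_t, val in enumerate(st.theta.ravel()):
                        chain_monitor.setdefault(f"theta[{idx_t}]", []).append(val)
                if has_random:
                    chain_monitor.setdefault("log_sigma_ind", []).append(st.log_sigma)
                if has_xi:
                    for j, val in enumerate(st.log_xi):
                        chain_monitor.setdefault(f"log_xi[{j}]", []).append(val)
                chain_monitor.setdefault("deviance", []).append(-2.0 * float(ll_vec.sum()))

        draws_p.append(np.array(chain_p))
        draws_global.append(np.array(chain_gp))
        draws_ll.append(np.array(chain_ll))
        if has_random:
            draws_sigma.append(np.array(chain_sigma))
        if has_xi:
            draws_xi.append(np.array(chain_xi))
        if has_fixed:
            draws_level_p.append(np.array(chain_lvl))
        for key, vals in chain_monitor.items():
            monitor.setdefault(key, []).append(np.array(vals))

    rhats = {key: rhat(np.array(stack)) for key, stack in monitor.items()}
    finite = [v for v in rhats.values() if np.isfinite(v)]
    converged = bool(finite) and all(v < rhat_threshold for v in finite)
    if not converged:
        worst = max(rhats, key=lambda kk: (rhats[kk] if np.isfinite(rhats[kk]) else -1))
        logger.warning(
            "model %r did not converge: max R-hat %s = %.3f",
            spec.label, worst, rhats[worst],
        )

    return PosteriorDraws(
        p=np.concatenate(draws_p),
        global_p=np.concatenate(draws_global),
        loglik_pointwise=np.concatenate(draws_ll),
        chains=chains,
        rhat=rhats,
        converged=converged,
        consumer_ids=tuple(c.sample_id for c in consumers),
        source_labels=spec.source_labels,
        random_sd=np.concatenate(draws_sigma) if has_random else None,
        error_mult=np.concatenate(draws_xi) if has_xi else None,
        fixed_levels=levels,
        level_p=np.concatenate(draws_level_p) if has_fixed else None,
    )


# ---------------------------------------------------------------------------
# Mixing polygon goodness-of-fit


def _point_in_segment_band(points: np.ndarray, a: np.ndarray, b: np.ndarray, tol: float):
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return np.linalg.norm(points - a, axis=1) <= tol
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1) <= tol


def mixing_polygon_check(
    consumers: Sequence[IsotopeSample],
    sources: Sequence[SourceSummary],
    tdf: TDFSpec,
    n_iter: int = 1000,
    seed: int = 0,
    segment_tol: float | None = None,
) -> dict[str, float]:
    """Simulated mixing-polygon inclusion probability per consumer.

    Each iteration draws every TDF-shifted source vertex from its normal
    distribution and tests whether each consumer falls inside the convex
    hull (K >= 3) or within a tolerance band of the segment (K = 2).
    """
    if n_iter < 100:
        logger.warning("n_iter=%d < 100: inclusion probabilities will be coarse", n_iter)
    rng = np.random.default_rng(seed)
    pts = np.array([c.tracers for c in consumers])
    mean = np.array([s.mean for s in sources]) + tdf.mean
    sd = np.sqrt(np.array([s.sd for s in sources]) ** 2 + tdf.sd**2)
    k = len(sources)
    if segment_tol is None:
        segment_tol = 2.0 * float(sd.mean())
    inside = np.zeros(len(consumers))
    for _ in range(n_iter):
        verts = rng.normal(mean, sd)
        if k == 2:
            inside += _point_in_segment_band(pts, verts[0], verts[1], segment_tol)
            continue
        try:
            hull = Delaunay(verts)
            inside += hull.find_simplex(pts) >= 0
        except QhullError:
            # collinear draw: fall back to the segment band on the extremes
            order = np.argsort(verts[:, 0])
            inside += _point_in_segment_band(
                pts, verts[order[0]], verts[order[-1]], segment_tol
            )
    probs = inside / n_iter
    return {c.sample_id: float(pr) for c, pr in zip(consumers, probs)}


# ---------------------------------------------------------------------------
# Prior sensitivity


def prior_posterior_compare(spec: MixingModelSpec, draws: PosteriorDraws):
    """Per-source prior (Dirichlet marginal Beta) vs posterior summaries.

    Returns a pandas DataFrame with one row per source, including a
    histogram-overlap coefficient between prior and posterior marginals.
    """
    import pandas as pd

    alpha = spec.prior_alpha
    a0 = float(alpha.sum())
    rng = np.random.default_rng(0)
    rows = []
    edges = np.linspace(0.0, 1.0, 51)
    for idx, label in enumerate(spec.source_labels):
        a_k = float(alpha[idx])
        prior = stats.beta(a_k, a0 - a_k)
        post = draws.global_p[:, idx]
        prior_samp = prior.rvs(size=max(4000, post.size), random_state=rng)
        h1, _ = np.histogram(prior_samp, bins=edges, density=True)
        h2, _ = np.histogram(post, bins=edges, density=True)
        overlap = float(np.minimum(h1, h2).sum() * (edges[1] - edges[0]))
        rows.append(
            {
                "source": label,
                "prior_mean": a_k / a0,
                "prior_q025": prior.ppf(0.025),
                "prior_q975": prior.ppf(0.975),
                "post_mean": float(post.mean()),
                "post_q025": float(np.quantile(post, 0.025)),
                "post_q975": float(np.quantile(post, 0.975)),
                "overlap": overlap,
            }
        )
    return pd.DataFrame(rows)
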