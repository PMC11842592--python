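"""From-scratch permutation multivariate statistics.

PERMANOVA partitions the squared inter-point distances (Gower identity:
SS_total = sum of squared distances / n) and compares the between-group
mean square to the within-group mean square; significance comes from
permuting group labels. Pairwise contrasts are adjusted with the
Benjamini-Yekutieli step-up. A dispersion screen flags points whose
distance to their group centroid exceeds median + k * IQR.
"""

from __future__ import annotations

import enum
import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.spatial.distance import squareform, pdist

from isomix.isodata import InvalidInputError

logger = logging.getLogger(__name__)


class DesignError(ValueError):
    """Raised for degenerate grouping designs."""


class Metric(str, enum.Enum):
    MANHATTAN = "manhattan"
    EUCLIDEAN = "euclidean"


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray
    metric: Metric

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise InvalidInputError("distance matrix must be square")
        if not np.allclose(d, d.T):
            raise InvalidInputError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise InvalidInputError("distance matrix diagonal must be zero")
        if np.any(d < 0):
            raise InvalidInputError("distances must be non-negative")
        object.__setattr__(self, "d", d)

    @property
    def n(self) -> int:
        return self.d.shape[0]


@dataclass(frozen=True)
class PermanovaResult:
    factor: str
    pseudo_f: float
    r2: float
    p_perm: float
    n_perm: int
    partial_ss: Mapping[str, float]


def distance_matrix(
    points: np.ndarray,
    metric: Metric | str = Metric.EUCLIDEAN,
    labels: Sequence[str] | None = None,
) -> DistanceMatrix:
    """Pairwise distances between rows of a tracer matrix."""
    metric = Metric(metric)
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 2:
        raise InvalidInputError("need an n x p matrix with n >= 2")
    if not np.all(np.isfinite(points)):
        raise InvalidInputError("tracer matrix contains missing or non-finite values")
    scipy_name = "cityblock" if metric is Metric.MANHATTAN else metric.value
    d = squareform(pdist(points, metric=scipy_name))
    if labels is None:
        labels = tuple(str(i) for i in range(points.shape[0]))
    return DistanceMatrix(labels=tuple(labels), d=d, metric=metric)


def _group_indices(groups: Sequence) -> tuple[list[np.ndarray], list]:
    levels = sorted(set(groups), key=str)
    arr = np.asarray(groups)
    return [np.flatnonzero(arr == lv) for lv in levels], levels


def _pseudo_f(d2: np.ndarray, idx_groups: Sequence[np.ndarray], n: int) -> tuple[float, float, float, float]:
    """Pseudo-F from squared distances; returns (F, SS_between, SS_within, SS_total)."""
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for idx in idx_groups:
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    ss_between = ss_total - ss_within
    a = len(idx_groups)
    df_b, df_w = a - 1, n - a
    if ss_within <= 0:
        # zero within-group spread: F is infinite when groups differ at all,
        # undefined when every distance in the matrix is zero
        f = math.inf if ss_between > 1e-12 * max(ss_total, 1.0) else math.nan
        return f, ss_between, ss_within, ss_total
    f = (ss_between / df_b) / (ss_within / df_w)
    return f, ss_between, ss_within, ss_total


def permanova(
    d: DistanceMatrix,
    groups: Sequence,
    n_perm: int = 9999,
    seed: int = 0,
    factor: str = "group",
    method: str = "auto",
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    ``method``: "sample" draws ``n_perm`` random label permutations and uses
    the add-one rule p = (1 + #{F* >= F}) / (n_perm + 1); "exact" enumerates
    every distinct relabelling (identity included) and reports the exact
    permutation p; "auto" switches to exact when the number of distinct
    relabellings is at most n_perm.
    """
    n = d.n
    if len(groups) != n:
        raise DesignError("groups length must match distance matrix")
    idx_groups, levels = _group_indices(groups)
    if len(levels) < 2:
        raise DesignError("PERMANOVA needs at least 2 groups")
    if any(len(ix) < 2 for ix in idx_groups):
        raise DesignError("every group needs at least 2 members")
    if n_perm < 1:
        raise DesignError("n_perm must be >= 1")

    d2 = d.d ** 2
    f_obs, ss_b, ss_w, ss_t = _pseudo_f(d2, idx_groups, n)
    partial = {factor: ss_b, "Residual": ss_w, "Total": ss_t}
    r2 = ss_b / ss_t if ss_t > 0 else math.nan
    if math.isnan(f_obs):
        logger.warning("degenerate all-equal distances: pseudo-F undefined")
        return PermanovaResult(factor, math.nan, r2, math.nan, 0, partial)

    sizes = [len(ix) for ix in idx_groups]
    if method == "auto":
        n_distinct = math.factorial(n)
        for s in sizes:
            n_distinct //= math.factorial(s)
        method = "exact" if n_distinct <= n_perm else "sample"

    tol = 1e-12
    if method == "exact":
        count = total = 0
        for assignment in _distinct_assignments(n, sizes):
            f_perm, *_ = _pseudo_f(d2, assignment, n)
            total += 1
            if f_perm >= f_obs - tol:
                count += 1
        p = count / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        count = 0
        order = np.arange(n)
        for _ in range(n_perm):
            perm = rng.permutation(order)
            shuffled = [perm[ix] for ix in idx_groups]
            f_perm, *_ = _pseudo_f(d2, shuffled, n)
            if f_perm >= f_obs - tol:
                count += 1
        p = (1 + count) / (n_perm + 1)
        n_used = n_perm
    return PermanovaResult(factor, f_obs, r2, p, n_used, partial)


def _distinct_assignments(n: int, sizes: Sequence[int]):
    """Yield every distinct partition of range(n) into ordered groups of the
    given sizes, as lists of index arrays."""

    def rec(remaining: tuple[int, ...], sizes_left: Sequence[int]):
        if not sizes_left:
            yield []
            return
        k = sizes_left[0]
        if len(sizes_left) == 1:
            yield [np.array(remaining)]
            return
        for combo in itertools.combinations(remaining, k):
            for rest in rec(tuple(x for x in remaining if x not in combo), sizes_left[1:]):
                yield [np.array(combo)] + rest

    yield from rec(tuple(range(n)), list(sizes))


def by_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjustment, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    if m == 1:
        return p.copy()
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    ranked = p[order] * c_m * m / np.arange(1, m + 1)
    # enforce monotone non-decreasing adjusted p along the sorted order
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def pairwise_permanova(
    d: DistanceMatrix,
    groups: Sequence,
    n_perm: int = 9999,
    seed: int = 0,
) -> list[tuple[tuple, float, float]]:
    """All unordered pair contrasts with B-Y-adjusted p-values."""
    idx_groups, levels = _group_indices(groups)
    if len(levels) < 2:
        raise DesignError("need at least 2 groups")
    arr = np.asarray(groups)
    pairs = list(itertools.combinations(range(len(levels)), 2))
    raw = []
    for j, (i1, i2) in enumerate(pairs):
        sel = np.concatenate([idx_groups[i1], idx_groups[i2]])
        sub = DistanceMatrix(
            labels=tuple(d.labels[i] for i in sel),
            d=d.d[np.ix_(sel, sel)],
            metric=d.metric,
        )
        res = permanova(sub, arr[sel], n_perm=n_perm, seed=seed + j)
        raw.append(res.p_perm)
    adjusted = by_adjust(raw)
    return [
        ((levels[i1], levels[i2]), raw[j], float(adjusted[j]))
        for j, (i1, i2) in enumerate(pairs)
    ]


def centroid_distances(points: np.ndarray, groups: Sequence) -> np.ndarray:
    """Euclidean distance of each point to its own group centroid."""
    points = np.asarray(points, dtype=float)
    out = np.empty(points.shape[0])
    idx_groups, _ = _group_indices(groups)
    for idx in idx_groups:
        centroid = points[idx].mean(axis=0)
        out[idx] = np.linalg.norm(points[idx] - centroid, axis=1)
    return out


def dispersion_outliers(
    points: np.ndarray,
    groups: Sequence,
    labels: Sequence[str] | None = None,
    k: float = 1.5,
) -> list[str]:
    """Flag points farther than median + k*IQR from their group centroid.

    Distances are computed in the original tracer space. Groups with fewer
    than 3 members are skipped with a warning.
    """
    points = np.asarray(points, dtype=float)
    if labels is None:
        labels = [str(i) for i in range(points.shape[0])]
    flagged: list[str] = []
    idx_groups, levels = _group_indices(groups)
    for idx, level in zip(idx_groups, levels):
        if len(idx) < 3:
            logger.warning("group %r has < 3 members; outlier screen skipped", level)
            continue
        centroid = points[idx].mean(axis=0)
        dist = np.linalg.norm(points[idx] - centroid, axis=1)
        med = np.median(dist)
        q1, q3 = np.percentile(dist, [25, 75])
        cutoff = med + k * (q3 - q1)
        if np.all(dist == 0):
            continue
        for i, dv in zip(idx, dist):
            if dv > cutoff:
                flagged.append(labels[i])
    return sorted(flagged)


def mardia_test(points: np.ndarray) -> dict[str, float]:
    """Mardia's multivariate skewness/kurtosis normality check (warning-only).

    Returns the two statistics with asymptotic p-values (chi-square for
    skewness, standard normal for kurtosis).
    """
    x = np.asarray(points, dtype=float)
    n, p = x.shape
    xc = x - x.mean(axis=0)
    s = xc.T @ xc / n
    s_inv = np.linalg.inv(s)
    m = xc @ s_inv @ xc.T
    b1 = (m ** 3).sum() / n ** 2
    b2 = np.mean(np.diag(m) ** 2)
    skew_stat = n * b1 / 6.0
    skew_df = p * (p + 1) * (p + 2) / 6.0
    skew_p = float(stats.chi2.sf(skew_stat, skew_df))
    kurt_z = (b2 - p * (p + 2)) / math.sqrt(8.0 * p * (p + 2) / n)
    kurt_p = float(2 * stats.norm.sf(abs(kurt_z)))
    return {
        "skewness": float(b1),
        "skewness_stat": float(skew_stat),
        "skewness_p": skew_p,
        "kurtosis": float(b2),
        "kurtosis_z": float(kurt_z),
        "kurtosis_p": kurt_p,
    }
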