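"""Post-hoc diet analyses on per-consumer posterior diet estimates.

Includes the individual specialization index (normalized Euclidean
distance from the uniform diet; 0 = ultra-generalist, 1 =
ultra-specialist), merging of source groups (e.g. pelagic prey from
different areas), inter-individual heterogeneity as distance to the group
centroid with permutation dispersion tests, and PERMANOVA-based diet
difference tests between classes/periods.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from isomix.isodata import (
    ConfigurationError,
    InvalidInputError,
    Period,
    SexAgeClass,
)
from isomix.multivar_stats import (
    DistanceMatrix,
    Metric,
    PermanovaResult,
    centroid_distances,
    distance_matrix,
    pairwise_permanova,
    permanova,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DietEstimate:
    """Per-consumer posterior diet summary over an ordered source set."""

    consumer_id: str
    sex_age_class: SexAgeClass | None
    period: Period
    year: int
    source_labels: tuple[str, ...]
    mean_p: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    draws: np.ndarray | None = None  # (n_draws, K) posterior draws if kept

    def __post_init__(self) -> None:
        mean_p = np.asarray(self.mean_p, dtype=float)
        object.__setattr__(self, "mean_p", mean_p)
        object.__setattr__(self, "ci_low", np.asarray(self.ci_low, dtype=float))
        object.__setattr__(self, "ci_high", np.asarray(self.ci_high, dtype=float))
        if abs(mean_p.sum() - 1.0) > 1e-6 or np.any(mean_p < 0):
            raise InvalidInputError(
                f"{self.consumer_id!r}: mean_p must be a simplex vector"
            )
        if np.any(self.ci_low > mean_p + 1e-9) or np.any(self.ci_high < mean_p - 1e-9):
            raise InvalidInputError(
                f"{self.consumer_id!r}: credible bounds must bracket the mean"
            )

    @property
    def k(self) -> int:
        return self.mean_p.size


def estimates_from_draws(draws, consumers, ci: float = 0.95) -> list[DietEstimate]:
    """Build per-consumer :class:`DietEstimate` records from posterior draws.

    ``draws`` is a :class:`~isomix.mixing_model.PosteriorDraws`; ``consumers``
    the samples the model was fitted to, in the same order.
    """
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    out = []
    for i, c in enumerate(consumers):
        p_i = draws.p[:, i, :]
        out.append(
            DietEstimate(
                consumer_id=c.sample_id,
                sex_age_class=c.sex_age_class,
                period=c.period,
                year=c.year,
                source_labels=draws.source_labels,
                mean_p=p_i.mean(axis=0),
                ci_low=np.minimum(np.quantile(p_i, lo_q, axis=0), p_i.mean(axis=0)),
                ci_high=np.maximum(np.quantile(p_i, hi_q, axis=0), p_i.mean(axis=0)),
                draws=p_i,
            )
        )
    return out


def read_estimates(path) -> list[DietEstimate]:
    """Load estimates from the tidy ``diet_estimates.csv`` layout
    (columns ``p_<source>``, ``lo_<source>``, ``hi_<source>``)."""
    frame = pd.read_csv(path)
    labels = tuple(c[2:] for c in frame.columns if c.startswith("p_"))
    out = []
    for _, r in frame.iterrows():
        cls = str(r.get("class", "")) or None
        out.append(
            DietEstimate(
                consumer_id=str(r["consumer_id"]),
                sex_age_class=SexAgeClass(cls) if cls else None,
                period=Period(str(r["period"])),
                year=int(r["year"]),
                source_labels=labels,
                mean_p=np.array([r[f"p_{s}"] for s in labels]),
                ci_low=np.array([r[f"lo_{s}"] for s in labels]),
                ci_high=np.array([r[f"hi_{s}"] for s in labels]),
            )
        )
    return out


def combine_sources(
    estimate: DietEstimate, merge_map: Mapping[str, str]
) -> DietEstimate:
    """Merge sources by summing their contributions (per draw when draws are
    available, otherwise on the posterior means)."""
    missing = [s for s in estimate.source_labels if s not in merge_map]
    if missing:
        raise ConfigurationError(f"merge_map lacks source(s) {missing}")
    merged_labels = []
    for s in estimate.source_labels:
        if merge_map[s] not in merged_labels:
            merged_labels.append(merge_map[s])
    idx = {lab: i for i, lab in enumerate(merged_labels)}
    m = np.zeros((len(merged_labels), estimate.k))
    for j, s in enumerate(estimate.source_labels):
        m[idx[merge_map[s]], j] = 1.0

    if estimate.draws is not None:
        draws = estimate.draws @ m.T
        mean_p = draws.mean(axis=0)
        ci_low = np.minimum(np.quantile(draws, 0.025, axis=0), mean_p)
        ci_high = np.maximum(np.quantile(draws, 0.975, axis=0), mean_p)
    else:
        draws = None
        mean_p = m @ estimate.mean_p
        ci_low = m @ estimate.ci_low
        ci_high = np.minimum(m @ estimate.ci_high, 1.0)
        ci_low = np.minimum(ci_low, mean_p)
        ci_high = np.maximum(ci_high, mean_p)
    return DietEstimate(
        consumer_id=estimate.consumer_id,
        sex_age_class=estimate.sex_age_class,
        period=estimate.period,
        year=estimate.year,
        source_labels=tuple(merged_labels),
        mean_p=mean_p,
        ci_low=ci_low,
        ci_high=ci_high,
        draws=draws,
    )


def epsilon_index(p: np.ndarray) -> float:
    """Specialization index: Euclidean distance from the uniform diet,
    normalized by the distance from uniform to a vertex, sqrt((K-1)/K).

    0 for a perfect generalist (uniform diet), 1 for an ultra-specialist
    (single-resource diet).
    """
    p = np.asarray(p, dtype=float)
    k = p.size
    if k < 2:
        raise InvalidInputError("need at least 2 resources")
    if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-6:
        raise InvalidInputError("p must lie on the simplex")
    u = np.full(k, 1.0 / k)
    d_max = math.sqrt((k - 1.0) / k)
    return float(np.linalg.norm(p - u) / d_max)


@dataclass(frozen=True)
class SpecializationResult:
    consumer_id: str
    epsilon: float
    k_resources: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0 + 1e-12:
            raise InvalidInputError("epsilon must lie in [0, 1]")


def _perm_gap_test(values: np.ndarray, labels: np.ndarray, a, b, n_perm, rng) -> float:
    """Permutation test on |mean difference| of a 1-D statistic."""
    mask = (labels == a) | (labels == b)
    v, l = values[mask], labels[mask]
    obs = abs(v[l == a].mean() - v[l == b].mean())
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(l)
        if abs(v[perm == a].mean() - v[perm == b].mean()) >= obs - 1e-12:
            count += 1
    return (1 + count) / (n_perm + 1)


def epsilon_population(
    estimates: Sequence[DietEstimate],
    merge_map: Mapping[str, str] | None = None,
    n_perm: int = 9999,
    seed: int = 0,
) -> tuple[list[SpecializationResult], pd.DataFrame, pd.DataFrame]:
    """Per-consumer specialization plus class summaries and pairwise tests.

    Returns (per-consumer results, class summary frame with mean/SD,
    pairwise class permutation-test frame). All estimates must share one
    period and source set.
    """
    if not estimates:
        raise InvalidInputError("no diet estimates")
    periods = {e.period for e in estimates}
    if len(periods) > 1:
        raise InvalidInputError("estimates span multiple periods")
    if len({e.source_labels for e in estimates}) > 1:
        raise InvalidInputError("estimates have inconsistent source sets")

    merged = [
        combine_sources(e, merge_map) if merge_map is not None else e
        for e in estimates
    ]
    results = [
        SpecializationResult(e.consumer_id, epsilon_index(e.mean_p), e.k)
        for e in merged
    ]
    eps = np.array([r.epsilon for r in results])
    classes = np.array([
        e.sex_age_class.value if e.sex_age_class else "unknown" for e in estimates
    ])
    summary = (
        pd.DataFrame({"class": classes, "epsilon": eps})
        .groupby("class")["epsilon"]
        .agg(["count", "mean", "std"])
        .reset_index()
    )
    rng = np.random.default_rng(seed)
    rows = []
    levels = sorted(set(classes))
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            p = _perm_gap_test(eps, classes, levels[i], levels[j], n_perm, rng)
            rows.append({"class_a": levels[i], "class_b": levels[j], "p_perm": p})
    return results, summary, pd.DataFrame(rows)


def _classical_mds(points: np.ndarray, n_axes: int = 2) -> np.ndarray:
    """Principal-coordinate (classical MDS) embedding of Euclidean points."""
    x = points - points.mean(axis=0)
    g = x @ x.T
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1][:n_axes]
    coords = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    return coords


def heterogeneity(
    estimates: Sequence[DietEstimate],
    grouping: str = "class",
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[pd.DataFrame, PermanovaResult | None, pd.DataFrame]:
    """Inter-individual diet heterogeneity (PERMDISP-style).

    Computes each consumer's Euclidean distance to the arithmetic-mean diet
    of its group (``grouping``: "class", "class_x_period", or "year"), tests
    group differences in dispersion by a permutation test on the distances,
    and exports 2-D MDS coordinates of the diet compositions.
    """
    if len({e.source_labels for e in estimates}) > 1:
        raise InvalidInputError("estimates have inconsistent source sets")
    p_mat = np.array([e.mean_p for e in estimates])
    if grouping == "class":
        labels = [e.sex_age_class.value if e.sex_age_class else "unknown" for e in estimates]
    elif grouping == "class_x_period":
        labels = [
            f"{e.sex_age_class.value if e.sex_age_class else 'unknown'}|{e.period.value}"
            for e in estimates
        ]
    elif grouping == "year":
        labels = [str(e.year) for e in estimates]
    else:
        raise InvalidInputError(f"unknown grouping {grouping!r}")
    labels = np.array(labels)

    counts = pd.Series(labels).value_counts()
    small = counts[counts < 3].index.tolist()
    if small:
        logger.warning("groups excluded from dispersion test (< 3 members): %s", small)
    keep = ~np.isin(labels, small)

    dist = np.full(len(estimates), np.nan)
    dist[keep] = centroid_distances(p_mat[keep], labels[keep])
    frame = pd.DataFrame(
        {
            "consumer_id": [e.consumer_id for e in estimates],
            "group": labels,
            "dist_to_centroid": dist,
        }
    )
    test = None
    kept_levels = sorted(set(labels[keep]))
    if len(kept_levels) >= 2:
        d = distance_matrix(
            dist[keep][:, None],
            metric=Metric.EUCLIDEAN,
            labels=[e.consumer_id for e, k in zip(estimates, keep) if k],
        )
        test = permanova(d, labels[keep], n_perm=n_perm, seed=seed, factor="dispersion")
    mds = _classical_mds(p_mat)
    mds_frame = pd.DataFrame(
        {
            "consumer_id": [e.consumer_id for e in estimates],
            "group": labels,
            "mds1": mds[:, 0],
            "mds2": mds[:, 1],
        }
    )
    return frame, test, mds_frame


def diet_difference_test(
    estimates: Sequence[DietEstimate],
    factor: str = "class",
    n_perm: int = 9999,
    seed: int = 0,
) -> tuple[PermanovaResult, list[tuple[tuple, float, float]]]:
    """PERMANOVA on posterior-mean diets (Euclidean) across factor levels,
    with pairwise B-Y-adjusted contrasts when more than two levels."""
    p_mat = np.array([e.mean_p for e in estimates])
    if factor == "class":
        labels = [e.sex_age_class.value if e.sex_age_class else "unknown" for e in estimates]
    elif factor == "period":
        labels = [e.period.value for e in estimates]
    elif factor == "class_x_period":
        labels = [
            f"{e.sex_age_class.value if e.sex_age_class else 'unknown'}|{e.period.value}"
            for e in estimates
        ]
    elif factor == "year":
        labels = [str(e.year) for e in estimates]
    else:
        raise InvalidInputError(f"unknown factor {factor!r}")
    d = distance_matrix(
        p_mat, metric=Metric.EUCLIDEAN, labels=[e.consumer_id for e in estimates]
    )
    result = permanova(d, labels, n_perm=n_perm, seed=seed, factor=factor)
    pairwise = []
    if len(set(labels)) > 2:
        pairwise = pairwise_permanova(d, labels, n_perm=n_perm, seed=seed)
    return result, pairwise
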