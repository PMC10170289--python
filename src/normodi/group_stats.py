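"""Nonparametric multi-group comparison: Kruskal-Wallis, Dunn's post-hoc,
Bonferroni and Benjamini-Hochberg adjustment.

Kruskal-Wallis delegates to :func:`scipy.stats.kruskal` (mid-ranks, standard
tie correction, chi-square approximation on g-1 degrees of freedom).  Dunn's
pairwise z statistics are computed here on pooled mid-ranks with the same tie
correction, since no installed package provides them.  BH adjustment wraps
:func:`statsmodels.stats.multitest.multipletests`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["TestResult", "kruskal_wallis", "dunn_posthoc", "bh_adjust", "bonferroni_adjust"]

ADJUSTMENTS = ("bonferroni", "bh", "none")


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: int | None = None
    pair: tuple | None = None
    adjusted_p: float | None = None
    extra: dict = field(default_factory=dict)


def _check_groups(groups: Sequence[Sequence[float]], min_size: int = 2) -> list[np.ndarray]:
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError(f"need at least 2 groups, got {len(arrays)}")
    for i, a in enumerate(arrays):
        if a.size < min_size:
            raise ValueError(f"group {i} has {a.size} observations; need >= {min_size}")
        if not np.isfinite(a).all():
            raise ValueError(f"group {i} contains non-finite values")
    return arrays


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test across two or more groups.

    All-identical pooled data (zero rank variance) is reported as H=0, p=1
    rather than an error.
    """
    arrays = _check_groups(groups)
    pooled = np.concatenate(arrays)
    df = len(arrays) - 1
    if np.all(pooled == pooled[0]):
        return TestResult(statistic=0.0, p_value=1.0, df=df)
    h, p = stats.kruskal(*arrays)
    return TestResult(statistic=float(h), p_value=float(p), df=df)


def _tie_term(pooled: np.ndarray) -> float:
    """Sum of (t^3 - t) over tied groups in the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float(np.sum(t**3 - t))


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    adjustment: str = "bonferroni",
    labels: Sequence | None = None,
) -> list[TestResult]:
    """Dunn's pairwise post-hoc test on pooled mid-ranks.

    For groups i, j with mean pooled ranks Rbar_i, Rbar_j,

        z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))

    with T = sum(t^3 - t) over tie groups; two-sided normal p-values,
    adjusted across all pairs by ``adjustment``.
    """
    if adjustment not in ADJUSTMENTS:
        raise ValueError(f"unknown adjustment {adjustment!r}; expected one of {ADJUSTMENTS}")
    arrays = _check_groups(groups)
    if labels is None:
        labels = list(range(len(arrays)))
    labels = list(labels)
    if len(labels) != len(arrays):
        raise ValueError("labels must match the number of groups")

    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = [a.size for a in arrays]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(arrays))]

    tie = _tie_term(pooled)
    base_var = n * (n + 1) / 12.0 - tie / (12.0 * (n - 1))

    results: list[TestResult] = []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0:  # every pooled observation identical
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * stats.norm.sf(abs(z))
        results.append(TestResult(statistic=float(z), p_value=float(p),
                                  pair=(labels[i], labels[j])))

    raw = np.array([r.p_value for r in results])
    if adjustment == "bonferroni":
        adjusted = bonferroni_adjust(raw)
    elif adjustment == "bh":
        adjusted = bh_adjust(raw)
    else:
        adjusted = raw
    for r, ap in zip(results, adjusted):
        r.adjusted_p = float(ap)
    return results


def bonferroni_adjust(p_values: Sequence[float]) -> np.ndarray:
    p = _check_p(p_values)
    return np.minimum(p * p.size, 1.0)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = _check_p(p_values)
    if p.size == 0:
        return p
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def _check_p(p_values: Sequence[float]) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if p.size and (not np.isfinite(p).all() or p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must be finite and in [0, 1]")
    return p
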