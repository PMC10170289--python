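"""Spearman association between two feature sets with BH correction.

Used for species-species, species-phage and species-metabolite edge lists:
rho on mid-ranks for every cross pair, two-sided p via the t approximation,
optional Benjamini-Hochberg adjustment across all pairs, and a ``kept`` flag
at the chosen significance threshold.  Constant features have no defined
rank correlation; their pairs are reported with missing rho/p and excluded
from the adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AbundanceTable
from .group_stats import bh_adjust

__all__ = ["CorrelationResult", "spearman_matrix", "results_to_frame"]

log = logging.getLogger("normodi")


@dataclass
class CorrelationResult:
    feature_a: object
    feature_b: object
    rho: float
    p_value: float
    p_adj: float
    kept: bool


def spearman_matrix(
    x: AbundanceTable,
    y: AbundanceTable | None = None,
    threshold: float = 0.05,
    adjust: bool = True,
) -> list[CorrelationResult]:
    """All-pairs Spearman correlation between features of ``x`` and ``y``.

    With ``y=None`` (or ``y`` identical to ``x``) only the upper triangle is
    reported — no self-pairs.  Samples must match between the two tables;
    ``kept`` is ``p_adj < threshold`` when ``adjust`` else ``p < threshold``.
    """
    same = y is None or (y.sample_ids == x.sample_ids and y.feature_ids == x.feature_ids
                         and np.array_equal(y.values, x.values, equal_nan=True))
    if y is None:
        y = x
    if list(y.sample_ids) != list(x.sample_ids):
        if set(y.sample_ids) != set(x.sample_ids):
            diff = set(x.sample_ids) ^ set(y.sample_ids)
            raise ValueError(f"sample sets differ between tables: {sorted(diff)[:10]}")
        y = y.subset_samples(x.sample_ids)

    xv, yv = x.values, y.values
    const_x = np.array([np.all(col == col[0]) for col in xv.T])
    const_y = np.array([np.all(col == col[0]) for col in yv.T])
    if const_x.any() or const_y.any():
        log.warning(
            "spearman_matrix: %d constant features; their correlations are undefined",
            int(const_x.sum()) + (0 if same else int(const_y.sum())),
        )

    rx = np.apply_along_axis(stats.rankdata, 0, xv)
    ry = rx if same else np.apply_along_axis(stats.rankdata, 0, yv)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.corrcoef(rx, ry, rowvar=False)[: xv.shape[1], xv.shape[1] :] if not same \
            else np.corrcoef(rx, rowvar=False)
    rho = np.atleast_2d(rho)
    n = xv.shape[0]
    # two-sided p via the t approximation with n-2 df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)

    pairs: list[tuple[int, int]] = []
    if same:
        d = xv.shape[1]
        pairs = [(i, j) for i in range(d) for j in range(i + 1, d)]
    else:
        pairs = [(i, j) for i in range(xv.shape[1]) for j in range(yv.shape[1])]

    records = []
    for i, j in pairs:
        undefined = const_x[i] or (const_x[j] if same else const_y[j])
        records.append(
            {
                "feature_a": x.feature_ids[i],
                "feature_b": (x if same else y).feature_ids[j],
                "rho": np.nan if undefined else float(np.clip(rho[i, j], -1.0, 1.0)),
                "p": np.nan if undefined else float(min(p[i, j], 1.0)),
            }
        )
    frame = pd.DataFrame.from_records(records)
    defined = frame["p"].notna()
    p_adj = np.full(len(frame), np.nan)
    if defined.any():
        p_adj[defined.to_numpy()] = bh_adjust(frame.loc[defined, "p"].to_numpy())
    frame["p_adj"] = p_adj
    crit = frame["p_adj"] if adjust else frame["p"]
    frame["kept"] = (crit < threshold).fillna(False)

    return [
        CorrelationResult(
            feature_a=row.feature_a,
            feature_b=row.feature_b,
            rho=row.rho,
            p_value=row.p,
            p_adj=row.p_adj,
            kept=bool(row.kept),
        )
        for row in frame.itertuples()
    ]


def results_to_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    """Edge-list DataFrame (feature_a, feature_b, rho, p, p_adj, kept)."""
    return pd.DataFrame(
        {
            "feature_a": [r.feature_a for r in results],
            "feature_b": [r.feature_b for r in results],
            "rho": [r.rho for r in results],
            "p": [r.p_value for r in results],
            "p_adj": [r.p_adj for r in results],
            "kept": [r.kept for r in results],
        }
    )
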