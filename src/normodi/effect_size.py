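"""Discriminatory-feature identification: Kruskal-Wallis gate + LDA effect size.

The procedure mirrors the LEfSe convention for flat (no subclass) designs:

1. every feature is tested across groups with Kruskal-Wallis; features with
   p >= ``kw_alpha`` fail the gate outright;
2. relative abundances of surviving features are rescaled to the per-million
   scale (x 10^6, floored at 1) and, for each enriched group, a regularized
   one-against-all linear discriminant is fit on bootstrap subsamples;
3. a feature's effect size is log10(1 + e) where e averages, over bootstrap
   rounds, the absolute raw class-mean difference and the feature's
   coefficient-weighted share of the discriminant class-mean separation;
4. a feature passes when kw_p < kw_alpha and the log10 effect size exceeds
   ``lda_threshold`` (2 by default, i.e. a hundredfold-scale separation on
   the per-million axis).

The enriched group is the group with the highest mean relative abundance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import AbundanceTable, SampleMetadata
from .group_stats import kruskal_wallis

__all__ = ["EffectSizeResult", "lda_effect_size"]

log = logging.getLogger("normodi")

RESCALE = 1.0e6  # per-million abundance axis, LEfSe convention
SUBSAMPLE_FRACTION = 2.0 / 3.0
RIDGE = 1e-6  # times mean eigenvalue of the pooled within-class scatter


@dataclass
class EffectSizeResult:
    feature_id: object
    kw_p: float
    lda_log10: float
    enriched_group: object
    passed: bool


def _discriminant(X1: np.ndarray, X0: np.ndarray) -> tuple[np.ndarray, float]:
    """Regularized LDA axis between two classes.

    Returns the unit-norm discriminant direction and the separation of the
    class means along it.
    """
    m1 = X1.mean(axis=0)
    m0 = X0.mean(axis=0)
    d = X1.shape[1]
    S = np.cov(X1, rowvar=False) * (len(X1) - 1) + np.cov(X0, rowvar=False) * (len(X0) - 1)
    S /= len(X1) + len(X0) - 2
    S = np.atleast_2d(S)
    S = S + RIDGE * (np.trace(S) / d + 1.0) * np.eye(d)
    w = np.linalg.solve(S, m1 - m0)
    norm = np.linalg.norm(w)
    if norm == 0:
        return np.zeros(d), 0.0
    w = w / norm
    return w, float(abs(w @ (m1 - m0)))


def lda_effect_size(
    table: AbundanceTable,
    metadata: SampleMetadata,
    kw_alpha: float = 0.05,
    lda_threshold: float = 2.0,
    n_boot: int = 30,
    seed: int = 0,
    rescale: float = RESCALE,
) -> list[EffectSizeResult]:
    """Score every feature for between-group discrimination.

    Results come back in the table's feature order; determinism is guaranteed
    for fixed ``(seed, n_boot)`` and is independent of sample order.
    """
    if n_boot < 1:
        raise ValueError(f"n_boot must be >= 1, got {n_boot}")
    if table.state != "relative":
        raise ValueError("lda_effect_size expects a relative-abundance table")
    groups = metadata.groups_for(table.sample_ids)
    labels = [g for g in metadata.group_labels() if g in set(groups)]
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    # canonical sample order (sorted ids) so results ignore input row order
    order = np.argsort(np.asarray(table.sample_ids, dtype=object).astype(str))
    data = table.data.iloc[order]
    groups = groups.iloc[order]
    sizes = groups.value_counts()
    small = sizes[sizes < 3]
    if len(small):
        raise ValueError(
            f"group {small.index[0]!r} has {int(small.iloc[0])} samples; LDA needs >= 3"
        )

    group_masks = {g: (groups == g).to_numpy() for g in labels}
    group_means = {g: data.loc[group_masks[g]].mean(axis=0) for g in labels}
    means_frame = pd.DataFrame(group_means)  # features x groups
    enriched = means_frame.idxmax(axis=1)

    kw_p = pd.Series(index=data.columns, dtype=float)
    for feature in data.columns:
        vectors = [data.loc[group_masks[g], feature].to_numpy() for g in labels]
        kw_p[feature] = kruskal_wallis(vectors).p_value

    survivors = [f for f in data.columns if kw_p[f] < kw_alpha]
    lda_scores = pd.Series(np.nan, index=data.columns)
    if survivors:
        scaled = np.maximum(data.loc[:, survivors].to_numpy() * rescale, 1.0)
        rng = np.random.default_rng(seed)
        # one-against-all comparison per enriched group present among survivors
        survivor_enriched = enriched.loc[survivors]
        effects = np.zeros((n_boot, len(survivors)))
        for b in range(n_boot):
            idx_by_class: dict = {}
            for g in labels:
                members = np.where(group_masks[g])[0]
                take = max(3, int(round(SUBSAMPLE_FRACTION * members.size)))
                idx_by_class[g] = rng.choice(members, size=min(take, members.size),
                                             replace=False)
            for g in survivor_enriched.unique():
                cols = np.where((survivor_enriched == g).to_numpy())[0]
                in_idx = idx_by_class[g]
                out_idx = np.concatenate([idx_by_class[h] for h in labels if h != g])
                X1 = scaled[np.ix_(in_idx, cols)]
                X0 = scaled[np.ix_(out_idx, cols)]
                w, separation = _discriminant(X1, X0)
                raw_diff = np.abs(X1.mean(axis=0) - X0.mean(axis=0))
                effects[b, cols] = 0.5 * (raw_diff + np.abs(w) * separation)
        mean_effect = effects.mean(axis=0)
        lda_scores.loc[survivors] = np.log10(1.0 + mean_effect)

    results = []
    for feature in table.feature_ids:
        score = lda_scores[feature]
        score = float(score) if np.isfinite(score) else 0.0
        p = float(kw_p[feature])
        results.append(
            EffectSizeResult(
                feature_id=feature,
                kw_p=p,
                lda_log10=score,
                enriched_group=enriched[feature],
                passed=bool(p < kw_alpha and score > lda_threshold),
            )
        )
    n_pass = sum(r.passed for r in results)
    log.info("lda_effect_size: %d/%d features pass (kw_alpha=%g, lda_threshold=%g)",
             n_pass, len(results), kw_alpha, lda_threshold)
    return results
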