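"""End-to-end orchestration: raw counts -> normobiotic model -> DI scores.

The transform parameters (pseudocount in particular) are locked on the
reference cohort at fit time and reused for every scored sample, so test
samples are mapped into exactly the space the model was fit in.
"""

from __future__ import annotations

import logging

from .containers import AbundanceTable, SampleMetadata
from .io import PipelineConfig
from .model import DIScoreSet, ReferenceModel, fit_reference_model, score_samples
from .preprocessing import default_pseudocount, prevalence_filter, to_relative_abundance, transform

__all__ = ["fit_normobiotic", "score_raw", "score_trial"]

log = logging.getLogger("normodi")


def fit_normobiotic(
    reference_raw: AbundanceTable,
    config: PipelineConfig | None = None,
    min_prevalence: float = 0.0,
    n_components: int | None = None,
) -> tuple[ReferenceModel, float]:
    """Fit the reference model on raw healthy-control counts.

    Returns the model plus the pseudocount locked on the reference table
    (needed to transform future samples identically).
    """
    config = config or PipelineConfig()
    rel = to_relative_abundance(reference_raw)
    if min_prevalence > 0:
        rel = prevalence_filter(rel, min_prevalence)
    pseudocount = config.pseudocount or default_pseudocount(rel)
    if config.transform == "relative":
        transformed = rel.with_data(rel.data, state="transformed")
    else:
        transformed = transform(rel, method=config.transform, pseudocount=pseudocount)
    model = fit_reference_model(
        transformed,
        variance_target=config.variance_target,
        alpha=config.alpha,
        autoscale=False,
        n_components=n_components,
    )
    return model, pseudocount


def score_raw(
    model: ReferenceModel,
    samples_raw: AbundanceTable,
    pseudocount: float,
    config: PipelineConfig | None = None,
) -> DIScoreSet:
    """Score raw-count samples against a fitted model.

    Features absent from the model are dropped before closure so the
    compositional denominator matches the reference space.
    """
    config = config or PipelineConfig()
    have = set(samples_raw.feature_ids)
    missing = [f for f in model.feature_ids if f not in have]
    if missing:
        raise ValueError(f"samples lack model features: {missing[:10]}")
    restricted = samples_raw.with_data(samples_raw.data.loc[:, model.feature_ids])
    rel = to_relative_abundance(restricted)
    if config.transform == "relative":
        transformed = rel.with_data(rel.data, state="transformed")
    else:
        transformed = transform(rel, method=config.transform, pseudocount=pseudocount)
    return score_samples(model, transformed)


def score_trial(
    trial,
    config: PipelineConfig | None = None,
    arms: tuple | None = None,
) -> tuple[ReferenceModel, DIScoreSet, SampleMetadata]:
    """Fit on the trial's HC_ref arm and score every other arm."""
    config = config or PipelineConfig()
    model, pseudocount = fit_normobiotic(trial.tables["HC_ref"], config)
    scores = score_raw(model, trial.combined(arms), pseudocount, config)
    return model, scores, trial.metadata
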