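"""Normalisation and transformation of abundance tables.

The chain the dysbiosis-index model expects is

    raw counts -> relative abundance (closure) -> [prevalence filter]
               -> CLR or log-relative transform

while the metabolite-style helpers (:func:`min_impute`, :func:`log2_zscore`,
:func:`pareto_scale`) mirror the standard LC-MS preprocessing conventions:
minimum-value imputation for features missing in at most a given fraction of
samples, per-feature z-scores after log2, and Pareto scaling (centering and
division by the square root of the standard deviation).

All standard deviations use the sample (n-1) convention.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import AbundanceTable

__all__ = [
    "to_relative_abundance",
    "min_impute",
    "prevalence_filter",
    "transform",
    "default_pseudocount",
    "log2_zscore",
    "pareto_scale",
]

log = logging.getLogger("normodi")


def to_relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Close each sample (row) to sum 1. Idempotent and scale-invariant."""
    if table.state == "transformed":
        raise ValueError("cannot close a transformed table to relative abundance")
    if table.has_missing():
        raise ValueError("table has missing cells; impute before closure")
    values = table.values
    totals = values.sum(axis=1)
    zero = np.where(totals <= 0)[0]
    if zero.size:
        raise ValueError(f"sample {table.sample_ids[zero[0]]!r} has zero total abundance")
    rel = pd.DataFrame(
        values / totals[:, None], index=table.data.index, columns=table.data.columns
    )
    return AbundanceTable(rel, state="relative")


def min_impute(table: AbundanceTable, max_missing_fraction: float = 0.25) -> AbundanceTable:
    """Impute missing cells with each feature's minimum observed value.

    Features missing in more than ``max_missing_fraction`` of samples are
    dropped first (the count is logged). Observed values are never changed.
    """
    if not 0 <= max_missing_fraction <= 1:
        raise ValueError(f"max_missing_fraction must be in [0,1], got {max_missing_fraction}")
    frame = table.data
    n = len(frame)
    missing_frac = frame.isna().sum(axis=0) / n
    keep = missing_frac <= max_missing_fraction
    dropped = int((~keep).sum())
    if dropped:
        log.info("min_impute: dropped %d features missing in >%.0f%% of samples",
                 dropped, 100 * max_missing_fraction)
    kept = frame.loc[:, keep]
    all_missing = kept.columns[kept.isna().all(axis=0)]
    if len(all_missing):
        raise ValueError(
            f"feature {all_missing[0]!r} has no observed values; no minimum exists"
        )
    imputed = kept.fillna(kept.min(axis=0))
    return table.with_data(imputed)


def prevalence_filter(table: AbundanceTable, min_prevalence: float) -> AbundanceTable:
    """Keep features detected (nonzero) in at least ``min_prevalence`` of samples."""
    if not 0 <= min_prevalence <= 1:
        raise ValueError(f"min_prevalence must be in [0,1], got {min_prevalence}")
    if table.state != "relative":
        raise ValueError("prevalence_filter expects a relative-abundance table")
    prevalence = (table.data > 0).sum(axis=0) / len(table.data)
    keep = prevalence >= min_prevalence
    if not keep.any():
        raise ValueError(f"min_prevalence={min_prevalence} removes every feature")
    kept = table.data.loc[:, keep]
    # re-close rows so the relative-abundance invariant survives the drop
    totals = kept.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("prevalence filter left a sample with zero total abundance")
    return table.with_data(kept.div(totals, axis=0))


def default_pseudocount(table: AbundanceTable) -> float:
    """Half the smallest nonzero value in the table (multiplicative-replacement heuristic)."""
    values = table.values
    nonzero = values[values > 0]
    if nonzero.size == 0:
        raise ValueError("table has no nonzero values")
    return float(nonzero.min()) / 2.0


def transform(
    table: AbundanceTable, method: str = "clr", pseudocount: float | None = None
) -> AbundanceTable:
    """Log-transform a relative-abundance table for multivariate statistics.

    ``clr``: per sample, log(x + pseudocount) centered by its own mean — the
    centered log-ratio, whose rows sum to zero.  ``log-relative``: elementwise
    log(x + pseudocount).  ``pseudocount=None`` uses
    :func:`default_pseudocount`.
    """
    if method not in ("clr", "log-relative"):
        raise ValueError(f"unknown transform method {method!r}")
    if table.state != "relative":
        raise ValueError("transform expects a relative-abundance table (close first)")
    if pseudocount is None:
        pseudocount = default_pseudocount(table)
    if not pseudocount > 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    logged = np.log(table.values + pseudocount)
    if method == "clr":
        logged = logged - logged.mean(axis=1, keepdims=True)
    out = pd.DataFrame(logged, index=table.data.index, columns=table.data.columns)
    return AbundanceTable(out, state="transformed")


def _feature_sd(frame: pd.DataFrame) -> pd.Series:
    return frame.std(axis=0, ddof=1)


def log2_zscore(table: AbundanceTable) -> AbundanceTable:
    """Per-feature z-scores after log2 (columns end with mean 0, sd 1)."""
    if table.has_missing():
        raise ValueError("table has missing cells; impute before log2_zscore")
    if (table.values <= 0).any():
        raise ValueError("log2_zscore needs strictly positive values")
    logged = np.log2(table.data)
    sd = _feature_sd(logged)
    zero_var = sd.index[sd == 0]
    if len(zero_var):
        raise ValueError(f"feature {zero_var[0]!r} has zero variance after log2")
    z = (logged - logged.mean(axis=0)) / sd
    return AbundanceTable(z, state="transformed")


def pareto_scale(table: AbundanceTable) -> AbundanceTable:
    """Center each feature and divide by the square root of its standard deviation."""
    frame = table.data
    if not np.isfinite(frame.to_numpy(dtype=float)).all():
        raise ValueError("pareto_scale needs finite values")
    sd = _feature_sd(frame)
    zero_var = sd.index[sd == 0]
    if len(zero_var):
        raise ValueError(f"feature {zero_var[0]!r} has zero variance")
    scaled = (frame - frame.mean(axis=0)) / np.sqrt(sd)
    return AbundanceTable(scaled, state="transformed")
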