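"""The normobiotic reference model and Dysbiosis Index (DI) scoring.

A PCA model is fit on transformed abundance profiles of healthy-control
samples only.  Any sample is then scored by two complementary statistics
from multivariate statistical process control:

* Hotelling's T² — the Mahalanobis distance inside the retained
  k-dimensional principal-component score space, ``sum_i t_i^2 / lambda_i``;
* Q (squared prediction error) — the squared norm of the residual left after
  projecting the sample onto the retained components.

Each statistic has a (1-alpha) confidence limit under the reference model:
the T² limit comes from the F distribution for a new observation,

    T2_lim = k (n-1)(n+1) / (n (n-k)) * F_{1-alpha}(k, n-k),

and the Q limit from the Jackson-Mudholkar approximation built on the
discarded eigenvalues.  The Dysbiosis Index combines both exceedance ratios,

    DI = (T^2 / T2_lim + Q / Q_lim) / 2,

so DI > 1 means the sample sits outside the normobiotic confidence range on
average.  When the model retains the full rank of the reference data there
is no residual space (theta_1 = 0); Q scoring is then disabled and
DI = T^2 / T2_lim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AbundanceTable, SampleMetadata
from .group_stats import TestResult, dunn_posthoc, kruskal_wallis

__all__ = [
    "ReferenceModel",
    "DIScoreSet",
    "fit_reference_model",
    "score_samples",
    "di_between_groups",
    "save_model",
    "load_model",
]

log = logging.getLogger("normodi")

MIN_REFERENCE_SIZE = 10


@dataclass
class ReferenceModel:
    """Fitted normobiotic PCA model.

    ``loadings`` is d x k with orthonormal columns; ``eigenvalues`` holds the
    variances of all d principal components (zero-padded past the rank);
    ``center``/``scale`` were computed on the reference samples only.
    """

    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    k: int
    n_ref: int
    alpha: float
    t2_limit: float
    q_limit: float
    feature_ids: list
    autoscale: bool = False

    @property
    def q_enabled(self) -> bool:
        return self.q_limit > 0

    def validate(self) -> None:
        d = len(self.feature_ids)
        if self.loadings.shape != (d, self.k):
            raise ValueError("loadings shape inconsistent with feature count and k")
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(self.k), atol=1e-8):
            raise ValueError("loadings columns are not orthonormal")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues are not non-increasing")
        if not self.t2_limit > 0:
            raise ValueError("t2_limit must be positive")


@dataclass
class DIScoreSet:
    """Per-sample T², Q, DI and out-of-limit flags."""

    frame: pd.DataFrame  # columns: T2, Q, DI, outside_T2, outside_Q

    @property
    def sample_ids(self) -> list:
        return self.frame.index.tolist()

    @property
    def di(self) -> pd.Series:
        return self.frame["DI"]


def _jackson_mudholkar_limit(residual_eigenvalues: np.ndarray, alpha: float) -> float:
    """(1-alpha) limit for the squared prediction error Q.

    Uses theta_i = sum_j lambda_j^i over the discarded components and
    h0 = 1 - 2 theta1 theta3 / (3 theta2^2). Returns 0 when no residual
    variance exists.
    """
    lam = residual_eigenvalues[residual_eigenvalues > 0]
    theta1 = float(np.sum(lam))
    if theta1 <= 0:
        return 0.0
    theta2 = float(np.sum(lam**2))
    theta3 = float(np.sum(lam**3))
    h0 = 1.0 - 2.0 * theta1 * theta3 / (3.0 * theta2**2)
    z = stats.norm.ppf(1.0 - alpha)
    inner = (
        z * np.sqrt(2.0 * theta2 * h0**2) / theta1
        + 1.0
        + theta2 * h0 * (h0 - 1.0) / theta1**2
    )
    if inner <= 0:  # pathological spectrum; fall back to the mean residual power
        return theta1
    return float(theta1 * inner ** (1.0 / h0))


def t2_limit_for(n_ref: int, k: int, alpha: float) -> float:
    """Hotelling T² (1-alpha) limit for a new observation against the model."""
    f = stats.f.ppf(1.0 - alpha, k, n_ref - k)
    return float(k * (n_ref - 1) * (n_ref + 1) / (n_ref * (n_ref - k)) * f)


def fit_reference_model(
    reference: AbundanceTable,
    variance_target: float = 0.90,
    alpha: float = 0.05,
    autoscale: bool = False,
    n_components: int | None = None,
) -> ReferenceModel:
    """Fit the normobiotic PCA model on (transformed) reference samples.

    ``n_components`` forces the retained count k (up to the matrix rank);
    otherwise k is the smallest count whose cumulative explained variance
    reaches ``variance_target``, capped at ``n_ref - 2``.
    """
    if not 0 < variance_target <= 1:
        raise ValueError(f"variance_target must be in (0,1], got {variance_target}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    X = reference.values
    n, d = X.shape
    if n < MIN_REFERENCE_SIZE:
        raise ValueError(
            f"reference has {n} samples; minimum reference size is {MIN_REFERENCE_SIZE}"
        )
    center = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    nonzero_var = int(np.sum(sd > 0))
    if nonzero_var < 2:
        raise ValueError("need at least 2 features with nonzero variance")
    if autoscale:
        if np.any(sd == 0):
            j = int(np.argmin(sd))
            raise ValueError(
                f"autoscale with zero-variance feature {reference.feature_ids[j]!r}"
            )
        scale = sd.copy()
    else:
        scale = np.ones(d)

    Xc = (X - center) / scale
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = np.zeros(d)
    eigenvalues[: s.size] = s**2 / (n - 1)
    rank = int(np.sum(s > s[0] * max(n, d) * np.finfo(float).eps)) if s.size else 0
    if rank < 1:
        raise ValueError("reference matrix has zero variance")

    if n_components is not None:
        if not 1 <= n_components <= rank:
            raise ValueError(f"n_components must be in [1, rank={rank}], got {n_components}")
        k = int(n_components)
    else:
        explained = np.cumsum(eigenvalues[:rank]) / eigenvalues.sum()
        k = int(np.searchsorted(explained, variance_target - 1e-12) + 1)
        k = min(k, rank, n - 2)
        k = max(k, 1)

    loadings = Vt[:k].T  # d x k, orthonormal columns
    # deterministic sign: largest-magnitude entry of each column made positive
    signs = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(k)])
    signs[signs == 0] = 1.0
    loadings = loadings * signs

    t2_limit = t2_limit_for(n, k, alpha)
    q_limit = _jackson_mudholkar_limit(eigenvalues[k:], alpha)
    if q_limit == 0:
        log.warning("no residual variance beyond k=%d; Q scoring disabled", k)

    model = ReferenceModel(
        center=center,
        scale=scale,
        loadings=loadings,
        eigenvalues=eigenvalues,
        k=k,
        n_ref=n,
        alpha=alpha,
        t2_limit=t2_limit,
        q_limit=q_limit,
        feature_ids=list(reference.feature_ids),
        autoscale=autoscale,
    )
    model.validate()
    log.info(
        "fit reference model: n_ref=%d, d=%d, k=%d, t2_limit=%.4g, q_limit=%.4g",
        n, d, k, t2_limit, q_limit,
    )
    return model


def score_samples(model: ReferenceModel, samples: AbundanceTable) -> DIScoreSet:
    """Score samples against the reference model (T², Q, DI, flags).

    Feature sets must match the model's; columns are reordered to the
    model's order, and any mismatch is an error listing the difference.
    """
    have = set(samples.feature_ids)
    want = set(model.feature_ids)
    if have != want:
        missing = sorted(want - have)
        extra = sorted(have - want)
        raise ValueError(
            f"feature mismatch with model: missing={missing[:10]} extra={extra[:10]}"
        )
    X = samples.data.loc[:, model.feature_ids].to_numpy(dtype=float)
    Xc = (X - model.center) / model.scale
    scores = Xc @ model.loadings  # n x k
    lam = model.eigenvalues[: model.k]
    t2 = np.sum(scores**2 / lam, axis=1)
    residual = Xc - scores @ model.loadings.T
    q = np.sum(residual**2, axis=1)
    if model.q_enabled:
        di = 0.5 * (t2 / model.t2_limit + q / model.q_limit)
        outside_q = q > model.q_limit
    else:
        di = t2 / model.t2_limit
        outside_q = np.zeros(len(q), dtype=bool)
    frame = pd.DataFrame(
        {
            "T2": t2,
            "Q": q,
            "DI": di,
            "outside_T2": t2 > model.t2_limit,
            "outside_Q": outside_q,
        },
        index=pd.Index(samples.sample_ids, name="sample_id"),
    )
    return DIScoreSet(frame)


def di_between_groups(
    scores: DIScoreSet,
    metadata: SampleMetadata,
    adjustment: str = "bonferroni",
) -> dict:
    """Kruskal-Wallis + Dunn post-hoc comparison of DI values across groups.

    Returns ``{"kruskal_wallis": TestResult, "dunn": [TestResult, ...],
    "groups": labels}``; each Dunn result carries its pair of group labels.
    """
    groups_series = metadata.groups_for(scores.sample_ids)
    labels = [g for g in metadata.group_labels() if g in set(groups_series)]
    vectors = [scores.di[groups_series == g].to_numpy() for g in labels]
    for label, v in zip(labels, vectors):
        if v.size < 2:
            raise ValueError(f"group {label!r} has fewer than 2 samples")
    kw = kruskal_wallis(vectors)
    dunn = dunn_posthoc(vectors, adjustment=adjustment, labels=labels)
    return {"kruskal_wallis": kw, "dunn": dunn, "groups": labels}


# -- model persistence (plain-text: key-value header + TSV blocks) -----------

_MODEL_MAGIC = "#normodi-model\tv1"


def save_model(model: ReferenceModel, path: str | Path, extras: dict | None = None) -> None:
    """Write the model as plain text; ``extras`` are free-form key-value
    strings (e.g. the pipeline pseudocount) stored with an ``x-`` prefix."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [_MODEL_MAGIC]
    for key in ("n_ref", "k", "alpha", "t2_limit", "q_limit"):
        lines.append(f"{key}\t{getattr(model, key)!r}")
    lines.append(f"autoscale\t{int(model.autoscale)}")
    for key, value in (extras or {}).items():
        lines.append(f"x-{key}\t{value}")
    lines.append("eigenvalues\t" + "\t".join(repr(float(v)) for v in model.eigenvalues))
    header = ["feature_id", "center", "scale"] + [f"PC{i+1}" for i in range(model.k)]
    lines.append("\t".join(header))
    for j, fid in enumerate(model.feature_ids):
        row = [str(fid), repr(float(model.center[j])), repr(float(model.scale[j]))]
        row += [repr(float(v)) for v in model.loadings[j]]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def load_model(path: str | Path, with_extras: bool = False):
    text = Path(path).read_text().splitlines()
    if not text or text[0] != _MODEL_MAGIC:
        raise ValueError(f"{path}: not a normodi model file")
    meta: dict = {}
    extras: dict = {}
    i = 1
    eigenvalues = None
    while i < len(text):
        fields = text[i].split("\t")
        if fields[0] == "eigenvalues":
            eigenvalues = np.array([float(v) for v in fields[1:]])
            i += 1
        elif fields[0] == "feature_id":
            break
        elif fields[0].startswith("x-"):
            extras[fields[0][2:]] = fields[1]
            i += 1
        else:
            meta[fields[0]] = fields[1]
            i += 1
    if eigenvalues is None:
        raise ValueError(f"{path}: eigenvalues line missing")
    k = int(meta["k"])
    feature_ids: list = []
    center, scale, rows = [], [], []
    for line in text[i + 1 :]:
        if not line.strip():
            continue
        fields = line.split("\t")
        feature_ids.append(fields[0])
        center.append(float(fields[1]))
        scale.append(float(fields[2]))
        rows.append([float(v) for v in fields[3:]])
    model = ReferenceModel(
        center=np.array(center),
        scale=np.array(scale),
        loadings=np.array(rows).reshape(len(feature_ids), k),
        eigenvalues=eigenvalues,
        k=k,
        n_ref=int(meta["n_ref"]),
        alpha=float(meta["alpha"]),
        t2_limit=float(meta["t2_limit"]),
        q_limit=float(meta["q_limit"]),
        feature_ids=feature_ids,
        autoscale=bool(int(meta["autoscale"])),
    )
    model.validate()
    if with_extras:
        return model, extras
    return model
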