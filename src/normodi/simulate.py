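"""Synthetic four-arm microbiome trial generator.

Emulates the statistical structure the dysbiosis-index analysis assumes:

* a healthy reference cohort (HC_ref, default n=50) used to fit the
  normobiotic model and a held-out healthy test cohort (HC_test, n=30);
* two dysbiotic arms (NIP n=57, Placebo n=21) in which a chosen fraction of
  taxa receive a signed log-scale shift delta — half upward
  (opportunist-like) and half downward (beneficial-like);
* an intervention arm (Synbiotic, n=29) in which a fraction ``reversion`` of
  the shift has been undone.

Per-taxon latent log-abundances are normal around long-tailed baseline means
(log-normal rank-abundance); per-sample counts are multinomial draws from the
softmax of the latent vector, so compositional closure and count
overdispersion both emerge naturally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AbundanceTable, SampleMetadata

__all__ = ["TrialDesign", "SyntheticTrial", "generate_trial", "generate_correlated_metabolites"]

ARM_ORDER = ("HC_ref", "HC_test", "NIP", "Placebo", "Synbiotic")


@dataclass
class TrialDesign:
    """Generator settings; defaults follow the four-arm trial layout."""

    n_taxa: int = 100
    n_hc_ref: int = 50
    n_hc_test: int = 30
    n_nip: int = 57
    n_placebo: int = 21
    n_synbiotic: int = 29
    shift_fraction: float = 0.2
    shift_magnitude: float = 1.0  # delta, log scale
    reversion: float = 0.7  # rho, fraction of delta undone under intervention
    depth: int = 50_000
    latent_sd: float = 0.5
    baseline_sd: float = 2.0  # spread of per-taxon baseline log-means
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = self.arm_sizes()
        for arm, n in sizes.items():
            if n < 2:
                raise ValueError(f"arm {arm} needs >= 2 samples, got {n}")
        if self.n_taxa < 2:
            raise ValueError("need at least 2 taxa")
        if not 0 < self.shift_fraction <= 1:
            raise ValueError(f"shift_fraction must be in (0,1], got {self.shift_fraction}")
        if self.shift_magnitude < 0:
            raise ValueError("shift_magnitude must be >= 0")
        if not 0 <= self.reversion <= 1:
            raise ValueError(f"reversion must be in [0,1], got {self.reversion}")
        if round(self.shift_fraction * self.n_taxa) < 2:
            raise ValueError(
                "shift_fraction * n_taxa < 2: need at least one taxon per direction"
            )

    def arm_sizes(self) -> dict:
        return {
            "HC_ref": self.n_hc_ref,
            "HC_test": self.n_hc_test,
            "NIP": self.n_nip,
            "Placebo": self.n_placebo,
            "Synbiotic": self.n_synbiotic,
        }


@dataclass
class SyntheticTrial:
    tables: dict  # arm label -> AbundanceTable (raw counts)
    metadata: SampleMetadata
    truth: pd.DataFrame  # taxon, delta (signed log-scale shift); affected taxa only
    design: TrialDesign = field(repr=False, default=None)

    def combined(self, arms: tuple | None = None) -> AbundanceTable:
        """One table stacking the requested arms (all non-reference by default)."""
        arms = arms or tuple(a for a in ARM_ORDER if a != "HC_ref")
        data = pd.concat([self.tables[a].data for a in arms], axis=0)
        return AbundanceTable(data, state="raw")


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def generate_trial(design: TrialDesign) -> SyntheticTrial:
    """Draw a complete trial; identical design (incl. seed) gives identical output."""
    rng = np.random.default_rng(design.seed)
    d = design.n_taxa
    taxa = [f"taxon_{i:04d}" for i in range(d)]

    baseline = rng.normal(0.0, design.baseline_sd, size=d)

    n_shift = int(round(design.shift_fraction * d))
    affected = rng.choice(d, size=n_shift, replace=False)
    signs = np.ones(n_shift)
    signs[n_shift // 2 :] = -1.0  # half opportunist-like (up), half beneficial-like (down)
    delta = np.zeros(d)
    delta[affected] = signs * design.shift_magnitude

    arm_shift = {
        "HC_ref": 0.0,
        "HC_test": 0.0,
        "NIP": 1.0,
        "Placebo": 1.0,
        "Synbiotic": 1.0 - design.reversion,
    }

    tables: dict = {}
    meta: dict = {}
    for arm in ARM_ORDER:
        n = design.arm_sizes()[arm]
        mean = baseline + arm_shift[arm] * delta
        latent = mean + rng.normal(0.0, design.latent_sd, size=(n, d))
        probs = _softmax(latent)
        counts = np.vstack([rng.multinomial(design.depth, p) for p in probs])
        ids = [f"{arm}_{i:03d}" for i in range(n)]
        tables[arm] = AbundanceTable(
            pd.DataFrame(counts, index=pd.Index(ids, name="sample_id"), columns=taxa),
            state="raw",
        )
        for s in ids:
            meta[s] = arm

    truth = pd.DataFrame(
        {"taxon": [taxa[i] for i in affected], "delta": delta[affected]}
    ).sort_values("taxon", ignore_index=True)
    return SyntheticTrial(
        tables=tables,
        metadata=SampleMetadata.from_mapping(meta),
        truth=truth,
        design=design,
    )


def generate_correlated_metabolites(
    trial: SyntheticTrial,
    n_metabolites: int,
    linked_pairs: list[tuple] = (),
    seed: int = 0,
    arms: tuple | None = None,
) -> AbundanceTable:
    """Metabolite table over the trial's samples, linked to taxa via a copula.

    ``linked_pairs`` holds (taxon_id, metabolite_id, target Spearman rho)
    triples; the metabolite is generated from the taxon's normal scores with
    the latent Pearson correlation 2 sin(pi rho / 6), the Gaussian-copula
    inverse of the Spearman value, so the realized rank correlation matches
    the target.  Unlinked metabolites are independent log-normal noise.
    """
    if n_metabolites < 1:
        raise ValueError("n_metabolites must be >= 1")
    combined = trial.combined(arms) if arms is not None else trial.combined()
    samples = combined.data.index
    n = len(samples)
    rng = np.random.default_rng(seed)
    met_ids = [f"metabolite_{i:04d}" for i in range(n_metabolites)]
    latent = rng.normal(size=(n, n_metabolites))

    rel = combined.values / combined.values.sum(axis=1, keepdims=True)
    taxa_index = {t: i for i, t in enumerate(combined.feature_ids)}
    met_index = {m: i for i, m in enumerate(met_ids)}
    from scipy import stats as _stats

    for taxon, metabolite, rho in linked_pairs:
        if taxon not in taxa_index:
            raise KeyError(f"taxon {taxon!r} not in trial feature set")
        if metabolite not in met_index:
            raise KeyError(f"metabolite {metabolite!r} not among generated metabolites")
        if not abs(rho) < 1:
            raise ValueError(f"target rho must satisfy |rho| < 1, got {rho}")
        # normal scores of the taxon's abundances; ties broken by rank midpoints
        ranks = _stats.rankdata(rel[:, taxa_index[taxon]])
        u = _stats.norm.ppf(ranks / (n + 1))
        u = (u - u.mean()) / u.std(ddof=0)
        r = 2.0 * np.sin(np.pi * rho / 6.0)
        j = met_index[metabolite]
        latent[:, j] = r * u + np.sqrt(1.0 - r**2) * rng.normal(size=n)

    values = np.exp(latent)  # strictly positive concentrations
    return AbundanceTable(
        pd.DataFrame(values, index=samples, columns=met_ids), state="raw"
    )
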