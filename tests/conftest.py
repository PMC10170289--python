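import numpy as np
import pandas as pd
import pytest

from normodi import AbundanceTable, SampleMetadata, TrialDesign, generate_trial


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def count_table(rng):
    """Seeded 20-sample x 50-feature raw count table."""
    counts = rng.poisson(40, size=(20, 50)).astype(float)
    counts[0, 0] += 1  # guarantee a positive total everywhere
    return AbundanceTable(
        pd.DataFrame(
            counts,
            index=[f"s{i:02d}" for i in range(20)],
            columns=[f"f{j:02d}" for j in range(50)],
        ),
        state="raw",
    )


@pytest.fixture
def transformed_table(rng):
    """Seeded 50-sample x 20-feature table in transformed space (MVN-ish)."""
    values = rng.standard_normal((50, 20)) @ np.diag(np.linspace(3.0, 0.3, 20))
    return AbundanceTable(
        pd.DataFrame(
            values,
            index=[f"s{i:02d}" for i in range(50)],
            columns=[f"f{j:02d}" for j in range(20)],
        ),
        state="transformed",
    )


@pytest.fixture
def two_group_metadata():
    return SampleMetadata.from_mapping(
        {f"s{i:02d}": ("A" if i < 10 else "B") for i in range(20)}
    )


@pytest.fixture(scope="session")
def small_trial():
    """A small synthetic trial shared across read-only tests."""
    return generate_trial(
        TrialDesign(
            n_taxa=40,
            n_hc_ref=30,
            n_hc_test=12,
            n_nip=15,
            n_placebo=10,
            n_synbiotic=12,
            depth=20_000,
            shift_magnitude=1.5,
            reversion=0.8,
            seed=7,
        )
    )
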