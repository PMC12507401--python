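import numpy as np
import pandas as pd
import pytest

from guildaging.io import OtuTable
from guildaging.synth import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """120 samples x 60 OTUs with 4 planted guilds; shared across tests."""
    cfg = SynthConfig(
        n_samples=120,
        n_otus=60,
        n_guilds=4,
        guild_size_range=(8, 12),
        sequencing_depth_range=(2000, 4000),
        seed=11,
    )
    table, meta, truth = generate_cohort(cfg)
    return cfg, table, meta, truth


@pytest.fixture()
def toy_table():
    """3 samples x 4 OTUs with simple hand-checkable counts."""
    counts = pd.DataFrame(
        [[1, 4, 2, 0], [2, 2, 2, 1], [4, 1, 2, 3]],
        index=["s1", "s2", "s3"],
        columns=["otuA", "otuB", "otuC", "otuD"],
    )
    return OtuTable(counts)


def independent_basis_table(n: int, p: int, seed: int, scale: float = 1e5) -> OtuTable:
    """Counts from independent log-normal bases closed to a composition."""
    rng = np.random.default_rng(seed)
    basis = np.exp(rng.normal(0.0, 1.0, size=(n, p)))
    frac = basis / basis.sum(axis=1, keepdims=True)
    counts = np.round(frac * scale).astype(np.int64) + 1
    return OtuTable(
        pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(n)],
            columns=[f"o{j}" for j in range(p)],
        )
    )
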