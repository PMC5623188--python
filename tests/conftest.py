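import numpy as np
import pandas as pd
import pytest

from ganglioseq import SimConfig, generate_counts

NULL_PROPORTIONS = {
    "common": 1.0,
    "de_up_a": 0.0,
    "de_up_b": 0.0,
    "exclusive_a": 0.0,
    "exclusive_b": 0.0,
    "glial_contaminant": 0.0,
    "silent": 0.0,
}


def null_config(n_genes=2000, dispersion=0.2, seed=0, **kw):
    """Two identical NB conditions: no true differences of any kind."""
    return SimConfig(
        n_genes=n_genes,
        class_proportions=dict(NULL_PROPORTIONS),
        dispersion=dispersion,
        seed=seed,
        **kw,
    )


@pytest.fixture(scope="session")
def small_experiment():
    """A mixed 800-gene experiment reused by read-only tests."""
    return generate_counts(SimConfig(n_genes=800, seed=3))


@pytest.fixture
def toy_counts():
    """3 genes x 4 samples, all positive, with sample S2 = 2 x S1."""
    return pd.DataFrame(
        {
            "S1": [10, 20, 40],
            "S2": [20, 40, 80],
            "S3": [10, 20, 40],
            "S4": [12, 24, 48],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )


@pytest.fixture
def toy_conditions(toy_counts):
    return pd.Series(["A", "A", "B", "B"], index=toy_counts.columns)


def brute_force_bh(p):
    """Independent step-up BH oracle: per-definition, O(n^2)-naive."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * m / rank_from_top)
        adjusted[idx] = running_min
    return np.minimum(adjusted, 1.0)
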