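import numpy as np
import pandas as pd
import pytest

from hetfix.config import SimConfig, TraitConfig
from hetfix.genotypes import GenotypeMatrix, default_marker_table
from hetfix.sim import simulate_study


def make_genotypes(calls, ids=None, n_chromosomes=1):
    """GenotypeMatrix from a plain dosage array (rows = individuals)."""
    calls = np.asarray(calls, dtype=np.int8)
    if ids is None:
        ids = [f"ind{i}" for i in range(calls.shape[0])]
    markers = default_marker_table(
        [f"m{j}" for j in range(calls.shape[1])], n_chromosomes)
    return GenotypeMatrix(list(ids), markers, calls)


def small_sim_config(**overrides) -> SimConfig:
    """A quick-to-simulate study emulating the real design at reduced scale."""
    base = dict(
        n_elite_founders=12,
        n_exotic_founders=2,
        n_elite_ancestors=4,
        n_markers=1000,
        n_chromosomes=4,
        divergence=0.2,
        n_elite_hybrids=60,
        n_exotic_hybrids=25,
        n_selfed_parents=4,
        n_s1_offspring=10,
        n_harvests=1,
        seed=11,
        traits=[
            TraitConfig("yield", 60, 1.0, 0.8, 0.2, 0.3, 50.0,
                        0.2, 0.5, 0.5, 2.0, "sum"),
            TraitConfig("anc", 40, 1.0, 0.0, 0.2, 0.0, 100.0,
                        0.2, 0.5, 0.5, 2.0, "mean", qtl_balanced=True),
        ],
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_study():
    """One simulated study bundle shared across tests (read-only)."""
    cfg = small_sim_config()
    G, truth, records = simulate_study(cfg)
    return cfg, G, truth, records


def wc_fst(calls_a: np.ndarray, calls_b: np.ndarray) -> float:
    """Weir & Cockerham theta for two samples of dosage genotypes.

    Independent oracle used to check the simulator's divergence machinery.
    """
    counts = []
    for calls in (calls_a, calls_b):
        c = np.asarray(calls, float)
        n = c.shape[0]
        p = c.mean(axis=0) / 2.0
        h = (c == 1).mean(axis=0)
        counts.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = counts
    r = 2.0
    nbar = (n1 + n2) / 2.0
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2
        - ((2 * nbar - 1) / (4 * nbar)) * hbar)
    c = hbar / 2.0
    keep = (a + b + c) > 0
    return float(a[keep].sum() / (a + b + c)[keep].sum())
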