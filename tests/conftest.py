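import numpy as np
import pandas as pd
import pytest

from demesweep.panel import GenotypePanel, PopulationMap


def make_panel(genotypes, chrom=None, pos=None, haplotypes=None, phased=False,
               samples=None):
    """Build a panel from a (variants x samples) dosage array."""
    g = np.asarray(genotypes, dtype=np.int8)
    m, n = g.shape
    if chrom is None:
        chrom = ["1"] * m
    if pos is None:
        pos = (np.arange(m) + 1) * 1000
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    variants = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "ref": "A", "alt": "B"}
    )
    return GenotypePanel(
        variants=variants, samples=samples, genotypes=g,
        haplotypes=haplotypes, phased=phased,
    )


def make_popmap(assignments):
    """assignments: list of (sample, population, role)."""
    return PopulationMap(
        assignments=pd.DataFrame(
            assignments, columns=["sample_id", "population", "role"]
        )
    )


@pytest.fixture
def small_panel():
    rng = np.random.default_rng(7)
    g = rng.integers(0, 3, size=(40, 12)).astype(np.int8)
    return make_panel(g)


@pytest.fixture
def two_pop_panel():
    """Two diverged populations of 10 samples, 60 variants."""
    rng = np.random.default_rng(3)
    p_a = rng.uniform(0.05, 0.95, size=60)
    shift = rng.uniform(-0.4, 0.4, size=60)
    p_b = np.clip(p_a + shift, 0.02, 0.98)
    g_a = rng.binomial(2, p_a[:, None], size=(60, 10))
    g_b = rng.binomial(2, p_b[:, None], size=(60, 10))
    panel = make_panel(np.hstack([g_a, g_b]).astype(np.int8))
    popmap = make_popmap(
        [(f"s{i}", "A" if i < 10 else "B", "focal") for i in range(20)]
    )
    return panel, popmap
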