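import numpy as np
import pandas as pd
import pytest

from finepop import simdata
from finepop.genio import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_genotypes(calls, chrom=None, cm=None, bp=None, pops=None, ids=None):
    """Small GenotypeMatrix builder for hand-constructed fixtures."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    snp_meta = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["1"] * m,
            "id": [f"snp{j}" for j in range(m)],
            "cm": cm if cm is not None else np.arange(m, dtype=float),
            "bp": bp if bp is not None else np.arange(1, m + 1) * 1000,
            "a1": "A",
            "a2": "G",
        }
    )
    sample_meta = pd.DataFrame(
        {
            "id": ids if ids is not None else [f"ind{i}" for i in range(n)],
            "population": pops if pops is not None else ["POP"] * n,
        }
    )
    return GenotypeMatrix(calls, snp_meta, sample_meta)


@pytest.fixture
def two_pop_panel():
    """Two Balding-Nichols populations (F = 0.05), 40 diploids each."""
    rng = np.random.default_rng(7)
    anc = rng.uniform(0.1, 0.9, size=2000)
    freqs = simdata.simulate_source_freqs(anc, np.array([0.05, 0.05]), rng)
    meta = simdata.default_snp_meta(2000, 1, 1.0)
    pan0, _ = simdata.simulate_panel(freqs[0], 40, rng, meta, "P0")
    pan1, _ = simdata.simulate_panel(freqs[1], 40, rng, meta, "P1")
    return pan0.concat_individuals(pan1)
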