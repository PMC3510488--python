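import numpy as np
import pandas as pd
import pytest

from nucphase import (
    ArraySimConfig,
    FragmentSet,
    GenomeSeq,
    simulate_arrays,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_fragments(rows) -> FragmentSet:
    """rows: iterable of (chrom, start, end) tuples."""
    return FragmentSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


@pytest.fixture()
def iid_genome():
    """A 60% AT i.i.d. 50-kb genome (fixed seed)."""
    r = np.random.default_rng(77)
    is_w = r.random(50_000) < 0.6
    half = r.random(50_000) < 0.5
    codes = np.where(is_w, np.where(half, ord("A"), ord("T")),
                     np.where(half, ord("G"), ord("C"))).astype(np.uint8)
    return GenomeSeq({"chrI": codes.tobytes().decode("ascii")})


@pytest.fixture(scope="session")
def arrays_162():
    """Cell ensemble with 162-bp spacing and rotational cluster jitter."""
    cfg = ArraySimConfig.uniform(spacing=162, n_cells=2000, seed=42)
    return simulate_arrays(cfg)
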