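import numpy as np
import pandas as pd
import pytest

from methdev import calls as mcalls
from methdev import simulate as msim

CALL_COLUMNS = ["chrom", "pos", "strand", "n_meth", "n_unmeth", "context"]


def make_calls(rows, destranded=False):
    """Build a call table from (chrom, pos, strand, n_meth, n_unmeth[, context]) tuples."""
    full = [tuple(r) + ("CpG",) * (6 - len(r)) for r in rows]
    df = pd.DataFrame(full, columns=CALL_COLUMNS)
    df["pos"] = df["pos"].astype(np.int64)
    df["n_meth"] = df["n_meth"].astype(np.int64)
    df["n_unmeth"] = df["n_unmeth"].astype(np.int64)
    df.attrs["destranded"] = destranded
    return df


def random_stranded_calls(rng, n=200, chroms=("chr1", "chr2")):
    """Random strand-resolved CpG-context table for conservation properties."""
    rows = []
    for chrom in chroms:
        pos = np.sort(rng.choice(np.arange(2, 5000, 2), size=n // len(chroms), replace=False))
        for p in pos:
            rows.append((chrom, int(p), "+", int(rng.integers(0, 20)), int(rng.integers(0, 20))))
            if rng.random() < 0.8:
                rows.append((chrom, int(p) + 1, "-", int(rng.integers(0, 20)),
                             int(rng.integers(0, 20))))
    return make_calls(rows)


@pytest.fixture(scope="session")
def small_study():
    """One shared scaled-down synthetic study with planted truth (seed fixed)."""
    return msim.simulate_study(msim.demo_study(), seed=20)
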