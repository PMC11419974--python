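import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from bless.io import GenotypeMatrix, SampleTable

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def bh_bruteforce(p):
    """Benjamini–Hochberg from the definition: adj_(i) = min_{k>=i} m*p_(k)/k,
    capped at 1, mapped back to input order."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        running = min(running, m * p[order[i]] / (i + 1))
        adj_sorted[i] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


@pytest.fixture
def tiny_genotypes():
    """4 samples x 3 SNPs, one missing call, hand-checkable."""
    dosages = np.array([
        [0.0, 1.0, 2.0],
        [1.0, 1.0, 0.0],
        [2.0, np.nan, 1.0],
        [0.0, 0.0, 1.0],
    ])
    return GenotypeMatrix(["s1", "s2", "s3", "s4"],
                          ["rs1", "rs2", "rs3"], dosages)


@pytest.fixture
def tiny_samples():
    df = pd.DataFrame(
        {"cdr": [0.0, 0.5, 1.0, 0.0],
         "age": [70.0, 65.0, 80.0, 75.0],
         "apoe4": [0, 1, 1, 0]},
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample"),
    )
    return SampleTable(df, "cdr", ["age", "apoe4"])


def two_by_two_dataset():
    """80 samples, one binary SNP: y=1 in 10/40 at g=0 and 30/40 at g=1.

    Closed-form logistic coefficient ln(9) with SE sqrt(1/10+1/30+1/30+1/10).
    """
    g = np.repeat([0.0, 1.0], 40)
    y = np.concatenate([np.repeat([0, 1], [30, 10]), np.repeat([0, 1], [10, 30])])
    samples = [f"s{i}" for i in range(80)]
    G = GenotypeMatrix(samples, ["rsX"], g[:, None])
    S = SampleTable(pd.DataFrame({"y": y}, index=pd.Index(samples, name="sample")), "y")
    return G, S
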