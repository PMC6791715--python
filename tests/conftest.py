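import numpy as np
import pandas as pd
import pytest

import tempomod as tm


@pytest.fixture(scope="session")
def small_bundle():
    """400-gene synthetic bundle with all four latent classes."""
    return tm.simulate(tm.SimConfig(n_genes=400, seed=42))


@pytest.fixture(scope="session")
def small_et(small_bundle):
    b = small_bundle
    return tm.build_expression_table(b.counts, b.annotation, b.sheet)


@pytest.fixture(scope="session")
def small_calls(small_et):
    return tm.call_regulation(small_et)


@pytest.fixture(scope="session")
def dk1622_sheet():
    from tempomod.datasets import load_dk1622_sample_sheet

    return load_dk1622_sample_sheet()


def toy_expression_table(rep1, rep2, times=None, min_count=1000):
    """Single-gene ExpressionTable from two replicate RPKM trajectories.

    Counts are set high so the read filter never triggers unless asked.
    """
    rep1 = np.asarray(rep1, float)
    rep2 = np.asarray(rep2, float)
    times = list(times) if times is not None else list(range(len(rep1)))
    cols = pd.MultiIndex.from_product([times, [1, 2]],
                                      names=["time_h", "replicate"])
    rpkm = pd.DataFrame([np.column_stack([rep1, rep2]).ravel()],
                        index=pd.Index(["g1"], name="gene_id"), columns=cols)
    counts = pd.DataFrame(min_count, index=rpkm.index, columns=cols, dtype=float)
    merged = pd.DataFrame([0.5 * (rep1 + rep2)], index=rpkm.index, columns=times)
    return tm.ExpressionTable(counts=counts, rpkm_rep=rpkm, rpkm_merged=merged,
                              library_sizes=pd.Series(1e6, index=cols))


@pytest.fixture
def make_toy_et():
    return toy_expression_table
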