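import numpy as np
import pandas as pd
import pytest

from genedep.profile import GeneCentricProfile


def make_profile(cn, gex, groups, genes=None, recurrence=None):
    """Build a small profile from row-lists / arrays and a group vector."""
    cn = np.atleast_2d(np.asarray(cn, float))
    gex = np.atleast_2d(np.asarray(gex, float))
    n_genes, n_samples = gex.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    sample_ids = [f"s{i}" for i in range(n_samples)]
    meta = pd.DataFrame({"group": list(groups)}, index=pd.Index(sample_ids, name="sample"))
    if recurrence is not None:
        meta["recurrence"] = recurrence
    gidx = pd.Index(genes, name="gene")
    return GeneCentricProfile(
        cn=pd.DataFrame(cn, index=gidx, columns=sample_ids),
        gex=pd.DataFrame(gex, index=gidx, columns=sample_ids),
        samples=meta,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def exact_stats_vector(mean, sd, n=6):
    """A vector with exactly the requested sample mean and ddof-1 SD."""
    base = np.arange(n, dtype=float)
    base -= base.mean()
    base /= base.std(ddof=1)
    return mean + sd * base
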