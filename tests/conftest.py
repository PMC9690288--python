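import numpy as np
import pandas as pd
import pytest

from erodescan import GenomeLayout, GenotypeMatrix, SampleMetadata


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_923)


@pytest.fixture
def small_layout():
    return GenomeLayout(
        scaffolds=(("scaf1", 40_000_000), ("scaf2", 40_000_000),
                   ("scaf3", 40_000_000), ("tiny", 20_000)),
        masked={"scaf1": np.array([[0, 100_000]])},
    )


def make_matrix(scaffold="scaf1", positions=None, calls=None, depth=None,
                quals=None, samples=None, indels=None):
    """Build a GenotypeMatrix from compact per-sample call lists."""
    calls = np.atleast_2d(np.asarray(calls, dtype=np.int8))
    n_samples, n_sites = calls.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 1000
    if depth is None:
        depth = np.full_like(calls, 20, dtype=np.int32)
    if quals is None:
        quals = np.full(n_sites, 60.0)
    if samples is None:
        samples = [f"ind{i}" for i in range(n_samples)]
    scaffolds = [scaffold] * n_sites if isinstance(scaffold, str) else list(scaffold)
    sites = pd.DataFrame({
        "scaffold": scaffolds, "pos": np.asarray(positions, dtype=np.int64),
        "ref": "A", "alt": "G", "qual": quals,
    })
    kwargs = {}
    if indels is not None:
        kwargs["indels"] = pd.DataFrame(indels, columns=["scaffold", "pos"])
    return GenotypeMatrix(sites=sites, calls=calls, depth=np.asarray(depth),
                         samples=list(samples), **kwargs)


def make_metadata(samples, coverage=30.0, population="pop"):
    return SampleMetadata(pd.DataFrame({
        "sample": list(samples),
        "population": population,
        "year": 2019,
        "mean_coverage": coverage,
    }))
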