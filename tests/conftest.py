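import numpy as np
import pytest

from epipersist.intervals import FeatureSet, GenomeLayout, make_tiling
from epipersist.pipeline import run_all
from epipersist.simulate import SimConfig


@pytest.fixture
def layout():
    return GenomeLayout.from_dict({"chr1": 10_000, "chr2": 8_000})


@pytest.fixture
def tiling100(layout):
    return make_tiling(layout, 100)


def random_features(rng, layout, n, max_len=400, label="feat"):
    rows = []
    for _ in range(n):
        ci = rng.integers(len(layout.names))
        chrom = layout.names[ci]
        length = int(rng.integers(1, max_len))
        start = int(rng.integers(0, layout.lengths[ci] - length))
        rows.append((chrom, start, start + length))
    import pandas as pd

    return FeatureSet(label, pd.DataFrame(rows, columns=["chrom", "start", "end"]))


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run at the shipped default conditions."""
    outdir = tmp_path_factory.mktemp("run")
    return run_all(SimConfig(seed=0), outdir), outdir
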