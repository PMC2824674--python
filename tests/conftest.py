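import numpy as np
import pandas as pd
import pytest

import themesurv as ts


@pytest.fixture
def small_matrix():
    """3 probes x 4 samples with one missing cell."""
    data = pd.DataFrame(
        [[1.0, 2.0, 4.0, 3.0], [0.5, np.nan, -0.5, 1.5], [-1.0, -2.0, 0.0, 2.0]],
        index=["pA", "pB", "pC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ts.ExpressionMatrix(data)


@pytest.fixture
def small_clinical():
    return ts.ClinicalTable(
        endpoint="OS",
        data=pd.DataFrame(
            {"time": [5.0, 3.0, 8.0, 1.0], "event": [1, 0, 1, 1]},
            index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
        ),
    )


@pytest.fixture(scope="session")
def null_dataset():
    """Small no-signal synthetic dataset, preprocessed and indexed for reuse."""
    spec = ts.SimulationSpec(n_genes=600, n_samples=50, seed=11)
    ds = ts.gen_null_dataset(spec)
    cfg = ts.PreprocessConfig()
    m = ts.preprocess_matrix(ds.expression, cfg)
    prep = ts.prepare_dataset(m, ds.probe_map, ds.clinical, cfg)
    universe = sorted(ds.probe_map.mapping)
    return ds, prep, universe
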