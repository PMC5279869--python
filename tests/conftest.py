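import numpy as np
import pandas as pd
import pytest

from ctxcausal.rppa_io import META_COLUMNS, Context, RppaDataset


def make_dataset(values, cell_line="MCF7", stimulus="EGF", inhibitor="DMSO",
                 times=None, replicate=None, batch="B1", scale="log2",
                 antibodies=None):
    """Small-dataset factory: one row per row of ``values``."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = len(values)
    times = [0.0] * n if times is None else times
    replicate = list(range(1, n + 1)) if replicate is None else replicate
    meta = pd.DataFrame(
        {
            "cell_line": [cell_line] * n if isinstance(cell_line, str) else cell_line,
            "stimulus": [stimulus] * n if isinstance(stimulus, str) else stimulus,
            "inhibitor": [inhibitor] * n if isinstance(inhibitor, str) else inhibitor,
            "time_min": times,
            "replicate": replicate,
            "batch": [batch] * n if isinstance(batch, str) else batch,
        }
    )[META_COLUMNS]
    cols = antibodies or [f"AB{j}" for j in range(values.shape[1])]
    return RppaDataset(meta, pd.DataFrame(values, columns=cols), scale=scale)


@pytest.fixture
def ctx():
    return Context("MCF7", "EGF")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
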