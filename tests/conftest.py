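import numpy as np
import pandas as pd
import pytest

from adaptomics.quant import TMT_CHANNELS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_psm_table(rng, n_genes=20, max_psms=4, set_id="set1", all_unique=False):
    """Small random PSM table with positive intensities."""
    rows = []
    k = 0
    for gi in range(n_genes):
        for _ in range(int(rng.integers(1, max_psms + 1))):
            row = {"psm_id": f"p{k}", "gene": f"G{gi:03d}",
                   "unique": True if all_unique else bool(rng.random() > 0.1),
                   "set_id": set_id}
            for ch in TMT_CHANNELS:
                row[ch] = float(rng.lognormal(10, 1))
            rows.append(row)
            k += 1
    return pd.DataFrame(rows)


@pytest.fixture
def psm_table(rng):
    return random_psm_table(rng)
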