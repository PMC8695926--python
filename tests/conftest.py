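import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import methvar as mv

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_dataset():
    """Compact simulated dataset: 40 genes, 2 tissues x 2 locations x 3 samples."""
    return mv.simulate_dataset(
        n_genes=40, samples_per_group=3, n_locations=2, n_noncpg_sites=200, seed=7
    )


@pytest.fixture(scope="session")
def small_tables(small_dataset):
    return small_dataset.site_tables()


@pytest.fixture(scope="session")
def small_matrix(small_dataset, small_tables):
    return mv.build_matrix(small_dataset.samples, small_dataset.genes, small_tables)


@pytest.fixture(scope="session")
def default_dataset():
    """Dataset under the default study conditions (2 tissues x 4 locations x 12)."""
    return mv.simulate_dataset(seed=11)


def make_sites(rows, columns=("scaffold", "position", "strand", "context", "meth_count", "total_count")):
    """Build a site table from plain tuples, adding the ratio column."""
    df = pd.DataFrame(rows, columns=list(columns))
    total = df["total_count"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        df["ratio"] = np.where(total > 0, df["meth_count"] / total, np.nan)
    return df
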