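import numpy as np
import pandas as pd
import pytest

from siderotrait.synthetic import SyntheticConfig, simulate_siderophore


@pytest.fixture
def rng():
    return np.random.default_rng(20240827)


@pytest.fixture
def small_config():
    """A cheap synthetic dataset: 4 groups x 3 replicates x 8 isolates."""
    return SyntheticConfig(seed=11, n_replicates=3, n_isolates=8)


@pytest.fixture
def small_isolates(small_config):
    return simulate_siderophore(small_config)


@pytest.fixture
def paper_scale_config():
    """Design and parameter scale used for recovery simulations."""
    return SyntheticConfig(
        seed=1,
        alpha=(0.49, 0.70),
        beta=(0.045, -0.04),
        sigma=(0.10, 0.07, 0.03, 0.035),
        tau=(0.02, 0.02, 0.02, 0.02),
    )


def make_isolate_table(values_by_cell: dict) -> pd.DataFrame:
    """Build an isolate table from {(isolate_type, copper, replicate): values}."""
    rows = []
    for (itype, copper, rep), values in values_by_cell.items():
        for i, v in enumerate(values):
            rows.append(
                {
                    "isolate_id": f"{itype}.{copper}.{rep}.{i}",
                    "microcosm_id": f"{itype}.{copper}.{rep}",
                    "replicate": rep,
                    "isolate_type": itype,
                    "copper": copper,
                    "siderophore": float(v),
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def cell_table_builder():
    return make_isolate_table
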