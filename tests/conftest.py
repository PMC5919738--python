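import numpy as np
import pytest

from aibayes import AlleleCountSet, BiasSpec, McmcSettings

# short chains for unit tests; statistical acceptance checks use defaults
FAST = McmcSettings(n_iter=6000, burn_in=2000, seed=7)


@pytest.fixture
def fast_settings():
    return FAST


@pytest.fixture
def balanced_unit():
    """Well-covered unit with no imbalance in either condition."""
    return AlleleCountSet(
        "bal", ("m", "v"),
        x=(np.array([101, 118, 72]), np.array([99, 132, 81])),
        y=(np.array([97, 121, 69]), np.array([103, 128, 77])),
        z=(np.array([4, 5, 3]), np.array([4, 6, 3])),
    )


@pytest.fixture
def imbalanced_unit():
    """Strong maternal imbalance in condition 1, balance in condition 2."""
    return AlleleCountSet(
        "imb", ("m", "v"),
        x=(np.array([400, 480, 280]), np.array([100, 130, 80])),
        y=(np.array([100, 120, 70]), np.array([100, 130, 80])),
        z=(np.array([10, 12, 7]), np.array([4, 5, 3])),
    )


@pytest.fixture
def default_bias():
    return BiasSpec.uniform(0.98)


def write_tsv(path, text):
    path.write_text(text.replace(" | ", "\t"))
    return path


@pytest.fixture
def toy_counts_file(tmp_path):
    """One QC-passing unit, 2 conditions x 3 replicates."""
    header = "unit_id | condition | replicate | x_maternal | y_paternal | z_unassigned"
    rows = [
        "e1:l1 | mated | 1 | 101 | 97 | 4",
        "e1:l1 | mated | 2 | 118 | 121 | 5",
        "e1:l1 | mated | 3 | 72 | 69 | 3",
        "e1:l1 | virgin | 1 | 99 | 103 | 4",
        "e1:l1 | virgin | 2 | 132 | 128 | 6",
        "e1:l1 | virgin | 3 | 81 | 77 | 3",
    ]
    return write_tsv(tmp_path / "counts.tsv", "\n".join([header] + rows) + "\n")
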