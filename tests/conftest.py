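import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from error_consistency.simulate import miniature_design, simulate_trial_table


@pytest.fixture(scope="session")
def mini_design():
    """2 human-like observers + 1 independent 'model', 2 times x 2 corruptions."""
    return miniature_design(seed=7, n_human=2, n_model=1)


@pytest.fixture(scope="session")
def mini_table(mini_design):
    return simulate_trial_table(mini_design, seed=11)
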