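import numpy as np
import pandas as pd
import pytest

from porecn import RunSimParams, simulate_run


@pytest.fixture(scope="session")
def deterministic_run():
    """Fixed-length, fixed-vacancy, immortal-channel run: fully predictable."""
    params = RunSimParams(
        n_channels=4,
        run_duration=1000.0,
        median_bp=450.0,
        length_log_sd=0.0,
        vacancy_model="fixed",
        mean_vacancy=2.0,
        channel_death_hazard=0.0,
        seed=0,
    )
    return params, simulate_run(params)


@pytest.fixture(scope="session")
def small_run():
    """A stochastic but seeded small run for kinetics oracles."""
    params = RunSimParams(
        n_channels=8, run_duration=1800.0, median_bp=600.0, seed=42
    )
    return simulate_run(params)


@pytest.fixture()
def toy_alignments():
    """Six records: 2 unmapped, 1 secondary, 1 low MAPQ, 2 good primaries."""
    return pd.DataFrame(
        {
            "read_id": [f"r{i}" for i in range(6)],
            "chrom": ["chr1"] * 6,
            "position": [10, 20, 30, 40, 50, 60],
            "mapq": [0, 0, 60, 5, 20, 60],
            "is_unmapped": [True, True, False, False, False, False],
            "is_secondary": [False, False, True, False, False, False],
            "is_supplementary": [False] * 6,
            "read_length": [400] * 6,
        }
    )


@pytest.fixture(scope="session")
def noisy_step():
    """100-bin profile, +1.0 step at bin 50, noise sd 0.05."""
    rng = np.random.default_rng(7)
    x = np.ones(100) + rng.normal(0, 0.05, 100)
    x[50:] += 1.0
    return x
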