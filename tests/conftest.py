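"""Shared fixtures: one default simulated dataset and its full sweep.

The heavy objects are session-scoped so the parameter-recovery checks and
the per-module tests reuse a single simulation and a single 126-point sweep.
"""

import warnings

import pytest

from cpsweep.evaluation import k_sweep
from cpsweep.simdata import SimParams, simulate_dataset

#: One fixed seed for every stochastic fixture in the suite.
SUITE_SEED = 7


@pytest.fixture(scope="session")
def default_dataset():
    """The default 20 kb chloroplast-like dataset (quality ramp, errors on)."""
    return simulate_dataset(SimParams(seed=SUITE_SEED))


@pytest.fixture(scope="session")
def default_sweep(default_dataset):
    """Full 3 x 42 sweep of the default dataset at the default HSP cutoff."""
    ds = default_dataset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return k_sweep(ds.reads, ds.reference)
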