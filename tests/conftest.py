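"""Shared fixtures: one Monte-Carlo run per sample size, reused suite-wide.

The heavy runs (100,000 replicates, the replicate count of the evaluation
protocol) are session-scoped so the simulation cost is paid once.
"""

from __future__ import annotations

import pytest

from coalratios.simulate import sample_statistics

#: Seed for all Monte-Carlo fixtures; fixed so every run is reproducible.
MC_SEED = 12345
MC_REPS = 100_000


@pytest.fixture(scope="session")
def mc_samples():
    """StatSamples at the validation sizes n in {5, 10, 20, 50}."""
    return {n: sample_statistics(n, MC_REPS, MC_SEED) for n in (5, 10, 20, 50)}


@pytest.fixture(scope="session")
def mc_samples_small():
    """A cheap run for unit-level checks."""
    return sample_statistics(8, 4000, MC_SEED)
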