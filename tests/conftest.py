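"""Shared fixtures.

The heavyweight session-scoped batch runs are only requested by the
acceptance tests; unit and property tests stay fast.
"""

import logging

import pytest

from pepsim import RunConfig, run_batch

logging.getLogger("pepsim").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def sim1_normal_df():
    """Simulation 1, normal model, 100 participants."""
    return run_batch(RunConfig(design="sim1", n_participants=100, base_seed=11))


@pytest.fixture(scope="session")
def sim1_lesion_df():
    """Simulation 1, temporal lesion, 450 participants (the lesioned CSPC
    effect is ~10 cycles with a ~43-cycle participant SD, so p < .001 needs
    a sample near the top of the spec's 100-500 envelope)."""
    return run_batch(RunConfig(design="sim1", n_participants=450, base_seed=12,
                               lesion_temporal=True))


@pytest.fixture(scope="session")
def sim2_df():
    """Simulation 2 (inducer/diagnostic), normal model, 150 participants."""
    return run_batch(RunConfig(design="sim2", n_participants=150, base_seed=13))


@pytest.fixture(scope="session")
def contingency_df():
    """75%-contingency stream with the temporal mechanism lesioned."""
    return run_batch(RunConfig(design="contingency", n_participants=150,
                               base_seed=14, lesion_temporal=True))
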