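"""Shared fixtures.

The session-scoped ``dark_selection`` fixture runs the full experimental
protocol once — ~400 trajectories (mean 35 frames, minimum 16) from the
dark-adapted three-state preset in an 8-µm disc, 50-nm localization noise,
trajectory filters, then variational-Bayes model selection over K = 1..5
with 25 restarts — and is shared by the acceptance-level tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from discspt import (
    AcquisitionParams,
    DiscGeometry,
    apply_localization_noise,
    extract_steps,
    filter_trajectories,
    preset,
    select_model,
    simulate_trajectories,
)


@pytest.fixture(scope="session")
def acq():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def dark():
    """(model, geometry, acq, kinetics) of the dark-adapted preset."""
    return preset("dark")


@pytest.fixture(scope="session")
def dark_trajectories(dark):
    """Paper-scale dark-preset trajectory set with localization noise."""
    model, geometry, acq_, _ = dark
    ts = simulate_trajectories(model, geometry, acq_, n_traj=400, seed=11)
    return apply_localization_noise(ts, acq_.localization_sigma, seed=12)


@pytest.fixture(scope="session")
def dark_filtered(dark, dark_trajectories):
    _, _, acq_, _ = dark
    kept, report = filter_trajectories(dark_trajectories, acq_)
    return kept, report


@pytest.fixture(scope="session")
def dark_selection(dark, dark_filtered):
    """Model-selection result on the filtered dark-preset data."""
    _, _, acq_, _ = dark
    kept, _ = dark_filtered
    series = extract_steps(kept, acq_)
    return select_model(series, k_max=5, n_restarts=25, seed=13)
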