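import numpy as np
import pytest
from hypothesis import settings

from saccurve.config import ApparatusConfig, SelectionCriteria, SimulationConfig
from saccurve.core import TrialEvents
from saccurve.synth import ParticipantParams, simulate_trial

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def apparatus():
    return ApparatusConfig()


@pytest.fixture
def criteria():
    return SelectionCriteria()


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def quiet_sim():
    """Generator settings with every stochastic trajectory component off."""
    return SimulationConfig(noise_sd_deg=0.0, idiosyncrasy_sd_deg=0.0,
                            trial_curvature_sd_deg=0.0, landing_sd_deg=0.0)


def make_events(trial_id=0, participant="p01", side="right", t2="up",
                modality="visual", dx=7.5, dy=7.5, onset=100.0, duration=50.0):
    if modality == "none":
        return TrialEvents(trial_id, participant, side, t2, "none")
    return TrialEvents(trial_id, participant, side, t2, modality,
                       dx, dy, onset, duration)


def make_trial(events, sim, rng, baseline=0.0, **artifacts):
    params = ParticipantParams(events.participant,
                               {events.sequence: baseline})
    return simulate_trial(events, params, rng, sim, **artifacts)
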