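import numpy as np
import pytest

from precereb import (
    AnalysisConfig,
    EventTrain,
    SimConfig,
    SpikeTrain,
    UnitSpec,
    simulate_session,
)


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def noise_free_session():
    """Deterministic-EMG synthetic session used by scoring tests."""
    sim = SimConfig.noise_free(
        duration=600.0, emg_rate=1000.0, seed=11,
        unit_specs=(
            UnitSpec.from_archetype("cd", "u00_cd"),
            UnitSpec.from_archetype("null", "u01_null"),
        ),
    )
    return simulate_session(sim, "noise_free")


@pytest.fixture(scope="session")
def noisy_session():
    """Default-settings synthetic session (noisy EMG, three muscles)."""
    sim = SimConfig(
        duration=600.0, emg_rate=500.0, seed=23,
        unit_specs=(
            UnitSpec.from_archetype("cd", "u00_cd"),
            UnitSpec.from_archetype("sensory", "u01_sensory"),
            UnitSpec.from_archetype("null", "u02_null"),
        ),
    )
    return simulate_session(sim, "noisy")


def random_pair(rng, n_events=50, n_spikes=400, duration=100.0):
    """Unstructured random event/spike pair for oracle comparisons."""
    ev = np.unique(rng.uniform(0, duration, n_events))
    sp = np.sort(rng.uniform(0, duration, n_spikes))
    return (EventTrain("ev", ev, duration), SpikeTrain("u", sp))


def psth_oracle(spike_times, event_times, edges):
    """O(n_spikes * n_events) lag-counting reference implementation."""
    counts = np.zeros(edges.size - 1)
    bw = edges[1] - edges[0]
    for e in event_times:
        for s in spike_times:
            lag = s - e
            if edges[0] <= lag < edges[-1]:
                counts[int(np.floor((lag - edges[0]) / bw))] += 1
    return counts
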