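import numpy as np
import pytest

from eegaffect import dataio, synthetic


@pytest.fixture(scope="session")
def small_dataset():
    """A cheap synthetic dataset: 12 trials, 8 channels, 4 s at 128 Hz."""
    spec = synthetic.SyntheticSpec(
        n_participants=2,
        n_trials_per_participant=6,
        n_channels=8,
        duration=4.0,
        label_ratios={name: 0.5 for name in ("arousal", "valence", "dominance", "liking")},
        seed=7,
    )
    return synthetic.generate(spec)


@pytest.fixture()
def toy_trial():
    """One hand-built trial: 2 channels x 10 samples with distinct values."""
    signal = np.arange(20, dtype=float).reshape(2, 10)
    return dataio.Trial(
        participant_id="p0",
        trial_id="p0/t00",
        signal=signal,
        sampling_rate=128.0,
        ratings={"arousal": 6.5, "valence": 3.0, "dominance": 5.0, "liking": 8.0},
    )


@pytest.fixture(scope="session")
def deap_arrays():
    """DEAP-geometry arrays (40 x 2 x 8064) small enough for fast round-trips."""
    rng = np.random.default_rng(11)
    data = rng.standard_normal((40, 2, 8064)).astype(np.float32)
    labels = rng.uniform(1.0, 9.0, size=(40, 4))
    return data, labels
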