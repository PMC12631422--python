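import numpy as np
import pytest

from cmcoh import (
    CouplingSpec,
    EpochSet,
    Muscle,
    RunConfig,
    Side,
    generate_subject_recording,
    generate_trial_pair,
    load_roi_map,
    subject_cmc,
)
from cmcoh.core_io import ChannelInfo


def make_pair_epochs(
    spec: CouplingSpec,
    n_trials: int = 40,
    seed: int = 0,
    fs: float = 1000.0,
    eeg_label: str = "E51",
    muscle: Muscle = Muscle.flexor_digitorum,
) -> EpochSet:
    """EpochSet with one coupled EEG/EMG channel pair, one 5-s trial per
    epoch (epoch window −1/+4 s, task coupling throughout)."""
    rng = np.random.default_rng(seed)
    trials = [generate_trial_pair(spec, fs, 5.0, rng) for _ in range(n_trials)]
    data = np.stack([np.stack([e, m]) for e, m in trials])
    channels = [ChannelInfo.eeg(eeg_label), ChannelInfo.emg(muscle, Side.right)]
    return EpochSet(data=data, fs=fs, channels=channels, pre_ms=1000, post_ms=4000)


@pytest.fixture(scope="session")
def roi_map():
    return load_roi_map()


@pytest.fixture(scope="session")
def small_recording(roi_map):
    """One synthetic subject, strong low-beta coupling in left M1 ×
    flexor digitorum, 6 trials (kept small for test runtime)."""
    spec = CouplingSpec.for_target_coherence(0.7, emg_noise_power=0.05)
    return generate_subject_recording(
        spec,
        n_trials=6,
        seed=11,
        roi_map=roi_map,
        target_region="M1",
        target_muscle=Muscle.flexor_digitorum,
        lesioned=Side.left,
        subject_id="S00",
    )


@pytest.fixture(scope="session")
def small_cmc_table(small_recording):
    return subject_cmc(small_recording, RunConfig())
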