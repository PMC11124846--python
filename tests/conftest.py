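import numpy as np
import pandas as pd
import pytest

import ethoacc as ea
from ethoacc.syndata import BoutScheduleConfig, make_bout_schedule, synthesize_signal


@pytest.fixture(scope="session")
def small_herd():
    """Two animals, 400 s each: frames, schedule, labeled epochs."""
    frames, schedule = ea.make_default_dataset(n_animals=2, duration_s=400.0, seed=7)
    epochs = ea.synthetic_epoch_table(frames, schedule)
    return frames, schedule, epochs


@pytest.fixture(scope="session")
def small_features(small_herd):
    """Feature table at the 10-s window for the small herd."""
    frames, _, epochs = small_herd
    tables = [ea.extract_features(f, ea.WindowSpec(window_s=10), labels=epochs) for f in frames]
    return pd.concat(tables, ignore_index=True)


@pytest.fixture()
def resting_frame():
    """Noise-free resting frame: constant (0, 0, 1) g."""
    sched = [ea.BehaviorBout("s1", 0.0, 60.0, "resting")]
    params = {"resting": ea.SignatureParams(noise_sd_g=0.0, periodic_amp_g=0.0)}
    return synthesize_signal(sched, params, seed=0)
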