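import dataclasses

import numpy as np
import pandas as pd
import pytest

from ethopersist import CohortDataset, Ethogram, Pulse, StimulusSeries
from ethopersist.simulate import FeedingModel, TriggerSpec, default_config


def random_ethogram(rng, n_frames=900, fps=30.0, animal_id="a0", with_track=True,
                    p_flags=(0.3, 0.35, 0.35, 0.08)):
    """Random raw-flag ethogram with persistent runs (not i.i.d. frames)."""
    flags = np.zeros((n_frames, 4), dtype=bool)
    for col, p in enumerate(p_flags):
        pos = 0
        while pos < n_frames:
            length = int(rng.geometric(1 / 15.0))
            if rng.random() < p:
                flags[pos : pos + length, col] = True
            pos += length
    track = rng.normal(0, 5, size=(n_frames, 2)).cumsum(axis=0) if with_track else None
    return Ethogram(animal_id, flags, fps=fps, track=track)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_cohort():
    """Two 100-frame animals with a light pulse, fully deterministic."""
    fps = 30.0
    flags_a = np.zeros((100, 4), dtype=bool)
    flags_a[10:40, 2] = True  # probe bout
    flags_a[50:70, 1] = True  # walk bout
    flags_b = np.zeros((100, 4), dtype=bool)
    flags_b[0:100:2, 3] = True  # alternating flight frames
    track = np.stack([np.arange(100.0), np.zeros(100)], axis=1)
    eth = [
        Ethogram("a", flags_a, fps=fps, track=track),
        Ethogram("b", flags_b, fps=fps, track=None),
    ]
    meta = pd.DataFrame(
        {
            "animal_id": ["a", "b"],
            "sex": ["F", "F"],
            "condition": ["ctrl", "ctrl"],
            "engorged": pd.array([1, pd.NA]),
        }
    )
    stimuli = StimulusSeries(channels={"light": [Pulse(1.0, 1.5, 1.0)]})
    return CohortDataset(eth, stimuli, meta)


def null_feeding_config(seed, n_animals=70, duration_s=300.0):
    """Generator config whose feeding outcome is independent of behavior."""
    cfg = default_config(seed=seed)
    return dataclasses.replace(
        cfg,
        n_animals=n_animals,
        duration_s=duration_s,
        triggers=(TriggerSpec("light", "local_search", 0.5, 60.0),),
        stimuli=(("light", (Pulse(60.0, 65.0, 1.0),)),),
        feeding=FeedingModel(
            intercept=-0.6, coef=0.0, channel="light", engorge_state=None
        ),
    )


def effect_table(rng, n=150, n_fed=60, shift=0.15):
    """Predictor table with the fed animals' probe proportion shifted up."""
    y = np.zeros(n, dtype=int)
    y[:n_fed] = 1
    rng.shuffle(y)
    props = rng.dirichlet((2, 3, 3, 1, 8), size=n)[:, :4]
    props[y == 1, 2] += shift
    tab = pd.DataFrame(props, columns=["groom", "walk", "probe", "fly"])
    tab.insert(0, "animal_id", [f"m{i}" for i in range(n)])
    tab["engorged"] = y
    return tab
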