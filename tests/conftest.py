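import dataclasses

import numpy as np
import pytest

from gazedys import features, simulate
from gazedys.trials import BLINK, FIXATION, SACCADE, GazeTrial


def make_trial(labels, x=None, y=None, fs=60.0, subject="s01", group="control",
               color="white_bg", trial_id="t1"):
    """Build a trial from a compact label string (F/S/B per sample)."""
    mapping = {"F": FIXATION, "S": SACCADE, "B": BLINK}
    event = np.array([mapping[c] for c in labels], dtype=object)
    n = len(event)
    if x is None:
        x = np.arange(n, dtype=float)
    if y is None:
        y = np.zeros(n, dtype=float)
    x = np.asarray(x, dtype=float).copy()
    y = np.asarray(y, dtype=float).copy()
    x[event == BLINK] = np.nan
    y[event == BLINK] = np.nan
    return GazeTrial(subject_id=subject, group=group, color_config=color,
                     trial_id=trial_id, sampling_rate=fs, x=x, y=y, event=event)


def random_trial(rng, n=None, subject="s01", group="control", trial_id="t1"):
    """A random but valid trial with all three event kinds."""
    n = n or int(rng.integers(5, 60))
    labels = rng.choice([FIXATION, SACCADE, BLINK], size=n, p=[0.7, 0.2, 0.1])
    x = rng.uniform(0, 1000, n)
    y = rng.uniform(0, 500, n)
    x[labels == BLINK] = np.nan
    y[labels == BLINK] = np.nan
    return GazeTrial(subject_id=subject, group=group, color_config="white_bg",
                     trial_id=trial_id, sampling_rate=float(rng.choice([60.0, 120.0])),
                     x=x, y=y, event=labels.astype(object))


@pytest.fixture(scope="session")
def tiny_sim_config():
    """Small study for fast end-to-end tests: 4+4 subjects, 3 colors."""
    return simulate.SimConfig(
        n_control=4, n_dyslexic=4,
        colors=("white_bg", "yellow_bg", "blue_ov"),
        n_lines=3, words_per_line=8,  # ~7 s per trial, above the 5-s filter
    )


@pytest.fixture(scope="session")
def default_feature_table():
    """Feature table of the full default synthetic study (one fixed seed).

    Session-scoped because simulation plus feature extraction of 390 trials
    is the most expensive fixture in the suite.
    """
    trials = simulate.simulate_dataset(simulate.SimConfig(), seed=11)
    return features.features_from_trials(trials)


@pytest.fixture(scope="session")
def tiny_feature_table(tiny_sim_config):
    trials = simulate.simulate_dataset(tiny_sim_config, seed=5)
    return features.features_from_trials(trials)


def replace_cfg(cfg, **kwargs):
    return dataclasses.replace(cfg, **kwargs)
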