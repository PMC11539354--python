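"""Shared fixtures and builders for the odorcode test suite.

Everything is generated programmatically; no stored data.  The builders in
this module construct amplitude-level feature sets (skipping calcium
rendering) for the decoding/geometry tests, and small rendered sessions for
the preprocessing tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from odorcode.preprocess import DffTensor
from odorcode.synthetic import (build_trial_table, make_ground_truth,
                                make_odor_scheme, simulate_behavior,
                                simulate_population)


@pytest.fixture(scope="session")
def exp1_scheme():
    return make_odor_scheme("exp1", day=2)


@pytest.fixture(scope="session")
def exp2_scheme():
    return make_odor_scheme("exp2", day=1)


def encoder_features(scheme, kind: str, seed: int, n_neurons: int = 20,
                     n_blocks: int = 30, amplitude: float = 15.0,
                     noise_sd: float = 5.0, behavior=None):
    """(amplitudes, odor labels, truth): per-trial response amplitudes of a
    pure-encoder population at a given amplitude / trial-noise ratio."""
    trials = build_trial_table(scheme, n_blocks, seed)
    kw = dict(n_identity=0, n_valence=0, n_vigor=0, n_silent=0,
              amplitude=amplitude, noise_sd=noise_sd)
    kw[f"n_{kind}"] = n_neurons
    truth = make_ground_truth(seed=seed + 1, **kw)
    if behavior == "auto":
        behavior = simulate_behavior(trials, scheme, init_learning=1.0,
                                     seed=seed + 7)
    amp = simulate_population(truth, trials, behavior, seed=seed + 2,
                              scheme=scheme)
    return amp, trials["odor_label"].to_numpy(), truth, trials


def single_odor_tensor(values: np.ndarray, frame_rate: float = 5.0,
                       label: str = "X_K") -> DffTensor:
    """Wrap a (neurons, trials, 20 frames) array as a [-2, 2) s tensor of one
    odor, for responsiveness tests that control the data directly."""
    n_trials = values.shape[1]
    trials = pd.DataFrame(dict(
        trial_index=range(n_trials), block=0, odor="hexanone",
        odor_label=label, odor_index=0, odor_on=0.0, odor_off=2.0,
        us_type="none", us_time=2.2, spout_present=True, iti=12.0, value=0.0))
    time = np.arange(-10, values.shape[2] - 10) / frame_rate
    return DffTensor(values=values, time=time, trials=trials,
                     frame_rate=frame_rate)


def paired_tensor(rng, n_neurons=10, trials_per_odor=10, sep=0.0,
                  labels=("A", "B"), n_frames=30, onset_frame=10,
                  odor_frames=slice(10, 20)) -> DffTensor:
    """Two-odor tensor with a mean separation injected during odor frames."""
    n_trials = 2 * trials_per_odor
    vals = rng.normal(0, 1, (n_neurons, n_trials, n_frames))
    vals[:, trials_per_odor:, odor_frames] += sep
    odor = [labels[0]] * trials_per_odor + [labels[1]] * trials_per_odor
    trials = pd.DataFrame(dict(
        trial_index=range(n_trials), block=0, odor=odor, odor_label=odor,
        odor_index=[labels.index(o) for o in odor], odor_on=0.0, odor_off=2.0,
        us_type="none", us_time=2.2, spout_present=True, iti=12.0, value=0.0))
    time = (np.arange(n_frames) - onset_frame) / 5.0
    return DffTensor(values=vals, time=time, trials=trials)
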