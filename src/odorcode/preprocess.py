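"""Raw fluorescence -> trial-aligned dF/F tensors and windowed response stats.

The baseline of each neuron is estimated with a two-component Gaussian
mixture fitted along a moving window (default 2500 frames = 500 s at 5 Hz);
the mean of the lower-mean component is the local baseline, which absorbs
slow drift while ignoring sparse transients.  dF/F = (F - F0) / F0.  Windows
are half-open ``[t0, t1)`` in seconds relative to odor onset, a frame being
assigned by its start time; the odor period is ``[0, 2)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from ._util import logger
from .synthetic import FRAME_RATE


def estimate_moving_baseline(trace: np.ndarray, window_frames: int = 2500,
                             n_components: int = 2, stride: int = 100) -> np.ndarray:
    """Per-frame baseline from a moving-window Gaussian mixture.

    A ``n_components``-component GMM is fitted in a centered window (truncated
    at the edges) every ``stride`` frames; the baseline at those anchors is
    the mean of the lowest-mean component, linearly interpolated in between.

    Accepts a 1-D trace or a (neurons, frames) matrix.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim == 2:
        return np.vstack([
            estimate_moving_baseline(row, window_frames, n_components, stride)
            for row in trace])
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite values")
    n = trace.size
    if n < window_frames // 2:
        raise ValueError(f"trace length {n} < window_frames/2 = {window_frames // 2}")

    anchors = np.arange(0, n, stride)
    if anchors[-1] != n - 1:
        anchors = np.append(anchors, n - 1)
    half = window_frames // 2
    values = np.empty(anchors.size)
    for j, c in enumerate(anchors):
        lo, hi = max(0, c - half), min(n, c + half)
        x = trace[lo:hi, None]
        if np.ptp(x) == 0:  # GMM degenerate on constant data
            values[j] = x[0, 0]
            continue
        gmm = GaussianMixture(n_components=n_components, random_state=0,
                              n_init=1, reg_covar=1e-4)
        gmm.fit(x)
        values[j] = gmm.means_.min()
    return np.interp(np.arange(n), anchors, values)


def compute_dff(trace: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Elementwise (F_t - F0) / F0."""
    trace = np.asarray(trace, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if trace.shape != baseline.shape:
        raise ValueError("trace and baseline shapes differ")
    if np.any(baseline <= 0):
        raise ValueError("baseline must be strictly positive")
    return (trace - baseline) / baseline


@dataclass
class DffTensor:
    """Trial-aligned dF/F: (neurons, trials, frames) with a time axis in
    seconds relative to odor onset and the trial table it was cut from."""

    values: np.ndarray
    time: np.ndarray
    trials: pd.DataFrame
    frame_rate: float = FRAME_RATE

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    def frame_slice(self, t0: float, t1: float) -> slice:
        """Frame indices whose start times fall in the half-open [t0, t1)."""
        i0 = int(np.searchsorted(np.round(self.time, 9), t0 - 1e-9))
        i1 = int(np.searchsorted(np.round(self.time, 9), t1 - 1e-9))
        if i1 <= i0:
            raise ValueError(f"window [{t0}, {t1}) selects no frames")
        return slice(i0, i1)

    def odor_trials(self, odor: str) -> np.ndarray:
        """Trial indices for an odor, by name or short label (e.g. 'S_K')."""
        col = "odor_label" if odor in set(self.trials["odor_label"]) else "odor"
        return np.flatnonzero((self.trials[col] == odor).to_numpy())


def align_trials(dff: np.ndarray, trials: pd.DataFrame, pre_s: float = 2.0,
                 post_s: float = 8.0, frame_rate: float = FRAME_RATE) -> DffTensor:
    """Cut a (neurons, frames) dF/F matrix into a trial-aligned tensor with
    frames from ``pre_s`` before to ``post_s`` after each odor onset."""
    dff = np.atleast_2d(np.asarray(dff, dtype=float))
    n_pre = int(round(pre_s * frame_rate))
    n_post = int(round(post_s * frame_rate))
    n_frames_total = dff.shape[1]
    chunks = []
    for _, tr in trials.iterrows():
        onset = int(np.round(tr.odor_on * frame_rate))
        i0, i1 = onset - n_pre, onset + n_post
        if i0 < 0 or i1 > n_frames_total:
            raise ValueError(
                f"trial {int(tr.trial_index)} window [{i0}, {i1}) out of bounds "
                f"for recording of {n_frames_total} frames")
        chunks.append(dff[:, i0:i1])
    values = np.stack(chunks, axis=1)
    time = (np.arange(-n_pre, n_post)) / frame_rate
    return DffTensor(values=values, time=time, trials=trials.reset_index(drop=True),
                     frame_rate=frame_rate)


def window_features(tensor: DffTensor, window: tuple = (1.0, 2.0),
                    trials: np.ndarray | None = None,
                    zscore: bool = False) -> np.ndarray:
    """Per-trial mean dF/F in a window: (neurons, selected trials).

    With ``zscore`` the features are standardized per neuron across the
    selected trials; zero-variance neurons come back as NaN rows and are
    logged (callers exclude them).
    """
    sl = tensor.frame_slice(*window)
    vals = tensor.values if trials is None else tensor.values[:, trials, :]
    feats = vals[:, :, sl].mean(axis=2)
    if zscore:
        mu = feats.mean(axis=1, keepdims=True)
        sd = feats.std(axis=1, keepdims=True)
        dead = sd[:, 0] == 0
        if dead.any():
            logger.info("window_features: excluding %d zero-variance neuron(s)",
                        int(dead.sum()))
            sd[dead] = np.nan
        feats = (feats - mu) / sd
    return feats


@dataclass
class ResponseMagnitude:
    """Per neuron x odor ddF/F response magnitudes.

    ``ddff[n, o]`` = trial-averaged dF/F in the last second of odor minus the
    trial-averaged dF/F in the 2 s before onset.  ``scaled`` divides each row
    by its largest positive entry; rows with no positive entry are NaN
    (excluded from scaled-correlation analyses).
    """

    ddff: np.ndarray       # (neurons, odors)
    scaled: np.ndarray     # (neurons, odors), NaN rows where undefined
    odor_labels: list

    @property
    def undefined_rows(self) -> np.ndarray:
        return np.isnan(self.scaled).all(axis=1)


def delta_delta_f(tensor: DffTensor, odor_window: tuple = (1.0, 2.0),
                  pre_window: tuple = (-2.0, 0.0),
                  odors: list | None = None) -> ResponseMagnitude:
    """ddF/F per neuron and odor, plus the positively-scaled variant."""
    if odors is None:
        seen = []
        for lab in tensor.trials["odor_label"]:
            if lab not in seen:
                seen.append(lab)
        odors = seen
    odor_sl = tensor.frame_slice(*odor_window)
    pre_sl = tensor.frame_slice(*pre_window)
    ddff = np.empty((tensor.n_neurons, len(odors)))
    for o, lab in enumerate(odors):
        idx = tensor.odor_trials(lab)
        resp = tensor.values[:, idx, odor_sl].mean(axis=2)
        pre = tensor.values[:, idx, pre_sl].mean(axis=2)
        ddff[:, o] = (resp - pre).mean(axis=1)
    max_pos = np.where(ddff.max(axis=1) > 0, ddff.max(axis=1), np.nan)
    n_undef = int(np.isnan(max_pos).sum())
    if n_undef:
        logger.info("delta_delta_f: %d neuron(s) with no positive ddF/F; "
                    "scaled rows undefined", n_undef)
    scaled = ddff / max_pos[:, None]
    return ResponseMagnitude(ddff=ddff, scaled=scaled, odor_labels=list(odors))
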