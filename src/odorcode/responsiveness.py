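"""Frame-wise statistical responsiveness calls with family-wise error control.

For each neuron and odor, dF/F at every frame of the 2 s odor period is
compared against the pooled pre-odor distribution (all frames in the 2 s
before onset, across trials) with a two-sided Wilcoxon rank-sum test; the 10
frame-wise p-values form one Holm-Bonferroni family (FWER 0.05).  A neuron is
responsive to an odor when at least four frames are significant (any four,
not necessarily consecutive); its direction comes from the sign of the
significant frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from ._util import logger
from .preprocess import DffTensor

MIN_SIGNIFICANT_FRAMES = 4


def framewise_rank_test(tensor: DffTensor, odor: str,
                        window: tuple = (0.0, 2.0),
                        pre_window: tuple = (-2.0, 0.0)):
    """Two-sided rank-sum p-value per odor-period frame, per neuron.

    Returns ``(pvals, signs)``, each (neurons, window frames): at frame *j*
    the per-trial dF/F values are tested against the pooled pre-odor values
    (trials x pre frames); ``signs`` is the sign of the median difference.
    """
    idx = tensor.odor_trials(odor)
    if idx.size < 2:
        raise ValueError(f"need >= 2 trials of odor {odor!r}, got {idx.size}")
    win = tensor.frame_slice(*window)
    pre = tensor.frame_slice(*pre_window)
    resp = tensor.values[:, idx, win]                       # (n, trials, F)
    pool = tensor.values[:, idx, pre].reshape(tensor.n_neurons, -1)
    x = resp.transpose(0, 2, 1)                             # (n, F, trials)
    # all-tied frame/pool combinations are degenerate: p = 1 with a warning
    tied = (np.ptp(x, axis=2) == 0) & (np.ptp(pool, axis=1) == 0)[:, None] \
        & (x[:, :, 0] == pool[:, :1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = mannwhitneyu(x, pool[:, None, :], axis=-1,
                           alternative="two-sided", method="asymptotic",
                           use_continuity=False)
    pvals = np.where(tied | ~np.isfinite(res.pvalue), 1.0, res.pvalue)
    if tied.any():
        warnings.warn(f"{int(tied.sum())} all-tied frame comparison(s); p = 1")
    signs = np.sign(np.median(x, axis=2) - np.median(pool, axis=1)[:, None])
    return pvals, signs


def holm_bonferroni(pvals: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Step-down Holm rejection flags controlling FWER at ``alpha``.

    1-D input is one family; 2-D input is one family per row (vectorized).
    The rejected set is always a prefix of the sorted p-values.
    """
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    squeeze = pvals.ndim == 1
    p = np.atleast_2d(pvals)
    m = p.shape[1]
    order = np.argsort(p, axis=1)
    psort = np.take_along_axis(p, order, axis=1)
    step_ok = psort <= alpha / (m - np.arange(m))
    # reject the prefix before the first step failure
    n_reject = np.where(step_ok.all(axis=1), m, np.argmin(step_ok, axis=1))
    reject_sorted = np.arange(m) < n_reject[:, None]
    reject = np.zeros_like(p, dtype=bool)
    np.put_along_axis(reject, order, reject_sorted, axis=1)
    return reject[0] if squeeze else reject


@dataclass
class ResponsivenessResult:
    """Responsiveness calls for all neurons against one odor."""

    odor: str
    framewise_p: np.ndarray        # (neurons, frames)
    significant: np.ndarray        # (neurons, frames) Holm flags
    signs: np.ndarray              # (neurons, frames)
    significant_frames: np.ndarray  # (neurons,)
    responsive: np.ndarray         # (neurons,) bool
    direction: np.ndarray          # (neurons,) excited/inhibited/mixed/none

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(
            neuron=np.arange(len(self.responsive)), odor=self.odor,
            significant_frames=self.significant_frames,
            responsive=self.responsive, direction=self.direction))


def classify_responsiveness(tensor_or_pvals, odor: str | None = None,
                            signs: np.ndarray | None = None,
                            alpha: float = 0.05,
                            min_frames: int = MIN_SIGNIFICANT_FRAMES,
                            window: tuple = (0.0, 2.0),
                            pre_window: tuple = (-2.0, 0.0)) -> ResponsivenessResult:
    """Responsive = at least ``min_frames`` Holm-significant frames.

    Direction is the majority sign among significant frames; exact ties are
    labelled "mixed" and excluded from direction-specific counts downstream.
    Accepts either a :class:`DffTensor` plus odor, or precomputed
    ``(pvals, signs)``.
    """
    if isinstance(tensor_or_pvals, DffTensor):
        pvals, signs = framewise_rank_test(tensor_or_pvals, odor, window, pre_window)
    else:
        pvals = np.asarray(tensor_or_pvals)
        if signs is None:
            raise ValueError("signs required when passing raw p-values")
    significant = holm_bonferroni(pvals, alpha)
    sig_frames = significant.sum(axis=1)
    responsive = sig_frames >= min_frames
    direction = np.full(pvals.shape[0], "none", dtype=object)
    for i in np.flatnonzero(responsive):
        s = signs[i, significant[i]]
        pos, neg = int((s > 0).sum()), int((s < 0).sum())
        if pos > neg:
            direction[i] = "excited"
        elif neg > pos:
            direction[i] = "inhibited"
        else:
            direction[i] = "mixed"
            logger.info("neuron %d responsive with tied direction (mixed)", i)
    return ResponsivenessResult(odor=odor or "", framewise_p=pvals,
                                significant=significant, signs=signs,
                                significant_frames=sig_frames,
                                responsive=responsive,
                                direction=np.asarray(direction, dtype=str))


def us_window_responsiveness(tensor: DffTensor, odor: str, us_len: float = 2.0,
                             alpha: float = 0.05,
                             min_frames: int = MIN_SIGNIFICANT_FRAMES) -> ResponsivenessResult:
    """Responsiveness in the post-US window [us, us + us_len), against the
    same pre-odor pool.  US delay is taken from the trial table (median over
    the odor's trials, snapped to the frame grid)."""
    idx = tensor.odor_trials(odor)
    sub = tensor.trials.iloc[idx]
    delay = float(np.median(sub["us_time"] - sub["odor_on"]))
    t0 = np.floor(delay * tensor.frame_rate) / tensor.frame_rate
    return classify_responsiveness(tensor, odor, alpha=alpha, min_frames=min_frames,
                                   window=(t0, t0 + us_len))


def cross_day_transfer(day_a: ResponsivenessResult, day_b: ResponsivenessResult,
                       pairs: np.ndarray,
                       mag_a: np.ndarray | None = None,
                       mag_b: np.ndarray | None = None):
    """Fraction of matched neurons responsive in both epochs with the same
    direction (e.g. sucrose-responsive on day 1 and cue-responsive on day 3),
    plus per-neuron day B - day A response-magnitude changes.

    ``pairs`` is an (m, 2) array of (neuron id day A, neuron id day B).
    """
    pairs = np.atleast_2d(np.asarray(pairs, dtype=int))
    if pairs.size == 0:
        raise ValueError("matched-pair set is empty")
    ia, ib = pairs[:, 0], pairs[:, 1]
    both = (day_a.responsive[ia] & day_b.responsive[ib]
            & (day_a.direction[ia] == day_b.direction[ib])
            & np.isin(day_a.direction[ia], ("excited", "inhibited")))
    out = {"fraction_transferred": float(both.mean()),
           "n_pairs": int(len(pairs)), "transferred": both}
    if mag_a is not None and mag_b is not None:
        out["magnitude_change"] = np.asarray(mag_b)[ib] - np.asarray(mag_a)[ia]
    return out


def responsiveness_table(tensor: DffTensor, odors: list | None = None,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Tidy (neuron, odor, direction, significant_frames, responsive) table."""
    if odors is None:
        odors = list(dict.fromkeys(tensor.trials["odor_label"]))
    return pd.concat([classify_responsiveness(tensor, o, alpha=alpha).to_frame()
                      for o in odors], ignore_index=True)
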