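"""Population response geometry: pairwise distance trajectories and
participation-ratio dimensionality.

The participation ratio PR = (sum lambda_i)^2 / sum lambda_i^2 over the
eigenvalues of the neurons x neurons covariance matrix ranges from 1 (one
principal component carries all variance) to the number of features (all
components equal).  Because PR grows with population size, populations of
different sizes are compared by repeatedly subsampling a fixed number of
neurons (k = 15, 1000 resamples) and averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from ._util import as_rng
from .preprocess import DffTensor


@dataclass
class DistanceTrajectories:
    """Normalized Euclidean distance between trial-averaged population vectors
    for every odor pair, per frame; global maximum is exactly 1."""

    pairs: list
    distances: np.ndarray      # (n_pairs, frames), in [0, 1]
    time: np.ndarray
    normalization: float       # the pre-normalization global max

    def to_long(self):
        import pandas as pd
        rows = [dict(pair="|".join(p), time=float(t), distance=self.distances[i, j])
                for i, p in enumerate(self.pairs)
                for j, t in enumerate(self.time)]
        return pd.DataFrame(rows)


def distance_trajectories(tensor: DffTensor,
                          pre_window: tuple = (-2.0, 0.0)) -> DistanceTrajectories:
    """Baseline-subtracted, trial-averaged population trajectories and their
    pairwise Euclidean distances, normalized to the maximum over all pairs
    and frames."""
    pre_sl = tensor.frame_slice(*pre_window)
    odors = list(dict.fromkeys(tensor.trials["odor_label"]))
    means = {}
    for o in odors:
        idx = tensor.odor_trials(o)
        v = tensor.values[:, idx, :]
        v = v - v[:, :, pre_sl].mean(axis=2, keepdims=True)
        means[o] = v.mean(axis=1)                      # (neurons, frames)
    pairs = list(combinations(odors, 2))
    dist = np.stack([np.linalg.norm(means[a] - means[b], axis=0)
                     for a, b in pairs])
    norm = float(dist.max())
    if norm > 0:
        dist = dist / norm
    return DistanceTrajectories(pairs=pairs, distances=dist, time=tensor.time,
                                normalization=norm)


@dataclass
class PrResult:
    eigenvalues: np.ndarray
    pr: float
    subsample_k: int | None = None
    n_resamples: int | None = None
    resample_prs: np.ndarray | None = None


def pr_from_eigenvalues(eigenvalues: np.ndarray) -> float:
    lam = np.asarray(eigenvalues, dtype=float)
    lam = np.clip(lam, 0, None)   # numerical negatives from eigh
    total = lam.sum()
    if total <= 0:
        raise ValueError("zero-variance data: participation ratio undefined")
    return float(total**2 / np.sum(lam**2))


def participation_ratio(data: np.ndarray) -> PrResult:
    """PR of a samples x neurons data matrix (unbiased covariance)."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("need a 2-D samples x neurons matrix with >= 2 samples")
    cov = np.cov(data, rowvar=False)
    lam = np.linalg.eigvalsh(np.atleast_2d(cov))
    return PrResult(eigenvalues=lam[::-1], pr=pr_from_eigenvalues(lam))


def subsampled_pr(data: np.ndarray, k: int = 15, n_resamples: int = 1000,
                  seed: int = 0) -> PrResult:
    """Average PR over random k-neuron subsamples (without replacement)."""
    data = np.asarray(data, dtype=float)
    n_neurons = data.shape[1]
    if k > n_neurons:
        raise ValueError(f"k={k} exceeds population size {n_neurons}")
    if k == n_neurons:
        full = participation_ratio(data)
        return PrResult(eigenvalues=full.eigenvalues, pr=full.pr, subsample_k=k,
                        n_resamples=n_resamples,
                        resample_prs=np.full(n_resamples, full.pr))
    rng = as_rng(seed)
    prs = np.empty(n_resamples)
    for r in range(n_resamples):
        cols = rng.choice(n_neurons, size=k, replace=False)
        prs[r] = participation_ratio(data[:, cols]).pr
    return PrResult(eigenvalues=np.array([]), pr=float(prs.mean()),
                    subsample_k=k, n_resamples=n_resamples, resample_prs=prs)


def tensor_samples(tensor: DffTensor) -> np.ndarray:
    """All trial-aligned dF/F frames concatenated across trials, as the
    samples x neurons matrix whose covariance feeds the PR."""
    n, t, f = tensor.values.shape
    return tensor.values.reshape(n, t * f).T
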