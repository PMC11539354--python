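"""Pooled response-profile featurization and hierarchical clustering.

Each neuron's trial-averaged, Z-scored responses are averaged in three
windows per odor -- first second of odor, last second of odor, first second
after odor -- giving an 18-element profile for six-odor sessions.  Profiles
are grouped by Ward-linkage agglomerative clustering on Euclidean distance
(6 clusters for the conditioning paradigm, 3 for the lick/no-lick paradigm),
which separates inhibited vs excited and broad vs narrow response motifs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from ._util import logger
from .preprocess import DffTensor

PROFILE_WINDOWS = ((0.0, 1.0), (1.0, 2.0), (2.0, 3.0))


@dataclass
class ClusterFeatures:
    """neurons x (3 windows x odors) Z-scored feature matrix."""

    features: np.ndarray
    neuron_ids: np.ndarray          # original indices (zero-variance excluded)
    odor_labels: list
    windows: tuple = PROFILE_WINDOWS


def build_cluster_features(tensor: DffTensor, zscore_axis: str = "time") -> ClusterFeatures:
    """Trial-average, Z-score, then window-average into 18 features.

    ``zscore_axis="time"`` standardizes each neuron's trial-averaged trace
    across all frames and odors before windowing (default);
    ``"features"`` standardizes the 18 window means instead.
    Zero-variance neurons are excluded with a log entry.
    """
    odors = list(dict.fromkeys(tensor.trials["odor_label"]))
    slices = [tensor.frame_slice(*w) for w in PROFILE_WINDOWS]
    avg = np.stack([tensor.values[:, tensor.odor_trials(o), :].mean(axis=1)
                    for o in odors], axis=1)   # (neurons, odors, frames)
    n = avg.shape[0]
    if zscore_axis == "time":
        flat = avg.reshape(n, -1)
        mu, sd = flat.mean(axis=1), flat.std(axis=1)
        keep = sd > 0
        z = (avg[keep] - mu[keep, None, None]) / sd[keep, None, None]
        feats = np.stack([z[:, :, sl].mean(axis=2) for sl in slices], axis=2)
        feats = feats.reshape(z.shape[0], -1)   # (neurons, odors*3) odor-major
    elif zscore_axis == "features":
        raw = np.stack([avg[:, :, sl].mean(axis=2) for sl in slices], axis=2)
        raw = raw.reshape(n, -1)
        mu, sd = raw.mean(axis=1), raw.std(axis=1)
        keep = sd > 0
        feats = (raw[keep] - mu[keep, None]) / sd[keep, None]
    else:
        raise ValueError("zscore_axis must be 'time' or 'features'")
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("build_cluster_features: excluded %d zero-variance neuron(s)",
                    n_drop)
    return ClusterFeatures(features=feats, neuron_ids=np.flatnonzero(keep),
                           odor_labels=odors)


@dataclass
class ClusterAssignment:
    labels: np.ndarray             # cluster per kept neuron, 1..n_clusters
    linkage: np.ndarray            # standard 4-column merge table
    neuron_ids: np.ndarray
    n_clusters: int

    def composition(self, region: np.ndarray) -> pd.DataFrame:
        """Fraction of each cluster contributed by each region tag."""
        df = pd.DataFrame(dict(cluster=self.labels,
                               region=np.asarray(region)[self.neuron_ids]))
        frac = (df.groupby(["cluster", "region"]).size()
                / df.groupby("cluster").size())
        return frac.rename("fraction").reset_index()


def cluster_profiles(features: ClusterFeatures, n_clusters: int = 6) -> ClusterAssignment:
    """Ward-linkage agglomeration on Euclidean distance, cut at ``n_clusters``.

    Clusters are renumbered by ascending mean feature value (inhibited
    motifs first) for stable reporting.
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    x = features.features
    if x.shape[0] < n_clusters:
        raise ValueError("fewer neurons than clusters")
    z = linkage(x, method="ward", metric="euclidean")
    raw = fcluster(z, t=n_clusters, criterion="maxclust")
    order = np.argsort([x[raw == c].mean() for c in np.unique(raw)])
    remap = {int(c): int(np.flatnonzero(order == i)[0]) + 1
             for i, c in enumerate(np.unique(raw))}
    labels = np.array([remap[int(c)] for c in raw])
    return ClusterAssignment(labels=labels, linkage=z,
                             neuron_ids=features.neuron_ids,
                             n_clusters=n_clusters)
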