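"""Population-level decoding of odor pairs and odor identity.

Pairwise decoders are linear classifiers (logistic by default, RBF-kernel SVM
as a robustness check) trained on trials x neurons feature matrices and
scored by stratified 5-fold cross-validation; significance comes from
refitting on label permutations.  Cross-pair generalization trains on one
odor pair and tests on another, mapping class labels through a canonical
odor order (sucrose-contingent odor first) so "class 1" means the
higher-contingency odor on both sides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from sklearn.decomposition import PCA
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._util import as_rng
from .preprocess import DffTensor

LEARNERS = ("logistic", "svm_rbf", "multinomial")


def _make_learner(learner: str):
    if learner in ("logistic", "multinomial"):
        return LogisticRegression(max_iter=2000)
    if learner == "svm_rbf":
        return SVC(C=1.0, kernel="rbf", gamma="scale")
    raise ValueError(f"unknown learner {learner!r}; expected one of {LEARNERS}")


@dataclass
class DecoderRecord:
    odor_pair: tuple
    learner: str
    cv_accuracy: float
    fold_accuracies: np.ndarray
    null_p: float = np.nan
    n_shuffles: int = 0
    timepoint: object = "window"


def _cv_accuracy(x: np.ndarray, y: np.ndarray, learner: str, folds: int,
                 rng: np.random.Generator) -> np.ndarray:
    cv = StratifiedKFold(folds, shuffle=True,
                         random_state=int(rng.integers(2**31 - 1)))
    accs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for tr, te in cv.split(x, y):
            scaler = StandardScaler().fit(x[tr])
            clf = _make_learner(learner).fit(scaler.transform(x[tr]), y[tr])
            accs.append(clf.score(scaler.transform(x[te]), y[te]))
    return np.array(accs)


def cv_pairwise_accuracy(features: np.ndarray, labels, learner: str = "logistic",
                         folds: int = 5, n_shuffles: int = 0,
                         seed: int = 0) -> DecoderRecord:
    """Stratified k-fold CV accuracy of a binary population decoder.

    ``features`` is trials x neurons (normalized per neuron within training
    folds).  With ``n_shuffles`` > 0, a permutation p-value is computed by
    refitting the full CV on label-shuffled data (production default in the
    study design is 10,000; configurable down for runtime).
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("need exactly 2 classes")
    if counts.min() < folds:
        raise ValueError(f"class with {counts.min()} trials cannot be "
                         f"stratified into {folds} folds")
    rng = as_rng(seed)
    fold_acc = _cv_accuracy(x, y, learner, folds, rng)
    rec = DecoderRecord(odor_pair=tuple(classes), learner=learner,
                        cv_accuracy=float(fold_acc.mean()),
                        fold_accuracies=fold_acc)
    if n_shuffles:
        null = np.empty(n_shuffles)
        for s in range(n_shuffles):
            null[s] = _cv_accuracy(x, rng.permutation(y), learner, folds, rng).mean()
        rec.null_p = float((1 + np.sum(null >= rec.cv_accuracy - 1e-12))
                           / (n_shuffles + 1))
        rec.n_shuffles = n_shuffles
    return rec


def time_resolved_accuracy(tensor: DffTensor, pair: tuple,
                           learner: str = "logistic", folds: int = 5,
                           seed: int = 0) -> list:
    """One DecoderRecord per frame, features = dF/F at that frame.

    The window summary (mean over the last second of odor) is attached by
    :func:`summarize_time_resolved`.
    """
    ia, ib = tensor.odor_trials(pair[0]), tensor.odor_trials(pair[1])
    idx = np.concatenate([ia, ib])
    y = np.array([pair[0]] * ia.size + [pair[1]] * ib.size)
    records = []
    for f, t in enumerate(tensor.time):
        x = tensor.values[:, idx, f].T
        rec = cv_pairwise_accuracy(x, y, learner=learner, folds=folds,
                                   seed=seed + f)
        rec.timepoint = float(t)
        records.append(rec)
    return records


def summarize_time_resolved(records: list, window: tuple = (1.0, 2.0)) -> float:
    accs = [r.cv_accuracy for r in records
            if window[0] - 1e-9 <= r.timepoint < window[1] - 1e-9]
    return float(np.mean(accs))


@dataclass
class GeneralizationMatrix:
    """15 x 15 accuracy matrix indexed by (train pair, test pair).

    Off-diagonal entries come from classifiers never fitted on the test
    pair's trials; diagonal entries are within-pair CV maxima over the same
    frames and are flagged (they do not measure generalization).
    """

    pairs: list                    # list of (odor_hi, odor_lo) in canonical order
    accuracy: np.ndarray           # (15, 15)
    diagonal_is_cv: bool = True

    def to_long(self):
        import pandas as pd
        rows = [dict(train_pair="|".join(tp), test_pair="|".join(sp),
                     accuracy=self.accuracy[i, j],
                     within_pair_cv=(i == j))
                for i, tp in enumerate(self.pairs)
                for j, sp in enumerate(self.pairs)]
        return pd.DataFrame(rows)


def canonical_pairs(order: list) -> list:
    """All 15 unordered odor pairs, each ordered by the canonical odor order
    (higher-contingency odor first)."""
    return list(combinations(order, 2))


def generalization_matrix(tensor_or_features, odor_order: list,
                          learner: str = "logistic", folds: int = 5,
                          window: tuple = (0.0, 2.0),
                          seed: int = 0) -> GeneralizationMatrix:
    """Train on each odor pair, test on every other, max over odor-period frames.

    ``tensor_or_features``: a DffTensor (per-frame features over ``window``)
    or a dict odor -> (trials, neurons) feature matrix (single "frame").
    ``odor_order`` is the canonical odor order defining the class-1 mapping
    (see :meth:`odorcode.synthetic.OdorScheme.canonical_order`).
    """
    rng = as_rng(seed)
    if isinstance(tensor_or_features, DffTensor):
        tensor = tensor_or_features
        sl = tensor.frame_slice(*window)
        frames = range(sl.start, sl.stop)
        feats = {o: tensor.values[:, tensor.odor_trials(o), :].transpose(1, 0, 2)
                 for o in odor_order}  # (trials, neurons, frames)
        get = lambda o, f: feats[o][:, :, f]
    else:
        feats = {o: np.asarray(v, dtype=float)
                 for o, v in tensor_or_features.items()}
        frames = [0]
        get = lambda o, f: feats[o]

    pairs = canonical_pairs(odor_order)
    acc = np.zeros((len(pairs), len(pairs)))
    for f_i, f in enumerate(frames):
        for i, (a, b) in enumerate(pairs):
            xa, xb = get(a, f), get(b, f)
            x = np.vstack([xa, xb])
            y = np.r_[np.ones(len(xa)), np.zeros(len(xb))]
            scaler = StandardScaler().fit(x)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                clf = _make_learner(learner).fit(scaler.transform(x), y)
            for j, (c, d) in enumerate(pairs):
                if i == j:
                    a_cv = _cv_accuracy(x, y, learner, folds, rng).mean()
                    acc[i, i] = max(acc[i, i], a_cv)
                    continue
                xt = np.vstack([get(c, f), get(d, f)])
                yt = np.r_[np.ones(len(get(c, f))), np.zeros(len(get(d, f)))]
                a_gen = clf.score(scaler.transform(xt), yt)
                acc[i, j] = max(acc[i, j], a_gen)
    return GeneralizationMatrix(pairs=pairs, accuracy=acc)


def population_confusion(features: np.ndarray, labels, cv_folds: int = 5,
                         seed: int = 0) -> np.ndarray:
    """Row-stochastic confusion matrix of a CV multinomial population decoder."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < cv_folds:
        raise ValueError(f"each class needs >= {cv_folds} trials")
    x = StandardScaler().fit_transform(x)
    cv = StratifiedKFold(cv_folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        pred = cross_val_predict(LogisticRegression(max_iter=2000), x, y, cv=cv)
    return confusion_matrix(y, pred, labels=classes, normalize="true")


def pca_restricted_accuracy(features: np.ndarray, labels, n_sub: int = 15,
                            k_pcs=None, n_resamples: int = 20, folds: int = 5,
                            seed: int = 0, whole_data_pca: bool = False):
    """CV accuracy vs number of principal components, on subsampled neurons.

    Per resample, ``n_sub`` neurons are drawn without replacement, PCs are
    computed on training folds only (``whole_data_pca`` relaxes this), both
    folds are projected onto the first k PCs, and a logistic decoder is
    scored.  Returns (k values, mean accuracy per k, per-resample matrix).
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n_neurons = x.shape[1]
    if n_sub > n_neurons:
        raise ValueError("n_sub exceeds population size")
    if k_pcs is None:
        k_pcs = list(range(1, n_sub + 1))
    if max(k_pcs) > n_sub:
        raise ValueError("k_pcs cannot exceed n_sub")
    rng = as_rng(seed)
    out = np.zeros((n_resamples, len(k_pcs)))
    for r in range(n_resamples):
        cols = rng.choice(n_neurons, size=n_sub, replace=False)
        xs = x[:, cols]
        cv = StratifiedKFold(folds, shuffle=True,
                             random_state=int(rng.integers(2**31 - 1)))
        fold_accs = np.zeros((folds, len(k_pcs)))
        for fi, (tr, te) in enumerate(cv.split(xs, y)):
            scaler = StandardScaler().fit(xs[tr])
            xtr, xte = scaler.transform(xs[tr]), scaler.transform(xs[te])
            pca = PCA(n_components=n_sub)
            pca.fit(np.vstack([xtr, xte]) if whole_data_pca else xtr)
            ztr, zte = pca.transform(xtr), pca.transform(xte)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                for ki, k in enumerate(k_pcs):
                    clf = LogisticRegression(max_iter=2000).fit(ztr[:, :k], y[tr])
                    fold_accs[fi, ki] = clf.score(zte[:, :k], y[te])
        out[r] = fold_accs.mean(axis=0)
    return np.asarray(k_pcs), out.mean(axis=0), out
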