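"""Single-neuron pairwise odor discriminability.

For each neuron and odor pair, the Z-scored odor-window responses (30 trials
per odor) are fed to a univariate logistic classifier and the auROC of the
fitted scores is reported.  Because the fitted score is a monotone transform
of the single input feature, this auROC equals the folded, tie-corrected
Mann-Whitney statistic max(A, 1 - A) with A = U / (n1 * n2) -- an identity
exploited for the 10,000-shuffle permutation null, which therefore permutes
labels over precomputed midranks instead of refitting classifiers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from ._util import as_rng

AUROC_THRESHOLD = 0.75


@dataclass
class AurocRecord:
    neuron: int
    odor_pair: tuple
    auroc: float
    null_p: float
    n_shuffles: int


def _as_binary(labels) -> np.ndarray:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.size}")
    return labels == classes[1]


def rank_auroc(values: np.ndarray, labels) -> float:
    """Folded tie-corrected Mann-Whitney statistic max(A, 1 - A)."""
    y = _as_binary(labels)
    n1, n0 = int(y.sum()), int((~y).sum())
    r = rankdata(values)
    a = (r[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    return float(max(a, 1.0 - a))


def fit_pairwise_auroc(values: np.ndarray, labels, neuron: int = 0,
                       cross_validate: bool = False, seed: int = 0) -> AurocRecord:
    """auROC of a univariate logistic classifier for one neuron and odor pair.

    Default scores the classifier on its training data (folded so chance is
    the floor); ``cross_validate`` switches to 5-fold held-out scores.
    """
    values = np.asarray(values, dtype=float)
    y = _as_binary(labels)
    if min(y.sum(), (~y).sum()) < 2:
        raise ValueError("need >= 2 trials per class")
    sd = values.std()
    x = ((values - values.mean()) / sd if sd > 0 else values * 0.0)[:, None]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf = LogisticRegression(C=np.inf, max_iter=1000)
        if cross_validate:
            cv = StratifiedKFold(5, shuffle=True, random_state=seed)
            scores = cross_val_predict(clf, x, y, cv=cv,
                                       method="decision_function")
        else:
            clf.fit(x, y)
            scores = clf.decision_function(x)
    if np.unique(scores).size < np.unique(x).size:
        # degenerate fit: a (near-)zero slope collapses distinct feature
        # values into tied scores, so the scores no longer carry the
        # feature's ordering; use the exact rank statistic instead
        auroc = rank_auroc(values, y)
    else:
        a = roc_auc_score(y, scores)
        auroc = float(max(a, 1.0 - a))
    return AurocRecord(neuron=neuron, odor_pair=tuple(np.unique(labels)),
                       auroc=auroc, null_p=np.nan, n_shuffles=0)


def shuffle_pvalue(values: np.ndarray, labels, n_shuffles: int = 10000,
                   seed: int = 0) -> float:
    """Permutation p-value for the folded auROC.

    p = (1 + #{shuffled >= observed}) / (n_shuffles + 1); label permutations
    preserve class counts.  The shuffled statistic is computed in closed form
    from midranks (identical to retraining the logistic classifier).
    """
    rng = as_rng(seed)
    values = np.asarray(values, dtype=float)
    y = _as_binary(labels)
    n1, n0 = int(y.sum()), int((~y).sum())
    r = rankdata(values)
    observed = rank_auroc(values, y)
    perms = rng.permuted(np.tile(y, (n_shuffles, 1)), axis=1)
    r1 = perms @ r
    a = (r1 - n1 * (n1 + 1) / 2) / (n1 * n0)
    stat = np.maximum(a, 1.0 - a)
    return float((1 + np.sum(stat >= observed - 1e-12)) / (n_shuffles + 1))


def auroc_with_null(values: np.ndarray, labels, neuron: int = 0,
                    n_shuffles: int = 10000, seed: int = 0) -> AurocRecord:
    rec = fit_pairwise_auroc(values, labels, neuron=neuron)
    rec.null_p = shuffle_pvalue(values, labels, n_shuffles=n_shuffles, seed=seed)
    rec.n_shuffles = n_shuffles
    return rec


@dataclass
class QuadrantLabel:
    category: str            # valence | identity | identity_S | uninformative
    auroc_inter: float
    auroc_intra: float
    threshold: float


def quadrant_classify(auroc_inter: float, auroc_intra: float,
                      threshold: float = AUROC_THRESHOLD) -> QuadrantLabel:
    """Categorize a neuron from its intervalence ({S_K vs X_K}) and
    intravalence ({S_K vs S_T}) auROC values against one threshold.

    valence: discriminates across contingency but not within it;
    identity: both; identity_S: only the two sucrose cues; uninformative:
    neither.
    """
    if not (0 <= auroc_inter <= 1 and 0 <= auroc_intra <= 1):
        raise ValueError("auROC values must lie in [0, 1]")
    inter, intra = auroc_inter > threshold, auroc_intra > threshold
    category = ("identity" if inter and intra else
                "valence" if inter else
                "identity_S" if intra else "uninformative")
    return QuadrantLabel(category=category, auroc_inter=auroc_inter,
                         auroc_intra=auroc_intra, threshold=threshold)


def single_neuron_confusion(values: np.ndarray, labels, cv_folds: int = 5,
                            seed: int = 0) -> np.ndarray:
    """Row-stochastic confusion matrix of a cross-validated multinomial
    logistic classifier trained on one neuron's responses to all odors."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < cv_folds:
        raise ValueError(f"each class needs >= {cv_folds} trials")
    sd = values.std()
    x = ((values - values.mean()) / sd if sd > 0 else values * 0.0)[:, None]
    cv = StratifiedKFold(cv_folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        pred = cross_val_predict(LogisticRegression(max_iter=1000), x, labels, cv=cv)
    return confusion_matrix(labels, pred, labels=classes, normalize="true")
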