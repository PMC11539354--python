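"""Lick quantification and the decoupling of reward contingency from vigor.

Covers anticipatory-lick metrics, a 3-feature logistic lick classifier from
face-tracking channels (tongue-tip confidence, mouth-corner confidence, lip
distance) for spout-absent epochs, distributed-lag regression of a target
series on lagged behavioral features, per-neuron nested-regression ddF/F
decoupling (loss in R^2 when contingency or licking is omitted), and linear
models of pairwise decoder accuracy on behavioral and contingency
differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .synthetic import BehaviorTrace, OdorScheme, anticipatory_lick_counts, anticipatory_window


# ---------------------------------------------------------------------------
# Lick metrics and bouts
# ---------------------------------------------------------------------------

def lick_metrics(behavior: BehaviorTrace, trials: pd.DataFrame,
                 scheme: OdorScheme, window: tuple | None = None,
                 ma_window: int = 10) -> dict:
    """Per-odor lick rates in the analysis window, the sucrose-cue lick
    fraction, and trailing moving-average trends per odor.

    The S-fraction is licks during sucrose cues over licks during any odor;
    with zero odor-period licks it is NaN (flagged in the result).
    """
    if window is None:
        window = anticipatory_window(scheme)
    t0, t1 = window
    counts = anticipatory_lick_counts(behavior, trials, window=window)
    dur = t1 - t0
    df = trials.assign(licks=counts, lick_rate=counts / dur)
    per_odor = df.groupby("odor_label")["lick_rate"].mean()

    if scheme.paradigm == "exp1":
        s_mask = df["odor_label"].str.startswith("S").to_numpy()
    else:
        s_mask = (df["value"] > 0).to_numpy()
    total = counts.sum()
    s_fraction = float(counts[s_mask].sum() / total) if total else np.nan

    trends = (df.pivot_table(index="trial_index", columns="odor_label",
                             values="licks")
                .apply(lambda c: c.dropna().rolling(ma_window, min_periods=1)
                       .mean()))
    return dict(per_odor_rate=per_odor, s_fraction=s_fraction,
                trend=trends, per_trial=df,
                undefined=not bool(total))


def detect_lick_bouts(lick_times: np.ndarray, quiet_gap: float = 1.0,
                      min_licks: int = 3, bout_window: float = 1.0) -> np.ndarray:
    """Bout onsets: first lick after >= ``quiet_gap`` s without licks, kept
    only when >= ``min_licks`` licks fall within ``bout_window`` s."""
    t = np.sort(np.asarray(lick_times, dtype=float))
    if t.size == 0:
        return np.empty(0)
    gaps = np.diff(t, prepend=-np.inf)
    onsets = []
    for i in np.flatnonzero(gaps >= quiet_gap):
        n_in = np.searchsorted(t, t[i] + bout_window) - i
        if n_in >= min_licks:
            onsets.append(t[i])
    return np.asarray(onsets)


# ---------------------------------------------------------------------------
# Face-feature lick inference
# ---------------------------------------------------------------------------

def face_lick_classifier(face_features: np.ndarray, lick_state: np.ndarray,
                         folds: int = 5, seed: int = 0):
    """Logistic lick classifier from the 3 face channels.

    ``face_features`` is (3, frames); ``lick_state`` the per-frame binary
    ground truth from the capacitive sensor.  Returns the fitted classifier,
    its CV accuracy, and per-frame lick probabilities (usable on spout-absent
    frames where the sensor is blind).
    """
    x = np.asarray(face_features, dtype=float).T
    y = np.asarray(lick_state).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("lick ground truth has a single class")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        cv = StratifiedKFold(folds, shuffle=True, random_state=seed)
        clf = LogisticRegression(max_iter=1000)
        acc = cross_val_score(clf, x, y, cv=cv).mean()
        clf.fit(x, y)
    prob = clf.predict_proba(x)[:, 1]
    return clf, float(acc), prob


# ---------------------------------------------------------------------------
# Distributed-lag model
# ---------------------------------------------------------------------------

def distributed_lag_model(x: np.ndarray, y: np.ndarray, lags: tuple = (-10, 0),
                          ridge: float = 0.0, holdout: float = 0.25,
                          max_condition: float = 1e8) -> dict:
    """Least-squares fit of ``y`` on lagged copies of ``x``.

    ``x`` is (frames,) or (frames, channels); ``lags`` = (l_min, l_max) in
    frames, negative lags meaning features precede the target.  Returns
    coefficients indexed by (lag, channel), in-sample R^2, and out-of-sample
    R^2 on the trailing ``holdout`` fraction.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float).T).T
    y = np.asarray(y, dtype=float)
    l_min, l_max = lags
    span = l_max - l_min
    if span >= len(y) - 2:
        raise ValueError("lag window must be shorter than the series")
    lag_list = list(range(l_min, l_max + 1))
    rows = np.arange(-l_min, len(y) - max(l_max, 0))
    design = np.column_stack([x[rows + l, c] for l in lag_list
                              for c in range(x.shape[1])])
    target = y[rows]
    design = np.column_stack([np.ones(len(rows)), design])

    cond = np.linalg.cond(design)
    if cond > max_condition:
        raise ValueError(f"degenerate collinear design (condition number {cond:.3g})")

    n_train = int(np.floor(len(target) * (1 - holdout)))
    if ridge > 0:
        gram = design[:n_train].T @ design[:n_train]
        gram += ridge * np.eye(gram.shape[0])
        beta = np.linalg.solve(gram, design[:n_train].T @ target[:n_train])
    else:
        beta, *_ = np.linalg.lstsq(design[:n_train], target[:n_train], rcond=None)

    def _r2(a, b):
        ss = np.sum((b - b.mean()) ** 2)
        return 1.0 - np.sum((b - a) ** 2) / ss if ss > 0 else np.nan

    pred_in = design[:n_train] @ beta
    pred_out = design[n_train:] @ beta
    coef = beta[1:].reshape(len(lag_list), x.shape[1])
    return dict(lags=np.array(lag_list), coefficients=coef, intercept=beta[0],
                r2_in=_r2(pred_in, target[:n_train]),
                r2_out=_r2(pred_out, target[n_train:]),
                prediction=np.concatenate([pred_in, pred_out]),
                condition_number=cond)


# ---------------------------------------------------------------------------
# ddF/F decoupling and accuracy-vs-behavior models
# ---------------------------------------------------------------------------

@dataclass
class DecouplingRecord:
    """Per-neuron loss in R^2 when contingency (valence) or anticipatory
    licking is dropped from the full contingency x licking model."""

    neuron: int
    r2_full: float
    delta_r2_minus_valence: float
    delta_r2_minus_licking: float


def _ols_r2(y, cols):
    x = sm.add_constant(np.column_stack(cols)) if cols else np.ones((len(y), 1))
    return sm.OLS(y, x).fit().rsquared


def delta_r2_decoupling(ddff_per_trial: np.ndarray, contingency: np.ndarray,
                        anticipatory_licks: np.ndarray, neuron: int = 0,
                        drop_interaction: bool = True) -> DecouplingRecord:
    """Nested linear fits of a neuron's per-trial ddF/F.

    Full model: contingency + licking + interaction.  Each reduced model
    drops one variable (and, by default, the interaction); the resulting
    ddR^2 values are >= 0 by nesting.  Constant regressors make the
    corresponding ddR^2 undefined (NaN).
    """
    y = np.asarray(ddff_per_trial, dtype=float)
    c = np.asarray(contingency, dtype=float)
    l = np.asarray(anticipatory_licks, dtype=float)
    if len(y) < 10:
        raise ValueError("need >= 10 trials")
    c_ok, l_ok = np.ptp(c) > 0, np.ptp(l) > 0
    if not (c_ok and l_ok):
        r2f = np.nan
    else:
        r2f = _ols_r2(y, [c, l, c * l])
    d_val = r2f - _ols_r2(y, [l] if drop_interaction else [l, c * l]) if c_ok and l_ok else np.nan
    d_lick = r2f - _ols_r2(y, [c] if drop_interaction else [c, c * l]) if c_ok and l_ok else np.nan
    return DecouplingRecord(neuron=neuron, r2_full=r2f,
                            delta_r2_minus_valence=d_val,
                            delta_r2_minus_licking=d_lick)


@dataclass
class BehaviorModelFit:
    model: str                 # "lick" | "contingency" | "combined"
    coefficients: dict
    r_squared: float
    p_values: dict


def range_normalize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    span = x.max() - x.min()
    if span == 0:
        raise ValueError("zero-variance regressor cannot be range-normalized")
    return (x - x.min()) / span


def accuracy_behavior_models(accuracies: np.ndarray, delta_lick: np.ndarray,
                             delta_ps: np.ndarray) -> dict:
    """OLS fits of pairwise decoder accuracy on behavioral differences.

    Three models: lick-only (range-normalized dlick), contingency-only
    (dP(S)), and combined with interaction.  Returns a dict of
    :class:`BehaviorModelFit`; the combined R^2 is >= each single-model R^2
    by nesting.
    """
    acc = np.asarray(accuracies, dtype=float)
    dl = range_normalize(delta_lick)
    dp = np.asarray(delta_ps, dtype=float)
    for name, v in (("delta_lick", dl), ("delta_ps", dp)):
        if np.unique(v).size < 2:
            raise ValueError(f"regressor {name} has fewer than 2 distinct values")

    def _fit(name, cols, labels):
        x = sm.add_constant(np.column_stack(cols))
        res = sm.OLS(acc, x).fit()
        keys = ["intercept"] + labels
        return BehaviorModelFit(model=name,
                                coefficients=dict(zip(keys, res.params)),
                                r_squared=float(res.rsquared),
                                p_values=dict(zip(keys, res.pvalues)))

    return {
        "lick": _fit("lick", [dl], ["delta_lick"]),
        "contingency": _fit("contingency", [dp], ["delta_ps"]),
        "combined": _fit("combined", [dl, dp, dl * dp],
                         ["delta_lick", "delta_ps", "interaction"]),
    }
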