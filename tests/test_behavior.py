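"""Lick metrics, face-feature lick inference, lag models, decoupling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import pearsonr, ttest_rel

import odorcode as oc
from odorcode.behavior import (accuracy_behavior_models, delta_r2_decoupling,
                               detect_lick_bouts, distributed_lag_model,
                               face_lick_classifier, lick_metrics,
                               range_normalize)
from odorcode.synthetic import (anticipatory_lick_counts, anticipatory_window,
                                build_trial_table, make_ground_truth,
                                simulate_behavior, simulate_population)

from conftest import encoder_features


class TestLickMetrics:
    def _behavior_with_counts(self, trials, counts, window=(0.0, 2.0)):
        """Synthesize lick times so each trial has the requested count."""
        times = []
        for on, c in zip(trials["odor_on"], counts):
            times.extend(on + window[0] + 1e-3
                         + np.arange(c) * (window[1] - window[0] - 2e-3) / max(c, 1))
        from odorcode.synthetic import BehaviorTrace
        frames = np.arange(int((trials["us_time"].iloc[-1] + 12) * 5)) / 5.0
        return BehaviorTrace(lick_times=np.sort(np.array(times)),
                             frame_times=frames,
                             lick_count=np.zeros_like(frames),
                             locomotion=np.zeros_like(frames),
                             eye_area=np.zeros_like(frames),
                             face_features=np.zeros((3, frames.size)))

    def test_all_s_licks_give_fraction_one(self, exp1_scheme):
        t = build_trial_table(exp1_scheme, 5, seed=0)
        counts = np.where(t["odor_label"].str.startswith("S"), 4, 0)
        m = lick_metrics(self._behavior_with_counts(t, counts), t, exp1_scheme)
        assert m["s_fraction"] == 1.0

    def test_uniform_licking_fraction_one_third(self, exp1_scheme):
        t = build_trial_table(exp1_scheme, 5, seed=1)
        m = lick_metrics(self._behavior_with_counts(t, np.full(len(t), 3)),
                         t, exp1_scheme)
        assert m["s_fraction"] == pytest.approx(2 / 6)

    def test_zero_licks_flagged_undefined(self, exp1_scheme):
        t = build_trial_table(exp1_scheme, 2, seed=2)
        m = lick_metrics(self._behavior_with_counts(t, np.zeros(len(t), int)),
                         t, exp1_scheme)
        assert m["undefined"] and np.isnan(m["s_fraction"])

    def test_exp2_analysis_window(self, exp2_scheme):
        assert anticipatory_window(exp2_scheme) == (1.5, 2.5)


class TestLickBouts:
    def test_onsets_require_quiet_gap_and_enough_licks(self):
        licks = np.r_[1.0, 1.2, 1.4,          # bout
                      1.9,                     # continuation, no gap
                      5.0,                     # isolated lick: no bout
                      9.0, 9.3, 9.6]           # bout
        onsets = detect_lick_bouts(licks)
        assert onsets.tolist() == [1.0, 9.0]

    def test_every_onset_preceded_by_quiet_gap(self):
        rng = np.random.default_rng(3)
        licks = np.sort(rng.uniform(0, 300, 400))
        for onset in detect_lick_bouts(licks, quiet_gap=1.0):
            assert ((licks >= onset - 1.0) & (licks < onset)).sum() == 0


class TestFaceLickClassifier:
    def test_separable_features_decode_licking(self):
        rng = np.random.default_rng(4)
        y = rng.random(2000) < 0.3
        x = np.vstack([y * 3.0 + rng.normal(0, 1, 2000) for _ in range(3)])
        _, acc, prob = face_lick_classifier(x, y, seed=0)
        assert acc >= 0.95
        assert prob.shape == (2000,)

    def test_uninformative_features_at_majority_rate(self):
        accs = []
        for seed in range(15):
            rng = np.random.default_rng(100 + seed)
            y = rng.random(800) < 0.3
            x = rng.normal(0, 1, (3, 800))
            _, acc, _ = face_lick_classifier(x, y, seed=seed)
            accs.append(acc - max(y.mean(), 1 - y.mean()))
        accs = np.array(accs)
        assert abs(accs.mean()) < 2 * accs.std()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            face_lick_classifier(np.zeros((3, 10)), np.zeros(10))


class TestDistributedLagModel:
    def test_planted_lag_recovered(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 2000)
        y = np.roll(x, 3)  # y_t = x_{t-3}
        fit = distributed_lag_model(x, y, lags=(-6, 0))
        coef = fit["coefficients"][:, 0]
        lag_idx = fit["lags"].tolist().index(-3)
        assert coef[lag_idx] == pytest.approx(1.0, abs=0.05)
        assert np.abs(np.delete(coef, lag_idx)).max() < 0.05

    def test_white_noise_has_no_out_of_sample_skill(self):
        r2s = []
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            fit = distributed_lag_model(rng.normal(0, 1, 3000),
                                        rng.normal(0, 1, 3000), lags=(-10, 0))
            r2s.append(fit["r2_out"])
        assert np.mean(r2s) <= 0.02
        assert max(r2s) <= 0.05

    def test_lick_coupled_neuron_predicts_bout_onsets(self):
        """A neuron driven by lick rate predicts bout-onset indicators better
        than the same model fitted to a shuffled copy of its activity."""
        true_r2, shuf_r2 = [], []
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            rate = np.clip(np.convolve(rng.normal(0, 1, 3000),
                                       np.ones(20) / 4, "same"), 0, None)
            onset = np.r_[0, np.diff((rate > 1.5).astype(int)) > 0].astype(float)
            neuron = np.convolve(rate, np.exp(-np.arange(10) / 3), "same")
            neuron += rng.normal(0, 0.5, neuron.size)
            fit = distributed_lag_model(neuron, onset, lags=(-10, 0))
            sfit = distributed_lag_model(rng.permutation(neuron), onset,
                                         lags=(-10, 0))
            true_r2.append(fit["r2_out"])
            shuf_r2.append(sfit["r2_out"])
        assert ttest_rel(true_r2, shuf_r2).pvalue / 2 < 0.05
        assert np.mean(true_r2) > np.mean(shuf_r2)

    def test_collinear_design_rejected(self):
        x = np.ones(500)
        with pytest.raises(ValueError, match="condition"):
            distributed_lag_model(x, np.ones(500), lags=(-3, 0))


class TestDeltaR2Decoupling:
    def _trial_regressors(self, rng, n=180):
        c = rng.choice([0.0, 0.5, 1.0], n)
        licks = rng.poisson(1 + 3 * c * (rng.random(n) < 0.7))  # correlated
        return c, licks

    def test_planted_contingency_neuron(self):
        for seed in range(15):
            rng = np.random.default_rng(400 + seed)
            c, licks = self._trial_regressors(rng)
            y = 2.0 * c + rng.normal(0, 0.3, c.size)
            r = delta_r2_decoupling(y, c, licks)
            assert r.delta_r2_minus_valence > 0.5
            assert r.delta_r2_minus_licking < 0.05

    def test_planted_lick_neuron(self):
        for seed in range(15):
            rng = np.random.default_rng(500 + seed)
            c, licks = self._trial_regressors(rng)
            y = 0.8 * licks + rng.normal(0, 0.3, c.size)
            r = delta_r2_decoupling(y, c, licks)
            assert r.delta_r2_minus_licking > 0.5
            assert r.delta_r2_minus_valence < 0.05

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_nested_deltas_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        c, licks = self._trial_regressors(rng, n=40)
        y = rng.normal(0, 1, 40)
        r = delta_r2_decoupling(y, c, licks)
        assert r.delta_r2_minus_valence >= -1e-10
        assert r.delta_r2_minus_licking >= -1e-10

    def test_constant_regressor_flagged(self):
        rng = np.random.default_rng(6)
        r = delta_r2_decoupling(rng.normal(0, 1, 20), np.ones(20),
                                rng.poisson(2, 20))
        assert np.isnan(r.delta_r2_minus_valence)


class TestAccuracyBehaviorModels:
    def test_planted_contingency_model_recovered(self):
        rng = np.random.default_rng(7)
        dp = rng.choice([0.0, 0.5, 1.0], 15)
        dl = rng.random(15)
        acc = 0.5 + 0.3 * dp + rng.normal(0, 0.01, 15)
        fits = accuracy_behavior_models(acc, dl, dp)
        assert abs(fits["contingency"].coefficients["delta_ps"] - 0.3) < 0.05
        assert fits["lick"].r_squared < 0.1
        assert fits["combined"].r_squared >= fits["contingency"].r_squared - 1e-12

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_combined_model_never_worse(self, seed):
        rng = np.random.default_rng(seed)
        acc = rng.random(15)
        dl = rng.random(15)
        dp = rng.choice([0.0, 0.5, 1.0], 15)
        if np.unique(dp).size < 2:
            return
        fits = accuracy_behavior_models(acc, dl, dp)
        assert fits["combined"].r_squared >= fits["lick"].r_squared - 1e-10
        assert fits["combined"].r_squared >= fits["contingency"].r_squared - 1e-10

    def test_range_normalization(self):
        out = range_normalize(np.array([2.0, 4.0, 6.0]))
        assert out.tolist() == [0.0, 0.5, 1.0]
        with pytest.raises(ValueError, match="zero-variance"):
            range_normalize(np.ones(5))


class TestVigorValenceDissociation:
    def test_disjoint_subpopulations_reproduce_auroc_decoupling(self, exp2_scheme):
        """Pooled over sessions of disjoint valence- and lick-coding neurons,
        {N_hi vs N_X} discriminability correlates with {L_hi vs L_X} (shared
        contingency axis) but not with {L_hi vs N_hi} (pure vigor axis)."""
        inter, vigor, lick_contingency = [], [], []
        for seed in range(5):
            amp, labels, truth, trials = encoder_features(
                exp2_scheme, "valence", seed=7000 + seed, n_neurons=10,
                behavior="auto")
            amp2, labels2, truth2, _ = encoder_features(
                exp2_scheme, "vigor", seed=8000 + seed, n_neurons=10,
                behavior="auto")
            for a, lab in ((amp, labels), (amp2, labels2)):
                for n in range(a.shape[0]):
                    def auroc(pair):
                        sel = np.isin(lab, pair)
                        return oc.fit_pairwise_auroc(a[n, sel], lab[sel]).auroc
                    inter.append(auroc(("N_hi", "N_X")))
                    vigor.append(auroc(("L_hi", "N_hi")))
                    lick_contingency.append(auroc(("L_hi", "L_X")))
        r_vigor = pearsonr(inter, vigor)
        r_shared = pearsonr(inter, lick_contingency)
        assert r_shared.statistic > 0 and r_shared.pvalue < 0.05
        assert r_vigor.statistic < 0.2 or r_vigor.pvalue > 0.05
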