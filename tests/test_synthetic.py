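"""Simulator contracts: schemes, trial structure, behavior, encoding, rendering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare, pearsonr

import odorcode as oc
from odorcode.synthetic import (ODORS, anticipatory_lick_counts,
                                build_trial_table, make_ground_truth,
                                make_odor_scheme, render_calcium,
                                simulate_behavior, simulate_population,
                                simulate_session)


class TestOdorScheme:
    def test_exp1_day2_matches_study_contingencies(self):
        s = make_odor_scheme("exp1", 2)
        groups = {g: {o for o in ODORS if s.contingency[o] == g} for g in "SXP"}
        assert groups["S"] == {"heptanone", "pinene"}
        assert groups["P"] == {"octanone", "limonene"}
        assert groups["X"] == {"hexanone", "terpinene"}

    def test_contingency_switch_reassigns_every_odor(self):
        before, after = make_odor_scheme("exp1", 2), make_odor_scheme("exp1", 5)
        assert all(before.contingency[o] != after.contingency[o] for o in ODORS)

    def test_exp2_levels_cover_both_spout_groups(self):
        s = make_odor_scheme("exp2", 1)
        for p in (0.0, 0.5, 1.0):
            spouts = {s.spout[o] for o in ODORS if s.p_sucrose[o] == p}
            assert spouts == {"L", "N"}
        assert {s.label(o) for o in ODORS} == {
            "L_X", "L_lo", "L_hi", "N_X", "N_lo", "N_hi"}

    def test_unknown_paradigm_and_day_bounds(self):
        with pytest.raises(ValueError, match="paradigm"):
            make_odor_scheme("exp3", 1)
        with pytest.raises(ValueError, match="day"):
            make_odor_scheme("exp1", 7)

    def test_canonical_order_puts_sucrose_cues_first(self):
        s = make_odor_scheme("exp1", 2)
        labels = [s.label(o) for o in s.canonical_order()]
        assert labels == ["S_K", "S_T", "X_K", "X_T", "P_K", "P_T"]


class TestTrialTable:
    @pytest.mark.parametrize("n_blocks", [1, 5, 30])
    def test_counts_runs_and_timing(self, exp1_scheme, n_blocks):
        t = build_trial_table(exp1_scheme, n_blocks, seed=3)
        assert len(t) == 6 * n_blocks
        assert (t.groupby("odor").size() == n_blocks).all()
        odors = t["odor"].tolist()
        assert all(len(set(odors[i:i + 3])) > 1 for i in range(len(odors) - 2))
        # each block is a permutation of the six odors
        for b in range(n_blocks):
            assert set(odors[6 * b:6 * b + 6]) == set(ODORS)
        assert np.allclose(t["odor_off"] - t["odor_on"], 2.0)
        delay = t["us_time"] - t["odor_off"]
        assert ((delay >= 0.1) & (delay <= 0.3)).all()
        assert ((t["iti"] >= 12) & (t["iti"] <= 18)).all()

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n_blocks=st.integers(1, 8),
           paradigm=st.sampled_from(["exp1", "exp2"]))
    def test_structure_audit_random_configs(self, seed, n_blocks, paradigm):
        scheme = make_odor_scheme(paradigm, 2)
        t = build_trial_table(scheme, n_blocks, seed)
        odors = t["odor"].tolist()
        assert (t.groupby("odor").size() == n_blocks).all()
        assert all(len(set(odors[i:i + 3])) > 1 for i in range(len(odors) - 2))
        delay = t["us_time"] - t["odor_off"]
        lo, hi = (0.1, 0.3) if paradigm == "exp1" else (1.1, 1.3)
        assert ((delay >= lo) & (delay <= hi)).all()
        assert (t["odor_on"].diff().dropna() >= 12.0).all()
        if paradigm == "exp2":
            # sucrose only ever delivered on nonzero-probability odors
            assert (t.loc[t["us_type"] == "sucrose", "value"] > 0).all()
            assert t["spout_present"].eq(
                t["odor"].map(lambda o: scheme.spout[o] == "L")).all()


class TestBehavior:
    def test_no_learning_gives_equal_odor_lick_rates(self, exp1_scheme):
        counts = np.zeros(6)
        for seed in range(40):
            t = build_trial_table(exp1_scheme, 5, seed)
            b = simulate_behavior(t, exp1_scheme, learning_rate=0.0, seed=seed)
            licks = anticipatory_lick_counts(b, t, scheme=exp1_scheme)
            for o in range(6):
                counts[o] += licks[t["odor_index"] == o].sum()
        assert chisquare(counts).pvalue > 0.01

    def test_learned_licking_concentrates_on_sucrose_cues(self, exp1_scheme):
        t = build_trial_table(exp1_scheme, 30, seed=1)
        b = simulate_behavior(t, exp1_scheme, init_learning=1.0, seed=2)
        licks = anticipatory_lick_counts(b, t, scheme=exp1_scheme)
        s_mask = t["odor_label"].str.startswith("S").to_numpy()
        assert licks[s_mask].sum() / licks.sum() > 0.8

    def test_no_licks_while_spout_retracted(self, exp2_scheme):
        t = build_trial_table(exp2_scheme, 10, seed=4)
        b = simulate_behavior(t, exp2_scheme, init_learning=1.0, seed=5)
        for _, tr in t[~t["spout_present"]].iterrows():
            assert b.licks_in(tr.odor_on - 0.2, tr.odor_off + 1.0) == 0


class TestEncodingModel:
    def test_pure_valence_amplitudes_follow_contingency(self, exp1_scheme):
        t = build_trial_table(exp1_scheme, 2, seed=0)
        truth = make_ground_truth(n_valence=3, amplitude=1.0, noise_sd=0.0)
        amp = simulate_population(truth, t, None, seed=0, scheme=exp1_scheme)
        s_mask = t["odor_label"].str.startswith("S").to_numpy()
        assert np.allclose(amp[:, s_mask], 1.0)
        assert np.allclose(amp[:, ~s_mask], 0.0)

    def test_lick_coupled_amplitudes_track_lick_counts(self, exp1_scheme):
        t = build_trial_table(exp1_scheme, 30, seed=6)
        b = simulate_behavior(t, exp1_scheme, init_learning=1.0, seed=7)
        truth = make_ground_truth(n_vigor=1, amplitude=1.0, noise_sd=0.1,
                                  lick_per_amplitude=1.0)
        amp = simulate_population(truth, t, b, seed=8, scheme=exp1_scheme)
        licks = anticipatory_lick_counts(b, t, scheme=exp1_scheme)
        assert pearsonr(amp[0], licks).statistic > 0.7

    def test_silent_population_decodes_at_chance(self, exp1_scheme):
        accs = []
        for seed in range(20):
            t = build_trial_table(exp1_scheme, 10, seed)
            truth = make_ground_truth(n_silent=15, noise_sd=5.0, seed=seed)
            amp = simulate_population(truth, t, None, seed=seed,
                                      scheme=exp1_scheme)
            sel = t["odor_label"].isin(["S_K", "X_K"]).to_numpy()
            rec = oc.cv_pairwise_accuracy(amp[:, sel].T,
                                          t.loc[sel, "odor_label"], seed=seed)
            accs.append(rec.cv_accuracy)
        accs = np.array(accs)
        assert abs(accs.mean() - 0.5) < 2 * accs.std()

    def test_pure_encoder_rank_structure(self, exp1_scheme):
        """Noise-free identity / valence / vigor populations span <= 6 / 1 / 1
        dimensions over the odor-value/lick regressor space."""
        t = build_trial_table(exp1_scheme, 10, seed=9)
        b = simulate_behavior(t, exp1_scheme, init_learning=1.0, seed=9)
        for kind, max_rank in (("identity", 6), ("valence", 1), ("vigor", 1)):
            kw = dict(n_identity=0, n_valence=0, n_vigor=0, noise_sd=0.0)
            kw[f"n_{kind}"] = 12
            truth = make_ground_truth(**kw, seed=10)
            amp = simulate_population(truth, t, b, seed=11, scheme=exp1_scheme)
            assert np.linalg.matrix_rank(amp, tol=1e-8) <= max_rank


class TestRenderCalcium:
    def test_zero_amplitude_no_noise_is_flat_baseline(self, exp1_scheme):
        t = build_trial_table(exp1_scheme, 2, seed=0)
        truth = make_ground_truth(n_silent=2, noise_sd=0.0, drift_slope_sd=0.0,
                                  drift_sin_amp=0.0, us_responsive_valence=False)
        f = render_calcium(np.zeros((2, len(t))), truth, t, obs_noise_sd=0.0)
        assert np.allclose(f, 100.0)

    def test_kernel_halves_every_tau_ln2(self, exp1_scheme):
        t = build_trial_table(exp1_scheme, 1, seed=0)
        truth = make_ground_truth(n_silent=1, noise_sd=0.0, drift_slope_sd=0.0,
                                  drift_sin_amp=0.0, kernel_tau=1.5)
        amp = np.zeros((1, len(t)))
        amp[0, 0] = 10.0
        f = render_calcium(amp, truth, t, obs_noise_sd=0.0) - 100.0
        onset = int(round(t["odor_on"].iloc[0] * 5))
        assert f[0, onset] == pytest.approx(10.0)
        half_frames = int(round(1.5 * np.log(2) * 5))  # tau*ln2 at 5 Hz
        ratio = f[0, onset + half_frames] / f[0, onset]
        assert ratio == pytest.approx(0.5, rel=0.05)

    def test_output_strictly_positive(self, exp1_scheme):
        t = build_trial_table(exp1_scheme, 2, seed=0)
        truth = make_ground_truth(n_silent=2, noise_sd=0.0, baseline=1.0)
        amp = np.full((2, len(t)), -50.0)  # drive fluorescence negative
        f = render_calcium(amp, truth, t, obs_noise_sd=0.0)
        assert (f > 0).all()


class TestSessionContainer:
    def test_same_seed_bit_identical(self):
        a = simulate_session(n_blocks=2, seed=11)
        b = simulate_session(n_blocks=2, seed=11)
        assert np.array_equal(a.fluorescence, b.fluorescence)
        assert np.array_equal(a.behavior.lick_times, b.behavior.lick_times)
        assert a.trials.equals(b.trials)

    def test_frame_count_matches_duration(self):
        s = simulate_session(n_blocks=2, seed=12)
        dur = s.trials["us_time"].iloc[-1] + 12.0
        assert s.fluorescence.shape[1] == int(np.ceil(dur * 5))

    def test_hdf5_round_trip(self, tmp_path):
        s = simulate_session(n_blocks=2, seed=13)
        path = tmp_path / "session.h5"
        oc.save_session(s, path)
        r = oc.load_session(path)
        assert np.array_equal(r.fluorescence, s.fluorescence)
        assert np.array_equal(r.behavior.face_features, s.behavior.face_features)
        assert r.trials["odor"].tolist() == s.trials["odor"].tolist()
        assert np.array_equal(r.truth.w_identity, s.truth.w_identity)
        assert r.scheme.paradigm == s.scheme.paradigm
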