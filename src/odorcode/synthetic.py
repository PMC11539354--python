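"""Synthetic Pavlovian odor-conditioning sessions with known encoding structure.

Generates complete sessions -- GCaMP-like fluorescence, licking/locomotion/eye/
face behavior, trial metadata and per-neuron ground-truth encoding weights --
with the statistical structure the downstream analyses assume: 6 odors x 30
trials, 2 s odor, variable US delay, 12-18 s ITI, calcium transients on a
drifting baseline, and neurons whose odor-window amplitudes mix identity
tuning, valence (reward-contingency) tuning and lick-vigor coupling.

Two paradigms are supported.  ``exp1`` is six-odor classical conditioning
where each contingency group (sucrose S, nothing X, airpuff P) contains one
ketone and one terpene and contingencies are reassigned from day 4.  ``exp2``
is the lick/no-lick paradigm: the spout is retracted during three odors (N)
and present for three (L), with sucrose probability 0 / 0.5 / 1 represented
once in each spout group, decoupling reward contingency from licking vigor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import h5py
import numpy as np
import pandas as pd

from ._util import as_rng, derive_rng, logger

FRAME_RATE = 5.0  # Hz, galvo-galvo scan rate

KETONES = ("hexanone", "heptanone", "octanone")
TERPENES = ("terpinene", "pinene", "limonene")
ODORS = KETONES + TERPENES

# exp1 contingency maps (S sucrose / X nothing / P airpuff).
_EXP1_EARLY = {
    "heptanone": "S", "pinene": "S",
    "hexanone": "X", "terpinene": "X",
    "octanone": "P", "limonene": "P",
}
_EXP1_LATE = {
    "octanone": "S", "terpinene": "S",
    "heptanone": "X", "limonene": "X",
    "hexanone": "P", "pinene": "P",
}

# exp2: spout group (L = spout present, N = retracted) x sucrose probability.
_EXP2 = {
    "hexanone": ("L", 0.0), "heptanone": ("L", 0.5), "octanone": ("L", 1.0),
    "terpinene": ("N", 0.0), "pinene": ("N", 0.5), "limonene": ("N", 1.0),
}

ODOR_S = 2.0           # odor duration (s)
EXP1_DELAY = (0.1, 0.3)   # US delay after odor offset (s)
EXP2_DELAY = (1.1, 1.3)
ITI_RANGE = (12.0, 18.0)
SESSION_LEAD_S = 10.0  # recording before the first odor
SESSION_TAIL_S = 12.0

_CONTINGENCY_RANK = {"S": 0, "X": 1, "P": 2}


@dataclass(frozen=True)
class OdorScheme:
    """Odor -> chemical class and reward-contingency assignment for one day."""

    paradigm: str                      # "exp1" | "exp2"
    day: int
    odors: tuple = ODORS
    chem_class: Mapping[str, str] = field(default_factory=dict)
    contingency: Mapping[str, str] = field(default_factory=dict)    # exp1
    spout: Mapping[str, str] = field(default_factory=dict)          # exp2
    p_sucrose: Mapping[str, float] = field(default_factory=dict)    # exp2
    switch_day: int = 4
    signed_valence: bool = False   # exp1: P -> -1 instead of 0

    def value(self, odor: str) -> float:
        """Reward-contingency value regressor for the encoding model."""
        if self.paradigm == "exp1":
            c = self.contingency[odor]
            if c == "S":
                return 1.0
            if c == "P" and self.signed_valence:
                return -1.0
            return 0.0
        return float(self.p_sucrose[odor])

    def label(self, odor: str) -> str:
        """Field-standard short label: S_K/X_T/... (exp1), L_hi/N_X/... (exp2)."""
        if self.paradigm == "exp1":
            return f"{self.contingency[odor]}_{'K' if self.chem_class[odor] == 'ketone' else 'T'}"
        level = {0.0: "X", 0.5: "lo", 1.0: "hi"}[self.p_sucrose[odor]]
        return f"{self.spout[odor]}_{level}"

    def odor_by_label(self, label: str) -> str:
        for o in self.odors:
            if self.label(o) == label:
                return o
        raise KeyError(label)

    def canonical_order(self) -> list:
        """Odors ordered by contingency (sucrose first) then chemical class.

        Defines which class a pairwise decoder calls "1" so that labels map
        consistently across train/test pairs in generalization analyses.
        """
        if self.paradigm == "exp1":
            key = lambda o: (_CONTINGENCY_RANK[self.contingency[o]],
                             0 if self.chem_class[o] == "ketone" else 1)
        else:
            key = lambda o: (-self.p_sucrose[o], 0 if self.spout[o] == "L" else 1)
        return sorted(self.odors, key=key)

    def validate(self) -> None:
        if self.paradigm == "exp1":
            for group in "SXP":
                members = [o for o in self.odors if self.contingency[o] == group]
                classes = {self.chem_class[o] for o in members}
                if len(members) != 2 or classes != {"ketone", "terpene"}:
                    raise ValueError(f"contingency group {group} must hold one ketone "
                                     f"and one terpene, got {members}")
        else:
            for p in (0.0, 0.5, 1.0):
                spouts = sorted(self.spout[o] for o in self.odors if self.p_sucrose[o] == p)
                if spouts != ["L", "N"]:
                    raise ValueError(f"p_sucrose={p} must map to exactly one L and one N odor")


def make_odor_scheme(paradigm: str, day: int, seed: int = 0) -> OdorScheme:
    """Build the odor scheme for one session day.

    exp1 uses the study's fixed contingency maps, with every odor reassigned
    from ``switch_day`` (day 4) onward; exp2 is day-invariant.  ``seed`` is
    accepted for interface symmetry (the maps themselves are deterministic).
    """
    chem = {o: ("ketone" if o in KETONES else "terpene") for o in ODORS}
    if paradigm == "exp1":
        if not 1 <= day <= 6:
            raise ValueError(f"exp1 day must be in [1, 6], got {day}")
        contingency = _EXP1_LATE if day >= 4 else _EXP1_EARLY
        scheme = OdorScheme(paradigm="exp1", day=day, chem_class=chem,
                            contingency=dict(contingency))
    elif paradigm == "exp2":
        scheme = OdorScheme(paradigm="exp2", day=day, chem_class=chem,
                            spout={o: s for o, (s, _) in _EXP2.items()},
                            p_sucrose={o: p for o, (_, p) in _EXP2.items()})
    else:
        raise ValueError(f"unknown paradigm {paradigm!r}; expected 'exp1' or 'exp2'")
    scheme.validate()
    return scheme


# ---------------------------------------------------------------------------
# Trial tables
# ---------------------------------------------------------------------------

def _snap(t: float, frame_rate: float) -> float:
    return np.round(t * frame_rate) / frame_rate


def build_trial_table(scheme: OdorScheme, n_blocks: int = 30, seed: int = 0,
                      frame_rate: float = FRAME_RATE) -> pd.DataFrame:
    """Pseudorandomized trial schedule: ``n_blocks`` blocks, each a permutation
    of the 6 odors, with no odor repeated more than twice in a row (enforced
    across block boundaries).  Odor onsets are snapped to the frame grid.

    exp2 sucrose delivery is realized per trial as a Bernoulli draw at the
    odor's sucrose probability.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = as_rng(seed)
    order: list = []
    for _ in range(n_blocks):
        while True:
            block = list(rng.permutation(list(scheme.odors)))
            cand = order[-2:] + block
            ok = all(not (cand[i] == cand[i + 1] == cand[i + 2])
                     for i in range(len(cand) - 2))
            if ok:
                order.extend(block)
                break

    delay_lo, delay_hi = EXP1_DELAY if scheme.paradigm == "exp1" else EXP2_DELAY
    rows = []
    t = SESSION_LEAD_S
    for i, odor in enumerate(order):
        odor_on = _snap(t, frame_rate)
        odor_off = odor_on + ODOR_S
        delay = rng.uniform(delay_lo, delay_hi)
        us_time = odor_off + delay
        if scheme.paradigm == "exp1":
            cont = scheme.contingency[odor]
            us_type = {"S": "sucrose", "P": "airpuff", "X": "none"}[cont]
            spout_present = True
        else:
            p = scheme.p_sucrose[odor]
            us_type = "sucrose" if rng.random() < p else "none"
            spout_present = scheme.spout[odor] == "L"
        iti = rng.uniform(*ITI_RANGE)
        rows.append(dict(trial_index=i, block=i // 6, odor=odor,
                         odor_label=scheme.label(odor),
                         odor_index=scheme.odors.index(odor),
                         odor_on=odor_on, odor_off=odor_off,
                         us_type=us_type, us_time=us_time,
                         spout_present=spout_present, iti=iti,
                         value=scheme.value(odor)))
        t = odor_off + iti
    return pd.DataFrame(rows)


def session_duration(trials: pd.DataFrame) -> float:
    return float(trials["us_time"].iloc[-1] + SESSION_TAIL_S)


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------

@dataclass
class BehaviorTrace:
    """Licking, locomotion, eye and face-feature time series for one session.

    ``face_features`` rows are the lick-classifier inputs: tongue-tip
    confidence, mouth-corner confidence, upper-lower lip distance.
    """

    lick_times: np.ndarray          # sorted event timestamps (s)
    frame_times: np.ndarray         # (frames,) frame start times (s)
    lick_count: np.ndarray          # (frames,) licks per frame
    locomotion: np.ndarray          # (frames,) treadmill speed (a.u.)
    eye_area: np.ndarray            # (frames,) ellipse area (a.u.)
    face_features: np.ndarray       # (3, frames)
    frame_rate: float = FRAME_RATE

    def licks_in(self, t0: float, t1: float) -> int:
        return int(np.searchsorted(self.lick_times, t1) -
                   np.searchsorted(self.lick_times, t0))


def _spout_absence(trials: pd.DataFrame, paradigm: str):
    """(start, end) intervals during which the spout is retracted (exp2)."""
    if paradigm == "exp1":
        return []
    out = []
    for _, tr in trials.iterrows():
        if not tr.spout_present:
            # retracted 200 ms before odor, returns 100 ms before the
            # earliest possible sucrose time (delay >= 1.1 s)
            out.append((tr.odor_on - 0.2, tr.odor_off + 1.0))
    return out


def simulate_behavior(trials: pd.DataFrame, scheme: OdorScheme,
                      learning_rate: float = 0.05, seed: int = 0,
                      frame_rate: float = FRAME_RATE,
                      base_rate: float = 0.1, antic_rate: float = 4.0,
                      us_rate: float = 7.0, init_learning: float = 0.0,
                      feature_noise_sd: float = 0.15) -> BehaviorTrace:
    """Simulate licking (inhomogeneous Poisson), locomotion, eye area and
    face features for one session.

    The anticipatory lick rate ramps during rewarded odors from onset to US
    time, scaled by the odor's contingency value and a learning state
    ``g_k = init + (1 - init) * (1 - exp(-learning_rate * k))`` that grows
    across trials; a burst follows sucrose delivery; the rate is clamped to
    zero while the spout is retracted.  Locomotion dips and the eye closes
    partially during airpuff-predicting odors.  Face features are noisy
    deterministic functions of the per-frame lick state.
    """
    if learning_rate < 0:
        raise ValueError("learning_rate must be >= 0")
    rng = as_rng(seed)
    duration = session_duration(trials)
    n_frames = int(np.ceil(duration * frame_rate))
    frame_times = np.arange(n_frames) / frame_rate
    rate = np.full(n_frames, 0.05)  # background licking

    g = init_learning + (1.0 - init_learning) * (
        1.0 - np.exp(-learning_rate * np.arange(len(trials))))

    for k, tr in trials.iterrows():
        on, us = tr.odor_on, tr.us_time
        sel = (frame_times >= on) & (frame_times < us)
        ramp = (frame_times[sel] - on) / (us - on)
        rate[sel] += base_rate + g[k] * antic_rate * tr.value * ramp
        if tr.us_type == "sucrose":
            burst = (frame_times >= us) & (frame_times < us + 1.0)
            rate[burst] += us_rate

    for t0, t1 in _spout_absence(trials, scheme.paradigm):
        rate[(frame_times >= t0) & (frame_times < t1)] = 0.0

    dt = 1.0 / frame_rate
    lick_count = rng.poisson(rate * dt)
    lick_times = np.sort(np.concatenate([
        frame_times[i] + rng.uniform(0, dt, size=c)
        for i, c in enumerate(lick_count) if c
    ]) if lick_count.any() else np.empty(0))

    # locomotion: smoothed noise around a baseline, dip during airpuff cues
    loco = 3.0 + np.convolve(rng.normal(0, 1.0, n_frames), np.ones(10) / 10, "same")
    eye = 1.0 + rng.normal(0, 0.05, n_frames)
    if scheme.paradigm == "exp1":
        for _, tr in trials.iterrows():
            if scheme.contingency[tr.odor] == "P":
                sel = (frame_times >= tr.odor_on) & (frame_times < tr.odor_off + 1.0)
                loco[sel] *= 0.5
                eye[sel] *= 0.7

    lick_state = (lick_count > 0).astype(float)
    face = np.vstack([
        0.10 + 0.80 * lick_state + rng.normal(0, feature_noise_sd, n_frames),
        0.20 + 0.60 * lick_state + rng.normal(0, feature_noise_sd, n_frames),
        1.00 + 2.00 * lick_state + rng.normal(0, 2 * feature_noise_sd, n_frames),
    ])
    return BehaviorTrace(lick_times=lick_times, frame_times=frame_times,
                         lick_count=lick_count, locomotion=loco, eye_area=eye,
                         face_features=face, frame_rate=frame_rate)


def anticipatory_window(scheme: OdorScheme) -> tuple:
    """Per-trial analysis bin (s, relative to odor onset) for anticipatory licks.

    exp1: the 2 s odor period.  exp2: last 0.5 s of odor + first 0.5 s of the
    delay, mirroring the delayed-spout design.
    """
    return (0.0, 2.0) if scheme.paradigm == "exp1" else (1.5, 2.5)


def anticipatory_lick_counts(behavior: BehaviorTrace, trials: pd.DataFrame,
                             window: tuple | None = None,
                             scheme: OdorScheme | None = None) -> np.ndarray:
    """Per-trial lick counts in a window relative to odor onset."""
    if window is None:
        window = anticipatory_window(scheme) if scheme is not None else (0.0, 2.0)
    t0, t1 = window
    return np.array([behavior.licks_in(on + t0, on + t1)
                     for on in trials["odor_on"].to_numpy()])


# ---------------------------------------------------------------------------
# Ground-truth encoding and calcium rendering
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Latent per-neuron encoding weights and biophysical parameters.

    The per-trial odor-window response amplitude of neuron *n* is
    ``sign * (w_identity . onehot(odor) + w_valence * value(odor)
    + w_lick * anticipatory_licks)`` plus Gaussian trial noise; amplitudes are
    rendered as instantaneous rises convolved with an exponential decay kernel
    on a drifting baseline.  Units of weights, baseline and noise are raw
    fluorescence; ``kernel_tau`` is seconds.
    """

    w_identity: np.ndarray      # (n, 6)
    w_valence: np.ndarray       # (n,)
    w_lick: np.ndarray          # (n,)
    w_us: np.ndarray            # (n,) US (sucrose)-locked transient amplitude
    sign: np.ndarray            # (n,) +-1
    baseline_level: np.ndarray  # (n,)
    drift_slope: np.ndarray     # (n,) fluorescence/s
    drift_sin_amp: np.ndarray   # (n,)
    drift_sin_period: float     # s
    noise_sd: np.ndarray        # (n,) amplitude trial noise
    kernel_tau: np.ndarray      # (n,) s

    def __post_init__(self):
        if np.any(self.noise_sd < 0) or np.any(self.kernel_tau <= 0):
            raise ValueError("noise_sd must be >= 0 and kernel_tau > 0")

    @property
    def n_neurons(self) -> int:
        return len(self.w_valence)

    @property
    def encoding_class(self) -> np.ndarray:
        """identity / valence / vigor / mixed / silent, from the weight blocks."""
        out = []
        for i in range(self.n_neurons):
            blocks = (np.any(self.w_identity[i] != 0), self.w_valence[i] != 0,
                      self.w_lick[i] != 0)
            names = [n for n, b in zip(("identity", "valence", "vigor"), blocks) if b]
            out.append("silent" if not names else
                       names[0] if len(names) == 1 else "mixed")
        return np.array(out)


def make_ground_truth(n_identity: int = 0, n_valence: int = 0, n_vigor: int = 0,
                      n_silent: int = 0, amplitude: float = 15.0,
                      noise_sd: float = 5.0, frac_inhibited: float = 0.0,
                      baseline: float = 100.0, kernel_tau: float = 1.5,
                      drift_slope_sd: float = 0.002, drift_sin_amp: float = 2.0,
                      drift_sin_period: float = 600.0,
                      lick_per_amplitude: float = 5.0,
                      us_responsive_valence: bool = True,
                      seed: int = 0) -> GroundTruth:
    """Construct pure-encoder populations.

    ``amplitude`` is the discriminable-contrast scale, in fluorescence units.
    Identity neurons respond to the six odors with a random permutation of
    six levels spaced ``amplitude`` apart, so every odor pair carries an
    identity contrast of at least one ``amplitude`` (graded full-rank tuning,
    the archetype of a neuron that discriminates all stimuli); valence
    neurons couple ``amplitude`` to the contingency value; vigor neurons
    couple to the anticipatory lick count scaled so ``lick_per_amplitude``
    licks produce one ``amplitude``.  The default amplitude/noise ratio of 3
    is the regime in which the recovery properties are stated.  With
    ``us_responsive_valence`` the valence neurons also carry a sucrose-locked
    transient of size ``amplitude`` (the putative plasticity substrate:
    US-responsive neurons become cue-responsive).
    """
    rng = as_rng(seed)
    n = n_identity + n_valence + n_vigor + n_silent
    w_id = np.zeros((n, 6))
    w_val = np.zeros(n)
    w_lick = np.zeros(n)
    for i in range(n_identity):
        w_id[i] = amplitude * rng.permutation(6)
    w_val[n_identity:n_identity + n_valence] = amplitude
    w_lick[n_identity + n_valence:n_identity + n_valence + n_vigor] = (
        amplitude / lick_per_amplitude)
    w_us = np.zeros(n)
    if us_responsive_valence:
        w_us[n_identity:n_identity + n_valence] = amplitude
    sign = np.where(rng.random(n) < frac_inhibited, -1.0, 1.0)
    return GroundTruth(
        w_identity=w_id, w_valence=w_val, w_lick=w_lick, w_us=w_us, sign=sign,
        baseline_level=np.full(n, baseline),
        drift_slope=rng.normal(0, drift_slope_sd, n),
        drift_sin_amp=rng.uniform(0, drift_sin_amp, n),
        drift_sin_period=drift_sin_period,
        noise_sd=np.full(n, noise_sd),
        kernel_tau=np.full(n, kernel_tau),
    )


def simulate_population(truth: GroundTruth, trials: pd.DataFrame,
                        behavior: BehaviorTrace | None, seed: int = 0,
                        scheme: OdorScheme | None = None) -> np.ndarray:
    """Per-trial response amplitudes (neurons x trials) from the encoding model."""
    if truth.w_identity.shape[1] != 6:
        raise ValueError("w_identity must have 6 odor columns")
    rng = as_rng(seed)
    odor_idx = trials["odor_index"].to_numpy()
    value = trials["value"].to_numpy()
    if behavior is not None:
        licks = anticipatory_lick_counts(behavior, trials, scheme=scheme)
    else:
        licks = np.zeros(len(trials))
    amp = (truth.w_identity[:, odor_idx]
           + np.outer(truth.w_valence, value)
           + np.outer(truth.w_lick, licks))
    amp = truth.sign[:, None] * amp
    amp = amp + rng.normal(0, 1, amp.shape) * truth.noise_sd[:, None]
    return amp


def render_calcium(amplitudes: np.ndarray, truth: GroundTruth,
                   trials: pd.DataFrame, frame_rate: float = FRAME_RATE,
                   obs_noise_sd: float = 1.0, seed: int = 0,
                   clip_eps: float = 1e-6) -> np.ndarray:
    """Render amplitudes as fluorescence: an instantaneous rise at odor onset
    convolved with ``exp(-t / kernel_tau)``, on baseline + linear drift +
    sinusoid, plus Gaussian observation noise.  Output is clipped to stay
    strictly positive (clips are logged).
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be > 0")
    rng = as_rng(seed)
    n, n_trials = amplitudes.shape
    duration = session_duration(trials)
    n_frames = int(np.ceil(duration * frame_rate))
    t = np.arange(n_frames) / frame_rate

    f = (truth.baseline_level[:, None]
         + truth.drift_slope[:, None] * t[None, :]
         + truth.drift_sin_amp[:, None]
         * np.sin(2 * np.pi * t[None, :] / truth.drift_sin_period))

    onsets = trials["odor_on"].to_numpy()
    kern_len = int(np.ceil(10 * truth.kernel_tau.max() * frame_rate))
    tk = np.arange(kern_len) / frame_rate
    kernel = np.exp(-tk[None, :] / truth.kernel_tau[:, None])  # (n, kern_len)
    us_amp = truth.sign * truth.w_us
    for j in range(n_trials):
        i0 = int(np.round(onsets[j] * frame_rate))
        i1 = min(i0 + kern_len, n_frames)
        f[:, i0:i1] += amplitudes[:, j, None] * kernel[:, : i1 - i0]
        if trials["us_type"].iloc[j] == "sucrose" and np.any(us_amp):
            u0 = int(np.round(trials["us_time"].iloc[j] * frame_rate))
            u1 = min(u0 + kern_len, n_frames)
            f[:, u0:u1] += us_amp[:, None] * kernel[:, : u1 - u0]

    if obs_noise_sd > 0:
        f += rng.normal(0, obs_noise_sd, f.shape)
    n_clip = int(np.sum(f < clip_eps))
    if n_clip:
        logger.info("render_calcium: clipped %d sample(s) at %.1e", n_clip, clip_eps)
        f = np.maximum(f, clip_eps)
    return f


# ---------------------------------------------------------------------------
# Session container
# ---------------------------------------------------------------------------

@dataclass
class SimulatedSession:
    """One complete simulated session: fluorescence, behavior, metadata, truth."""

    fluorescence: np.ndarray        # (neurons, frames)
    behavior: BehaviorTrace
    trials: pd.DataFrame
    truth: GroundTruth
    scheme: OdorScheme
    seed: int
    frame_rate: float = FRAME_RATE


def simulate_session(paradigm: str = "exp1", day: int = 6, n_blocks: int = 30,
                     seed: int = 0, learning_rate: float = 0.05,
                     init_learning: float = 0.0, obs_noise_sd: float = 1.0,
                     truth: GroundTruth | None = None,
                     **truth_kwargs) -> SimulatedSession:
    """End-to-end session generation under a single root seed.

    ``truth_kwargs`` are forwarded to :func:`make_ground_truth` when no
    ground truth is supplied (default: 10 identity, 10 valence, 5 vigor and
    5 silent neurons).
    """
    scheme = make_odor_scheme(paradigm, day, seed)
    trials = build_trial_table(scheme, n_blocks, derive_rng(seed, "trials"))
    behavior = simulate_behavior(trials, scheme, learning_rate=learning_rate,
                                 init_learning=init_learning,
                                 seed=derive_rng(seed, "behavior"))
    if truth is None:
        truth_kwargs.setdefault("n_identity", 10)
        truth_kwargs.setdefault("n_valence", 10)
        truth_kwargs.setdefault("n_vigor", 5)
        truth_kwargs.setdefault("n_silent", 5)
        truth = make_ground_truth(seed=derive_rng(seed, "truth"), **truth_kwargs)
    amp = simulate_population(truth, trials, behavior,
                              seed=derive_rng(seed, "population"), scheme=scheme)
    fluor = render_calcium(amp, truth, trials, obs_noise_sd=obs_noise_sd,
                           seed=derive_rng(seed, "calcium"))
    return SimulatedSession(fluorescence=fluor, behavior=behavior, trials=trials,
                            truth=truth, scheme=scheme, seed=seed)


_TRIAL_COLS = ("trial_index", "block", "odor", "odor_label", "odor_index",
               "odor_on", "odor_off", "us_type", "us_time", "spout_present",
               "iti", "value")


def save_session(session: SimulatedSession, path) -> None:
    """Serialize a session to an HDF5 container.

    Layout: /fluorescence, /behavior/{lick_times,frame_times,lick_count,
    locomotion,eye_area,face_features}, /trials/<column>, /truth/<field>,
    with paradigm/day/seed as root attributes.
    """
    with h5py.File(path, "w") as h5:
        h5.attrs.update(paradigm=session.scheme.paradigm, day=session.scheme.day,
                        seed=session.seed, frame_rate=session.frame_rate)
        h5.create_dataset("fluorescence", data=session.fluorescence, track_times=False)
        b = h5.create_group("behavior")
        for name in ("lick_times", "frame_times", "lick_count", "locomotion",
                     "eye_area", "face_features"):
            b.create_dataset(name, data=getattr(session.behavior, name), track_times=False)
        tg = h5.create_group("trials")
        for col in _TRIAL_COLS:
            data = session.trials[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            tg.create_dataset(col, data=data, track_times=False)
        gt = h5.create_group("truth")
        tr = session.truth
        for name in ("w_identity", "w_valence", "w_lick", "w_us", "sign",
                     "baseline_level", "drift_slope", "drift_sin_amp",
                     "noise_sd", "kernel_tau"):
            gt.create_dataset(name, data=getattr(tr, name), track_times=False)
        gt.attrs["drift_sin_period"] = tr.drift_sin_period


def load_session(path) -> SimulatedSession:
    with h5py.File(path, "r") as h5:
        scheme = make_odor_scheme(h5.attrs["paradigm"], int(h5.attrs["day"]))
        cols = {}
        for col in _TRIAL_COLS:
            data = h5["trials"][col][()]
            if data.dtype.kind == "S":
                data = data.astype(str)
            cols[col] = data
        trials = pd.DataFrame(cols)
        b = h5["behavior"]
        behavior = BehaviorTrace(
            lick_times=b["lick_times"][()], frame_times=b["frame_times"][()],
            lick_count=b["lick_count"][()], locomotion=b["locomotion"][()],
            eye_area=b["eye_area"][()], face_features=b["face_features"][()],
            frame_rate=float(h5.attrs["frame_rate"]))
        gt = h5["truth"]
        truth = GroundTruth(
            w_identity=gt["w_identity"][()], w_valence=gt["w_valence"][()],
            w_lick=gt["w_lick"][()], w_us=gt["w_us"][()], sign=gt["sign"][()],
            baseline_level=gt["baseline_level"][()],
            drift_slope=gt["drift_slope"][()], drift_sin_amp=gt["drift_sin_amp"][()],
            drift_sin_period=float(gt.attrs["drift_sin_period"]),
            noise_sd=gt["noise_sd"][()], kernel_tau=gt["kernel_tau"][()])
        return SimulatedSession(fluorescence=h5["fluorescence"][()],
                                behavior=behavior, trials=trials, truth=truth,
                                scheme=scheme, seed=int(h5.attrs["seed"]),
                                frame_rate=float(h5.attrs["frame_rate"]))
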