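"""Configuration-driven orchestration: simulate -> preprocess -> analyze -> report.

A validated :class:`RunConfig` (YAML-loadable) drives deterministic stage
execution under a single root seed fanned out to named substreams.  Every
output directory carries the serialized config and a machine-readable
manifest (inputs, seeds, output hashes); a report stage regenerates summary
tables from the bundle alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geometry, population, profiles, single_neuron
from ._util import derive_rng, logger
from .behavior import delta_r2_decoupling, lick_metrics
from .preprocess import (align_trials, compute_dff, delta_delta_f,
                         estimate_moving_baseline, window_features)
from .responsiveness import responsiveness_table
from .synthetic import (anticipatory_lick_counts, make_ground_truth,
                        save_session, simulate_session)

STAGES = ("simulate", "preprocess", "analyze", "report")


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``RunConfig.from_yaml``)."""

    paradigm: str = "exp1"
    day: int = 6
    n_blocks: int = 30
    n_identity: int = 10
    n_valence: int = 10
    n_vigor: int = 5
    n_silent: int = 5
    amplitude: float = 15.0
    noise_sd: float = 5.0
    learning_rate: float = 0.05
    init_learning: float = 1.0
    seed: int = 0
    n_shuffles: int = 1000
    pr_subsample_k: int = 15
    pr_resamples: int = 200
    stages: tuple = STAGES
    out_dir: str = "odorcode_run"

    def validate(self) -> "RunConfig":
        if self.paradigm not in ("exp1", "exp2"):
            raise ValueError(f"paradigm must be exp1|exp2, got {self.paradigm!r}")
        if self.paradigm == "exp1" and not 1 <= self.day <= 6:
            raise ValueError("exp1 day must be in [1, 6]")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        counts = (self.n_identity, self.n_valence, self.n_vigor, self.n_silent)
        if any(c < 0 for c in counts) or sum(counts) < 1:
            raise ValueError("population counts must be >= 0 and sum >= 1")
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise_sd must be >= 0")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw).validate()

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{needed_by}' requires output {path.name} of stage "
            f"'{stage}', which was not run")
    return path


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    session_h5 = out / "session.h5"

    if "simulate" in config.stages:
        logger.info("stage simulate")
        truth = make_ground_truth(
            n_identity=config.n_identity, n_valence=config.n_valence,
            n_vigor=config.n_vigor, n_silent=config.n_silent,
            amplitude=config.amplitude, noise_sd=config.noise_sd,
            seed=derive_rng(config.seed, "truth"))
        session = simulate_session(
            paradigm=config.paradigm, day=config.day, n_blocks=config.n_blocks,
            seed=config.seed, learning_rate=config.learning_rate,
            init_learning=config.init_learning, truth=truth)
        save_session(session, session_h5)
        session.trials.to_csv(out / "trials.csv", index=False)
    else:
        session = None

    if "preprocess" in config.stages:
        logger.info("stage preprocess")
        if session is None:
            from .synthetic import load_session
            session = load_session(_require(session_h5, "simulate", "preprocess"))
        baseline = estimate_moving_baseline(session.fluorescence)
        dff = compute_dff(session.fluorescence, baseline)
        post = 8.0 if config.paradigm == "exp1" else 9.0
        tensor = align_trials(dff, session.trials, pre_s=2.0, post_s=post)
        np.savez(out / "dff_tensor.npz", values=tensor.values, time=tensor.time)
    else:
        tensor = None

    if "analyze" in config.stages:
        logger.info("stage analyze")
        if session is None:
            from .synthetic import load_session
            session = load_session(_require(session_h5, "simulate", "analyze"))
        if tensor is None:
            z = np.load(_require(out / "dff_tensor.npz", "preprocess", "analyze"))
            from .preprocess import DffTensor
            tensor = DffTensor(values=z["values"], time=z["time"],
                               trials=session.trials)
        _analyze(config, session, tensor, out)

    if "report" in config.stages:
        logger.info("stage report")
        write_report(out)

    manifest = dict(
        config=dataclasses.asdict(config) | {"stages": list(config.stages)},
        seed=config.seed,
        outputs={p.name: _sha256(p) for p in sorted(out.glob("*"))
                 if p.is_file() and p.name != "manifest.json"},
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _analyze(config: RunConfig, session, tensor, out: Path) -> None:
    scheme = session.scheme
    order = scheme.canonical_order()
    labels_in_order = [scheme.label(o) for o in order]
    window = (1.0, 2.0) if scheme.paradigm == "exp1" else (1.5, 2.5)

    responsiveness_table(tensor).to_csv(out / "responsiveness.csv", index=False)

    mag = delta_delta_f(tensor, odor_window=window)
    pd.DataFrame(mag.ddff, columns=mag.odor_labels).to_csv(
        out / "ddff.csv", index_label="neuron")

    feats = window_features(tensor, window=window)   # (neurons, trials)
    odor_labels = tensor.trials["odor_label"].to_numpy()
    # 5-fold CV unless short sessions leave fewer trials per odor
    folds = int(min(5, pd.Series(odor_labels).value_counts().min()))

    # single-neuron pairwise auROC + quadrants
    if scheme.paradigm == "exp1":
        inter_pair, intra_pair = ("S_K", "X_K"), ("S_K", "S_T")
    else:
        inter_pair, intra_pair = ("N_hi", "N_X"), ("L_hi", "N_hi")
    recs, quads = [], []
    for pair_name, pair in (("inter", inter_pair), ("intra", intra_pair)):
        sel = np.isin(odor_labels, pair)
        for n in range(tensor.n_neurons):
            rec = single_neuron.auroc_with_null(
                feats[n, sel], odor_labels[sel], neuron=n,
                n_shuffles=config.n_shuffles,
                seed=derive_rng(config.seed, f"auroc-{pair_name}-{n}"))
            recs.append(dict(neuron=n, pair="|".join(pair), axis=pair_name,
                             auroc=rec.auroc, p=rec.null_p,
                             n_shuffles=rec.n_shuffles))
    auroc_df = pd.DataFrame(recs)
    auroc_df.to_csv(out / "auroc.csv", index=False)
    wide = auroc_df.pivot_table(index="neuron", columns="axis", values="auroc")
    for n in wide.index:
        q = single_neuron.quadrant_classify(wide.loc[n, "inter"],
                                            wide.loc[n, "intra"])
        quads.append(dict(neuron=n, category=q.category,
                          auroc_inter=q.auroc_inter, auroc_intra=q.auroc_intra))
    pd.DataFrame(quads).to_csv(out / "quadrants.csv", index=False)

    # population pairwise decoding + generalization
    pop_rows = []
    for a, b in population.canonical_pairs(labels_in_order):
        sel = np.isin(odor_labels, (a, b))
        rec = population.cv_pairwise_accuracy(
            feats[:, sel].T, odor_labels[sel], folds=folds,
            seed=derive_rng(config.seed, f"pop-{a}-{b}").integers(2**31 - 1))
        pop_rows.append(dict(pair=f"{a}|{b}", cv_accuracy=rec.cv_accuracy))
    pd.DataFrame(pop_rows).to_csv(out / "population_accuracy.csv", index=False)

    gen = population.generalization_matrix(
        {lab: feats[:, odor_labels == lab].T for lab in labels_in_order},
        labels_in_order, folds=folds,
        seed=derive_rng(config.seed, "generalization").integers(2**31 - 1))
    gen.to_long().to_csv(out / "generalization.csv", index=False)

    # geometry
    k = min(config.pr_subsample_k, tensor.n_neurons)
    data = geometry.tensor_samples(tensor)
    pr_full = geometry.participation_ratio(data)
    pr_sub = geometry.subsampled_pr(
        data, k=k, n_resamples=config.pr_resamples,
        seed=derive_rng(config.seed, "pr").integers(2**31 - 1))
    pd.DataFrame([dict(kind="full", k=tensor.n_neurons, pr=pr_full.pr),
                  dict(kind="subsampled", k=k, pr=pr_sub.pr)]).to_csv(
        out / "participation_ratio.csv", index=False)
    geometry.distance_trajectories(tensor).to_long().to_csv(
        out / "distances.csv", index=False)

    # response profiles
    n_clusters = 6 if scheme.paradigm == "exp1" else 3
    cf = profiles.build_cluster_features(tensor)
    if cf.features.shape[0] >= n_clusters:
        ca = profiles.cluster_profiles(cf, n_clusters=n_clusters)
        pd.DataFrame(dict(neuron=ca.neuron_ids, cluster=ca.labels)).to_csv(
            out / "clusters.csv", index=False)

    # behavior + decoupling
    lm = lick_metrics(session.behavior, session.trials, scheme)
    lm["per_trial"][["trial_index", "odor_label", "spout_present",
                     "licks"]].to_csv(out / "behavior.csv", index=False)
    licks = anticipatory_lick_counts(session.behavior, session.trials,
                                     scheme=scheme)
    value = session.trials["value"].to_numpy()
    win_amp = window_features(tensor, window=window)
    dec_rows = []
    if np.ptp(value) > 0 and np.ptp(licks) > 0:
        for n in range(tensor.n_neurons):
            r = delta_r2_decoupling(win_amp[n], value, licks, neuron=n)
            dec_rows.append(dict(neuron=n, r2_full=r.r2_full,
                                 delta_r2_minus_valence=r.delta_r2_minus_valence,
                                 delta_r2_minus_licking=r.delta_r2_minus_licking))
    pd.DataFrame(dec_rows).to_csv(out / "decoupling.csv", index=False)


def write_report(out_dir) -> Path:
    """Regenerate summary tables from a completed bundle (no hidden state)."""
    out = Path(out_dir)
    rep = out / "report"
    rep.mkdir(exist_ok=True)

    resp = pd.read_csv(_require(out / "responsiveness.csv", "analyze", "report"))
    (resp.groupby("odor")["responsive"].mean().rename("fraction_responsive")
         .reset_index()
         .to_csv(rep / "responsive_fraction.csv", index=False))

    quads = pd.read_csv(_require(out / "quadrants.csv", "analyze", "report"))
    frac = (quads["category"].value_counts(normalize=True)
            .rename("fraction").rename_axis("category").reset_index())
    frac.to_csv(rep / "quadrant_fractions.csv", index=False)

    gen = pd.read_csv(_require(out / "generalization.csv", "analyze", "report"))
    gen.to_csv(rep / "generalization_long.csv", index=False)

    pr = pd.read_csv(_require(out / "participation_ratio.csv", "analyze", "report"))
    pr.to_csv(rep / "participation_ratio.csv", index=False)

    dec = out / "decoupling.csv"
    if dec.exists():
        pd.read_csv(dec).to_csv(rep / "decoupling_scatter.csv", index=False)
    return rep
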