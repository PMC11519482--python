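"""End-to-end orchestration: data -> norms -> encoder -> spectrum -> terms.

One configuration drives the whole offline-learning flow: obtain windows
(from a synthetic corpus or an episode log), fit homeostatic norms on the
train partition, train the emotional encoder, fit the mixture spectrum
over candidate component counts, name the clusters via LOVE profile
matching, and attribute smoothed step-wise emotions to episodes.  Every
stage persists its artifact so later stages (and reruns) consume only
persisted state; one global seed fans out deterministically to stage
seeds.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import encoder as enc
from . import love, spectrum as spec_mod, synth, trajectory as traj

logger = logging.getLogger("emospec")


def stage_seeds(global_seed: int, n: int = 4) -> list[int]:
    """Derive per-stage seeds from one global seed, below 2**31."""
    ss = np.random.SeedSequence(global_seed)
    return [int(s) for s in ss.generate_state(n) % (2 ** 31)]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything one pipeline run needs, with cross-field invariants."""

    W: int = 20
    seed: int = 0
    # data: either a synthetic corpus...
    synth_n: int = 2000
    synth_noise_sd: float = 0.5
    # ...or a pre-recorded episode log
    episode_log: str | None = None
    test_fraction: float = 0.195
    split_unit: str = "window"
    encoder: enc.EncoderConfig = field(default_factory=enc.EncoderConfig)
    k_candidates: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8, 9, 10)
    force_k: int | None = None
    mapping_spec: str = "2:5x6"
    band: love.BandConfig = field(default_factory=love.BandConfig)
    smoothing: spec_mod.SmoothingConfig = field(default_factory=spec_mod.SmoothingConfig)
    attribution_episodes: tuple[str, ...] = ("success", "failure")
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, val in raw.items():
            if key == "encoder":
                cfg.encoder = enc.EncoderConfig.from_dict(val)
            elif key == "band":
                cfg.band = love.BandConfig(**val)
            elif key == "smoothing":
                cfg.smoothing = spec_mod.SmoothingConfig(**val)
            elif key in ("k_candidates", "attribution_episodes"):
                setattr(cfg, key, tuple(val))
            elif hasattr(cfg, key):
                setattr(cfg, key, val)
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cfg


def validate_config(config: RunConfig) -> list[str]:
    """Check all cross-field invariants; return the aggregated error list."""
    errors: list[str] = []
    if config.W < 1:
        errors.append("W: must be positive")
    if config.encoder.W != config.W:
        errors.append(
            f"encoder.W ({config.encoder.W}) does not match pipeline W ({config.W})")
    if not 0 < config.test_fraction < 1:
        errors.append("test_fraction: must be in (0, 1)")
    if config.episode_log is not None and not Path(config.episode_log).exists():
        errors.append(f"episode_log: file {config.episode_log!r} does not exist")
    if config.episode_log is None and config.synth_n < 2:
        errors.append("synth_n: need at least 2 synthetic windows")
    if config.synth_noise_sd < 0:
        errors.append("synth_noise_sd: must be >= 0")
    if not config.k_candidates:
        errors.append("k_candidates: must be non-empty")
    elif min(config.k_candidates) < 1:
        errors.append("k_candidates: components must be >= 1")
    try:
        love.build_mapping(config.mapping_spec, config.W, config.band)
    except ValueError as exc:
        errors.append(f"mapping_spec: {exc}")
    if not 0 < config.smoothing.threshold <= 1:
        errors.append("smoothing.threshold: must be in (0, 1]")
    if not isinstance(config.seed, int):
        errors.append("seed: must be an integer")
    return errors


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunReport:
    parameter_count: int
    bic_table: dict[int, float]
    selected_k: int
    cluster_shares: dict[int, float]
    cluster_terms: dict[int, str]
    rmse: dict[str, float]
    seeds: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "parameter_count": self.parameter_count,
            "bic_table": self.bic_table,
            "selected_k": self.selected_k,
            "cluster_shares": self.cluster_shares,
            "cluster_terms": self.cluster_terms,
            "rmse_raw": self.rmse,
            "seeds": self.seeds,
        }

    def render_text(self) -> str:
        lines = [f"encoder parameters: {self.parameter_count}",
                 f"selected K: {self.selected_k}",
                 "BIC: " + ", ".join(f"K={k}: {v:.1f}"
                                     for k, v in sorted(self.bic_table.items())),
                 "raw-scale RMSE: " + ", ".join(f"{k}: {v:.3f}"
                                                for k, v in self.rmse.items()),
                 "clusters:"]
        for k in sorted(self.cluster_shares):
            lines.append(f"  {k}: {self.cluster_terms.get(k, 'unnamed')} "
                         f"({100 * self.cluster_shares[k]:.1f}%)")
        return "\n".join(lines)


def _build_dataset(config: RunConfig, seed: int) -> traj.SequenceDataset:
    if config.episode_log is not None:
        episodes = traj.read_episode_log(config.episode_log)
        windows, partition = [], []
        for ep in episodes:
            for w in traj.windowize(ep, config.W):
                windows.append(w)
                partition.append("train")
        dataset = traj.SequenceDataset(windows, partition, config.W,
                                       traj.DEFAULT_VARIABLES)
        unit = "episode" if config.split_unit == "episode" else "window"
        return traj.split_dataset(dataset, config.test_fraction, seed, unit=unit)
    sspec = synth.SynthSpec(W=config.W, noise_sd=config.synth_noise_sd, seed=seed)
    corpus = synth.generate_corpus(sspec, config.synth_n)
    return traj.split_dataset(corpus, config.test_fraction, seed,
                              unit=config.split_unit)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> RunReport:
    """Execute every stage in order, persisting all intermediate artifacts.

    Raises at the failing stage with the stage name; artifacts produced
    before the failure remain on disk.  Idempotent given the seeds.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    seeds = dict(zip(("data", "encoder", "spectrum", "episodes"),
                     stage_seeds(config.seed)))
    stage = "data"
    try:
        t0 = time.time()
        dataset = _build_dataset(config, seeds["data"])
        dataset = traj.normalize_dataset(traj.SequenceDataset(
            dataset.windows, dataset.partition, dataset.W, dataset.variables,
            norms=traj.fit_norms(dataset), labels=dataset.labels))
        traj.write_dataset(dataset, out / "dataset")
        logger.info("stage data done in %.1fs (n=%d, seed=%d)",
                    time.time() - t0, len(dataset), seeds["data"])

        stage = "encoder"
        t0 = time.time()
        config.encoder.training.seed = seeds["encoder"]
        model = enc.train(dataset, config.encoder)
        model.save(out / "model")
        rmse = enc.reconstruction_rmse(model, dataset, scale="raw", part="test")
        logger.info("stage encoder done in %.1fs (%d epochs, seed=%d)",
                    time.time() - t0, len(model.history["loss"]), seeds["encoder"])

        stage = "spectrum"
        t0 = time.time()
        latents = model.encode_batch(dataset.matrix())
        spectrum = spec_mod.fit_spectrum(latents, config.k_candidates,
                                         seed=seeds["spectrum"],
                                         force_k=config.force_k)
        assignments = spec_mod.assign_clusters(spectrum, latents)
        raw_dataset = traj.SequenceDataset(
            [traj.denormalize(w, dataset.norms) for w in dataset.windows],
            list(dataset.partition), dataset.W, dataset.variables,
            norms=dataset.norms, labels=dataset.labels)
        protos = spec_mod.prototype_sequences(spectrum, raw_dataset, assignments)
        logger.info("stage spectrum done in %.1fs (K=%d, seed=%d)",
                    time.time() - t0, spectrum.K, seeds["spectrum"])

        stage = "interpretation"
        mapping = love.build_mapping(config.mapping_spec, config.W, config.band)
        for proto in protos:
            if proto.empty:
                continue
            ranked = love.match_profile(proto.mean_sequence, mapping, dataset.norms)
            best = ranked[0][0]
            z_mean = ((proto.mean_sequence - dataset.norms.mean)
                      / dataset.norms.sd).mean(axis=0)
            term = mapping.term_for(best.labels, means=z_mean)
            spectrum.term_map[proto.cluster] = term or "unnamed"
        spectrum.save(out / "spectrum")

        stage = "attribution"
        attr_dir = out / "attributions"
        attr_dir.mkdir(exist_ok=True)
        for scenario in config.attribution_episodes:
            episode = synth.toy_episode(250, scenario, seed=seeds["episodes"],
                                        W=config.W)
            series = attribute_episode(episode, model, spectrum, dataset.norms,
                                       config.smoothing, W=config.W)
            render_episode_timeline(series, attr_dir / f"{scenario}.csv",
                                    term_map=spectrum.term_map)

        stage = "report"
        report = RunReport(
            parameter_count=enc.count_parameters(config.encoder, "encoder"),
            bic_table=spectrum.bic_table,
            selected_k=spectrum.K,
            cluster_shares={p.cluster: p.share for p in protos},
            cluster_terms=dict(spectrum.term_map),
            rmse=rmse,
            seeds=seeds,
        )
        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
        (out / "report.txt").write_text(report.render_text() + "\n")
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def attribute_episode(episode: traj.Episode, model: enc.TrainedEncoder,
                      spectrum: spec_mod.EmotionSpectrum,
                      norms: traj.HomeostatNorms,
                      smoothing: spec_mod.SmoothingConfig | None = None,
                      W: int = 20) -> spec_mod.AttributionSeries:
    """Windowize, normalize, encode and attribute one episode."""
    windows = traj.windowize(episode, W)
    if not windows:
        raise ValueError(f"episode {episode.episode_id!r} shorter than the window")
    X = np.stack([traj.normalize(w, norms).values for w in windows])
    probs = spec_mod.predict_proba(spectrum, model.encode_batch(X))
    return spec_mod.smooth_attributions(probs, smoothing, start_step=W - 1)


def render_episode_timeline(series: spec_mod.AttributionSeries,
                            out_csv: str | Path,
                            term_map: dict[int, str] | None = None,
                            image: str | Path | None = None) -> pd.DataFrame:
    """Write the per-step attribution table (and optionally a figure)."""
    if series.t.size == 0:
        raise ValueError("empty attribution series")
    K = series.probabilities.shape[1]
    df = pd.DataFrame({"t": series.t})
    for k in range(K):
        df[f"p_{k}"] = series.probabilities[:, k]
    df["raw_label"] = series.raw_labels
    df["smoothed_label"] = series.smoothed_labels
    if term_map is not None:
        df["term"] = series.terms(term_map)
    df.to_csv(out_csv, index=False)
    if image is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(10, 4))
        for k in range(K):
            label = term_map.get(k, f"cluster {k}") if term_map else f"cluster {k}"
            ax.plot(series.t, series.smoothed[:, k], label=label)
        ax.step(series.t, series.smoothed_labels / max(K - 1, 1), lw=0.8,
                color="k", alpha=0.4, label="attribution")
        ax.set_xlabel("step")
        ax.set_ylabel("smoothed probability")
        ax.legend(fontsize=7, ncol=2)
        fig.tight_layout()
        fig.savefig(image, dpi=120)
        plt.close(fig)
    return df


# ---------------------------------------------------------------------------
# planted-label recovery (synthetic ground truth evaluation)
# ---------------------------------------------------------------------------

@dataclass
class RecoveryResult:
    accuracy: float
    matched_templates: int
    n_classes: int
    cluster_to_class: dict[int, str]
    selected_k: int


def evaluate_recovery(sspec: synth.SynthSpec, n: int, encoder_config: enc.EncoderConfig,
                      k_candidates, seed: int = 0,
                      test_fraction: float = 0.2) -> RecoveryResult:
    """Train the full stack on a planted corpus and score label recovery.

    Windows are scored by the best one-to-one cluster/class matching
    (Hungarian assignment on the contingency table); prototype recovery
    counts the clusters whose prototype's nearest planted template is the
    template of the cluster's matched class.
    """
    seeds = stage_seeds(seed)
    corpus = synth.generate_corpus(sspec, n)
    dataset = traj.split_dataset(corpus, test_fraction, seeds[0], unit="window")
    dataset = traj.normalize_dataset(dataset)
    encoder_config.training.seed = seeds[1]
    model = enc.train(dataset, encoder_config)
    latents = model.encode_batch(dataset.matrix())
    spectrum = spec_mod.fit_spectrum(latents, k_candidates, seed=seeds[2])
    assignments = spec_mod.assign_clusters(spectrum, latents)

    classes = sorted(set(dataset.labels))
    class_idx = {c: i for i, c in enumerate(classes)}
    truth = np.array([class_idx[lab] for lab in dataset.labels])
    K = spectrum.K
    contingency = np.zeros((K, len(classes)), dtype=int)
    for a, t in zip(assignments, truth):
        contingency[a, t] += 1
    rows, cols = linear_sum_assignment(-contingency)
    cluster_to_class = {int(r): classes[int(c)] for r, c in zip(rows, cols)}
    accuracy = contingency[rows, cols].sum() / len(truth)

    raw_dataset = traj.SequenceDataset(
        [traj.denormalize(w, dataset.norms) for w in dataset.windows],
        list(dataset.partition), dataset.W, dataset.variables,
        norms=dataset.norms, labels=dataset.labels)
    protos = spec_mod.prototype_sequences(spectrum, raw_dataset, assignments)
    templates = sspec.template_mapping()
    matched = 0
    for proto in protos:
        if proto.empty or proto.cluster not in cluster_to_class:
            continue
        z = (proto.mean_sequence - dataset.norms.mean) / dataset.norms.sd
        dists = {cls: float(np.mean((z - tpl) ** 2))
                 for cls, tpl in templates.items()}
        best = min(dists, key=dists.get)
        if best == cluster_to_class[proto.cluster]:
            matched += 1
    return RecoveryResult(float(accuracy), matched, len(classes),
                          cluster_to_class, K)
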