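"""The emotional spectrum: a Gaussian mixture over the latent emotion space.

Distinct temporal patterns in the observed-value windows appear as
clusters of their latent encodings.  A full-covariance Gaussian mixture
fitted on the latents models this spectrum: each component is a learned
emotion, its posterior responsibilities give the step-wise probability
that the agent is "feeling" it, and the per-cluster average raw window
(the prototype sequence) is what gets matched against LOVE reference
profiles for naming.

Step-wise attributions are stabilized by a trailing moving average of the
probability series plus a hysteresis rule: the displayed label only
switches to a new cluster once its smoothed probability clears a high
threshold, or once it has been the raw argmax for a sustained run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.mixture import GaussianMixture

from .encoder import LatentEmotion
from .trajectory import SequenceDataset


@dataclass
class EmotionSpectrum:
    """Fitted mixture over the latent space, with fit metadata."""

    model: GaussianMixture
    seed: int
    bic_table: dict[int, float]
    selected_k: int
    term_map: dict[int, str] = field(default_factory=dict)

    @property
    def K(self) -> int:
        return self.selected_k

    @property
    def weights(self) -> np.ndarray:
        return self.model.weights_

    @property
    def means(self) -> np.ndarray:
        return self.model.means_

    @property
    def covariances(self) -> np.ndarray:
        return self.model.covariances_

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "seed": self.seed,
            "selected_k": self.selected_k,
            "bic_table": {str(k): v for k, v in self.bic_table.items()},
            "term_map": {str(k): v for k, v in self.term_map.items()},
        }
        (path / "spectrum.json").write_text(json.dumps(meta, indent=2))
        np.savez(path / "spectrum.npz", weights=self.model.weights_,
                 means=self.model.means_, covariances=self.model.covariances_,
                 precisions_cholesky=self.model.precisions_cholesky_)

    @classmethod
    def load(cls, path: str | Path) -> "EmotionSpectrum":
        path = Path(path)
        meta = json.loads((path / "spectrum.json").read_text())
        with np.load(path / "spectrum.npz") as npz:
            arrays = {k: npz[k] for k in npz.files}
        K, d = arrays["means"].shape
        gm = GaussianMixture(n_components=K, covariance_type="full")
        gm.weights_ = arrays["weights"]
        gm.means_ = arrays["means"]
        gm.covariances_ = arrays["covariances"]
        gm.precisions_cholesky_ = arrays["precisions_cholesky"]
        return cls(gm, int(meta["seed"]),
                   {int(k): v for k, v in meta["bic_table"].items()},
                   int(meta["selected_k"]),
                   {int(k): v for k, v in meta["term_map"].items()})


def _as_matrix(latents) -> np.ndarray:
    if isinstance(latents, np.ndarray):
        X = latents
    else:
        X = np.stack([l.psi if isinstance(l, LatentEmotion) else np.asarray(l)
                      for l in latents])
    if X.ndim != 2:
        raise ValueError("latents must form an (n, d) matrix")
    return X


def fit_spectrum(latents, K_candidates, seed: int = 0,
                 force_k: int | None = None, reg_covar: float = 1e-6,
                 ) -> EmotionSpectrum:
    """Fit full-covariance mixtures over candidate K and keep the best.

    Selection is lowest BIC by default; ``force_k`` overrides it (the
    component count is ultimately an interpretive choice).  A small
    diagonal jitter (``reg_covar``) guards against singular covariances.
    Deterministic given ``seed``.
    """
    X = _as_matrix(latents)
    candidates = sorted(set(int(k) for k in K_candidates))
    if not candidates:
        raise ValueError("K_candidates must be non-empty")
    if candidates[0] < 1:
        raise ValueError("candidate K must be >= 1")
    if X.shape[0] < max(candidates):
        raise ValueError(
            f"n={X.shape[0]} latents cannot support K={max(candidates)} components"
        )
    if force_k is not None and force_k not in candidates:
        candidates.append(force_k)
        candidates.sort()

    bic_table: dict[int, float] = {}
    models: dict[int, GaussianMixture] = {}
    for K in candidates:
        gm = GaussianMixture(n_components=K, covariance_type="full",
                             random_state=seed, reg_covar=reg_covar, n_init=3)
        try:
            gm.fit(X)
        except Exception as exc:  # singular / degenerate data
            raise ValueError(
                f"mixture fit failed for K={K} (possibly duplicate points); "
                f"consider raising reg_covar: {exc}"
            ) from exc
        bic_table[K] = float(gm.bic(X))
        models[K] = gm
    selected = force_k if force_k is not None else min(bic_table, key=bic_table.get)
    return EmotionSpectrum(models[selected], seed, bic_table, selected)


def predict_proba(spectrum: EmotionSpectrum, latents) -> np.ndarray:
    """Posterior responsibilities over the K components; rows sum to 1."""
    if not hasattr(spectrum.model, "weights_"):
        raise ValueError("spectrum is not fitted")
    X = _as_matrix(latents if not isinstance(latents, LatentEmotion)
                   else [latents])
    return spectrum.model.predict_proba(X)


def assign_clusters(spectrum: EmotionSpectrum, latents) -> np.ndarray:
    """Hard maximum-responsibility assignment per latent."""
    return np.argmax(predict_proba(spectrum, latents), axis=1)


# ---------------------------------------------------------------------------
# prototypes
# ---------------------------------------------------------------------------

@dataclass
class ClusterPrototype:
    """Per-step mean +- sd of the raw windows assigned to one cluster."""

    cluster: int
    mean_sequence: np.ndarray   # W x V
    sd_sequence: np.ndarray     # W x V
    member_count: int
    share: float
    empty: bool = False


def prototype_sequences(spectrum: EmotionSpectrum, dataset: SequenceDataset,
                        assignments: np.ndarray) -> list[ClusterPrototype]:
    """Average member windows (raw scale) per hard-assigned cluster.

    Shares are member counts over the total; an empty cluster yields a
    zero-member prototype flagged ``empty``.
    """
    assignments = np.asarray(assignments)
    if len(assignments) != len(dataset):
        raise ValueError("one assignment per dataset window is required")
    X = dataset.matrix()
    total = len(dataset)
    protos = []
    for k in range(spectrum.K):
        members = X[assignments == k]
        if members.shape[0] == 0:
            shape = (dataset.W, len(dataset.variables))
            protos.append(ClusterPrototype(k, np.zeros(shape), np.zeros(shape),
                                           0, 0.0, empty=True))
            continue
        protos.append(ClusterPrototype(
            k, members.mean(axis=0), members.std(axis=0),
            int(members.shape[0]), members.shape[0] / total))
    return protos


# ---------------------------------------------------------------------------
# attribution smoothing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SmoothingConfig:
    """Hysteresis rules for stable step-wise attributions.

    ``ma_window``: trailing moving-average length on the probability
    series; ``threshold``: smoothed probability needed to license a label
    switch; ``min_consecutive``: alternatively, how many consecutive raw
    argmax steps a challenger needs; ``rule``: "either" | "threshold" |
    "consecutive".
    """

    ma_window: int = 5
    threshold: float = 0.9
    min_consecutive: int = 10
    rule: str = "either"

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")
        if self.ma_window < 1 or self.min_consecutive < 1:
            raise ValueError("ma_window and min_consecutive must be >= 1")
        if self.rule not in ("either", "threshold", "consecutive"):
            raise ValueError(f"unknown smoothing rule {self.rule!r}")


@dataclass
class AttributionSeries:
    """Step-wise emotion attribution for one episode, starting at t = W-1."""

    t: np.ndarray                 # step indices, first is W-1
    probabilities: np.ndarray     # raw posterior series, (T, K)
    smoothed: np.ndarray          # moving-average series, (T, K)
    raw_labels: np.ndarray
    smoothed_labels: np.ndarray
    config: SmoothingConfig

    def terms(self, term_map: dict[int, str]) -> list[str]:
        return [term_map.get(int(k), f"cluster {k}") for k in self.smoothed_labels]


def smooth_attributions(probabilities: np.ndarray, config: SmoothingConfig | None = None,
                        start_step: int = 19) -> AttributionSeries:
    """Smooth a probability series and apply the label-switch hysteresis.

    The moving average is trailing (causal): the smoothed vector at t uses
    only probabilities at steps <= t, renormalized to sum to 1.  The
    displayed label starts at the first raw argmax and thereafter switches
    to cluster k only when the smoothed p_k reaches the threshold, or when
    k has been the raw argmax for ``min_consecutive`` consecutive steps.
    ``start_step`` is the episode step index of the first attribution
    (W - 1: earlier steps carry no attribution).
    """
    config = config or SmoothingConfig()
    P = np.asarray(probabilities, dtype=float)
    if P.ndim != 2 or P.shape[0] == 0:
        raise ValueError("probabilities must be a non-empty (T, K) series")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("each probability vector must sum to 1")
    T, K = P.shape
    smoothed = np.empty_like(P)
    for t in range(T):
        lo = max(0, t - config.ma_window + 1)
        avg = P[lo:t + 1].mean(axis=0)
        smoothed[t] = avg / avg.sum()
    raw_labels = np.argmax(P, axis=1)

    labels = np.empty(T, dtype=int)
    current = int(raw_labels[0])
    labels[0] = current
    run_label, run_len = int(raw_labels[0]), 1
    for t in range(1, T):
        if raw_labels[t] == run_label:
            run_len += 1
        else:
            run_label, run_len = int(raw_labels[t]), 1
        challenger = int(np.argmax(smoothed[t]))
        by_threshold = (challenger != current
                        and smoothed[t, challenger] >= config.threshold)
        by_run = (run_label != current and run_len >= config.min_consecutive)
        if config.rule == "threshold":
            by_run = False
        elif config.rule == "consecutive":
            by_threshold = False
        if by_threshold:
            current = challenger
        elif by_run:
            current = run_label
        labels[t] = current

    t_index = start_step + np.arange(T)
    return AttributionSeries(t_index, P, smoothed, raw_labels, labels, config)
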