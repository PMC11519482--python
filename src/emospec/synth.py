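"""Synthetic inputs with the statistical structure the framework assumes.

Every stage of the pipeline is testable without an RL agent: windows are
planted LOVE-profile templates (sigma units) plus Gaussian noise,
de-standardized to realistic raw scales -- rewards centered at 0.67 with
sd 5.60, state-values at 62.41 with sd 18.99, matching the magnitudes of
recorded lunar-landing rollouts.  Scripted toy episodes emulate a
successful landing (drifting positive expectations, large terminal
reward) and a failed one (mid-episode expectation collapse, large
negative terminal reward).  A two-way random-effects survey generator
exercises the reliability statistics with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .love import LOVEMapping, build_mapping, _template_curve
from .padval import PAD_DIMENSIONS, SurveyDataset
from .trajectory import (Episode, HomeostatNorms, SequenceDataset,
                         SequenceWindow, StepRecord)

#: raw-scale anchors: historical mean/sd of each observed value
DEFAULT_ANCHORS = {"reward": (0.67, 5.60), "state_value": (62.41, 18.99)}

#: the eight planted classes used throughout: the learned-emotion
#: profiles of the lunar-landing case (template in sigma units per class)
DEFAULT_CLASSES: dict[str, tuple[str, str, float]] = {
    # name: (reward pattern, expectation pattern, expectation level gain)
    "distress": ("negative", "negative", 1.0),
    "optimism": ("average", "positive", 1.0),
    "neutral": ("average", "average", 1.0),
    "satisfaction": ("increased", "decreased_to_average", 1.0),
    "high optimism": ("average", "positive", 2.0),
    "concern": ("average", "negative", 1.0),
    "excitement": ("average", "increased", 1.0),
    "fear": ("average", "decreased_to_negative", 1.0),
}


@dataclass
class SynthSpec:
    """Recipe for a planted-profile corpus."""

    W: int = 20
    variables: tuple[str, str] = ("reward", "state_value")
    classes: dict[str, tuple[str, str, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLASSES))
    weights: dict[str, float] | None = None   # default: equal
    noise_sd: float = 0.5
    anchors: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ANCHORS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        for name, (mu, sigma) in self.anchors.items():
            if sigma <= 0:
                raise ValueError(f"anchor sd for {name!r} must be positive")
        if self.weights is not None:
            w = np.array([self.weights[c] for c in self.classes])
            if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
                raise ValueError("class weights must be non-negative and sum to 1")

    @property
    def anchor_mean(self) -> np.ndarray:
        return np.array([self.anchors[v][0] for v in self.variables])

    @property
    def anchor_sd(self) -> np.ndarray:
        return np.array([self.anchors[v][1] for v in self.variables])

    def norms(self) -> HomeostatNorms:
        """The anchors as homeostatic references (for noise-free checks)."""
        return HomeostatNorms(self.variables, self.anchor_mean,
                              self.anchor_sd, n_samples=0)

    def template(self, cls: str) -> np.ndarray:
        """W x 2 planted template in sigma units for one class."""
        if cls not in self.classes:
            raise KeyError(f"unknown class {cls!r}; known: {sorted(self.classes)}")
        rp, ep, gain = self.classes[cls]
        return np.column_stack([_template_curve(rp, self.W),
                                gain * _template_curve(ep, self.W)])

    def template_mapping(self) -> "dict[str, np.ndarray]":
        return {c: self.template(c) for c in self.classes}


def generate_window(spec: SynthSpec, cls: str,
                    rng: np.random.Generator | None = None,
                    index: int = 0) -> tuple[SequenceWindow, str]:
    """One raw-scale window: planted template + iid Gaussian noise."""
    rng = rng or np.random.default_rng(spec.seed)
    z = spec.template(cls) + rng.normal(0.0, spec.noise_sd, size=(spec.W, 2))
    raw = z * spec.anchor_sd + spec.anchor_mean
    return SequenceWindow(raw, (f"synth:{cls}", spec.W - 1 + index)), cls


def generate_corpus(spec: SynthSpec, n: int) -> SequenceDataset:
    """A labeled corpus of n windows with multinomial class mixture.

    All windows start on the train partition; use
    :func:`emospec.trajectory.split_dataset` to carve out a test set.
    Reproducible given ``spec.seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(spec.seed)
    names = list(spec.classes)
    probs = (np.full(len(names), 1.0 / len(names)) if spec.weights is None
             else np.array([spec.weights[c] for c in names]))
    draws = rng.choice(len(names), size=n, p=probs)
    windows, labels = [], []
    for i, ci in enumerate(draws):
        w, lab = generate_window(spec, names[ci], rng, index=i)
        windows.append(w)
        labels.append(lab)
    return SequenceDataset(windows, ["train"] * n, spec.W, spec.variables,
                           labels=labels)


# ---------------------------------------------------------------------------
# scripted toy episodes
# ---------------------------------------------------------------------------

def toy_episode(length: int, scenario: str, seed: int = 0,
                noise_sd: float = 0.0, W: int = 20,
                anchors: dict[str, tuple[float, float]] | None = None,
                ) -> Episode:
    """A scripted landing episode with recognizable emotional structure.

    ``scenario='success'``: expectations drift upward and the episode
    ends with a large positive terminal reward.  ``scenario='failure'``:
    expectations collapse mid-episode over exactly one window length (a
    ramp from average to -1 sigma -- the fear signature), then stay
    depressed until a large negative terminal reward.  Deterministic per
    seed; at ``noise_sd=0`` the trajectories are exactly the script.
    """
    if length < W:
        raise ValueError(f"episode length {length} must be >= window {W}")
    if scenario not in ("success", "failure"):
        raise ValueError("scenario must be 'success' or 'failure'")
    anchors = anchors or DEFAULT_ANCHORS
    mu_r, sd_r = anchors["reward"]
    mu_v, sd_v = anchors["state_value"]
    rng = np.random.default_rng(seed)

    z_v = np.zeros(length)
    if scenario == "success":
        z_v = np.linspace(-0.2, 1.2, length)
        terminal = 100.0
    else:
        collapse_at = length // 2
        ramp_end = collapse_at + W
        z_v[:collapse_at] = 0.0
        z_v[collapse_at:ramp_end] = np.linspace(0.0, -1.0, min(W, length - collapse_at))
        z_v[ramp_end:] = -1.0
        terminal = -100.0
    rewards = np.full(length, mu_r) + rng.normal(0.0, noise_sd * sd_r, size=length)
    state_values = mu_v + sd_v * z_v + rng.normal(0.0, noise_sd * sd_v, size=length)
    rewards[-1] = terminal
    steps = [StepRecord(t, float(rewards[t]), float(state_values[t]))
             for t in range(length)]
    return Episode(f"toy-{scenario}-{seed}", steps)


# ---------------------------------------------------------------------------
# survey fixtures
# ---------------------------------------------------------------------------

@dataclass
class SurveyEffectSpec:
    """Two-way random-effects variances for the survey generator."""

    grand_mean: float = 5.0
    target_sd: float = 1.5     # between-video (true emotion) spread
    rater_sd: float = 0.5      # systematic rater bias spread
    noise_sd: float = 0.5      # residual
    dimension_shift: float = 0.0   # offset between PAD dimensions

    def __post_init__(self) -> None:
        if min(self.target_sd, self.rater_sd, self.noise_sd) < 0:
            raise ValueError("variance components must be >= 0")

    def analytic_icc2k(self, k_raters: int) -> float:
        """Population ICC(2,k) implied by the variance components."""
        st2, sr2, se2 = self.target_sd**2, self.rater_sd**2, self.noise_sd**2
        return st2 / (st2 + (sr2 + se2) / k_raters)


def survey_fixture(n_raters: int, n_videos: int,
                   effect: SurveyEffectSpec | None = None,
                   seed: int = 0) -> SurveyDataset:
    """Generate a complete rater x video PAD survey with known structure.

    Ratings follow y_ij = mu + target_i + rater_j + noise_ij per
    dimension (independent draws per dimension), unbounded scale so the
    ANOVA decomposition stays exact.
    """
    if n_raters < 2 or n_videos < 2:
        raise ValueError("need at least 2 raters and 2 videos")
    effect = effect or SurveyEffectSpec()
    rng = np.random.default_rng(seed)
    rows = []
    for d_i, dim in enumerate(PAD_DIMENSIONS):
        targets = rng.normal(0.0, effect.target_sd, size=n_videos)
        raters = rng.normal(0.0, effect.rater_sd, size=n_raters)
        noise = rng.normal(0.0, effect.noise_sd, size=(n_videos, n_raters))
        base = effect.grand_mean + d_i * effect.dimension_shift
        vals = base + targets[:, None] + raters[None, :] + noise
        for vi in range(n_videos):
            for ri in range(n_raters):
                rows.append({"video_id": f"v{vi:03d}", "rater_id": f"r{ri:03d}",
                             "dim": dim, "value": vals[vi, ri]})
    df = pd.DataFrame(rows).pivot(index=["rater_id", "video_id"],
                                  columns="dim", values="value").reset_index()
    df = df[["rater_id", "video_id", *PAD_DIMENSIONS]]
    return SurveyDataset(df, scale=None)
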