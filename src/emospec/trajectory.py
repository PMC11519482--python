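"""Multivariate time series of per-step observed values from agent episodes.

An episode log records, for every environment step, the scalar values an
agent can "feel": the instantaneous reward and the critic's state-value
estimate (plus optional extras such as the TD error).  Emotions are read
from sliding windows over these series, judged against *homeostatic*
references -- the per-variable historical mean and standard deviation of
the agent's own experience, which define what "average" feels like.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_VARIABLES = ("reward", "state_value")

#: extras an episode log may carry beyond the two core variables
KNOWN_EXTRAS = ("td_error", "avg_reward", "ema_reward", "cum_reward")


@dataclass
class StepRecord:
    """One environment step of observed scalar values."""

    t: int
    reward: float
    state_value: float
    extras: dict[str, float] = field(default_factory=dict)

    def value(self, name: str) -> float:
        if name == "reward":
            return self.reward
        if name == "state_value":
            return self.state_value
        if name in self.extras:
            return self.extras[name]
        raise KeyError(f"variable {name!r} not recorded at step {self.t}")


@dataclass
class Episode:
    """An ordered run of steps with contiguous indices starting at 0."""

    episode_id: str
    steps: list[StepRecord]
    terminal_flag: bool = True

    def __post_init__(self) -> None:
        if len(self.steps) < 1:
            raise ValueError(f"episode {self.episode_id!r} has no steps")
        ts = [s.t for s in self.steps]
        if ts != list(range(len(ts))):
            raise ValueError(
                f"episode {self.episode_id!r}: step indices must be contiguous from 0"
            )

    def __len__(self) -> int:
        return len(self.steps)

    def values(self, variables: tuple[str, ...] | list[str]) -> np.ndarray:
        """L x V matrix of the requested variables, in declared order."""
        out = np.empty((len(self.steps), len(variables)), dtype=float)
        for j, name in enumerate(variables):
            for i, s in enumerate(self.steps):
                out[i, j] = s.value(name)
        if not np.all(np.isfinite(out)):
            raise ValueError(f"episode {self.episode_id!r} contains non-finite values")
        return out


@dataclass
class SequenceWindow:
    """A W-step x V-variable slice of an episode (the encoder input).

    ``source`` is ``(episode_id, end_step)``: the window covers steps
    ``end_step - W + 1 .. end_step``.
    """

    values: np.ndarray
    source: tuple[str, int]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("window values must be a W x V matrix with W>0, V>=1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"window {self.source} contains non-finite values")
        if self.source[1] < self.values.shape[0] - 1:
            raise ValueError("end_step must be >= W - 1")

    @property
    def W(self) -> int:
        return self.values.shape[0]

    @property
    def V(self) -> int:
        return self.values.shape[1]


@dataclass
class HomeostatNorms:
    """Per-variable mean/sd of the training experience (the homeostatic reference).

    Population standard deviation (divide by N); fitted only on the train
    partition so "average" reflects past experience, never held-out data.
    """

    variables: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.variables = tuple(self.variables)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (len(self.variables) == self.mean.size == self.sd.size):
            raise ValueError("variables, mean, and sd must have matching lengths")
        if np.any(self.sd <= 0):
            bad = [v for v, s in zip(self.variables, self.sd) if s <= 0]
            raise ValueError(f"non-positive sd for variable(s): {bad}")

    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "n_samples": int(self.n_samples),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HomeostatNorms":
        return cls(tuple(d["variables"]), np.array(d["mean"]), np.array(d["sd"]),
                   int(d["n_samples"]))


@dataclass
class SequenceDataset:
    """A corpus of equal-shape windows with train/test partition labels."""

    windows: list[SequenceWindow]
    partition: list[str]
    W: int
    variables: tuple[str, ...]
    norms: HomeostatNorms | None = None
    labels: list[str] | None = None  # optional hidden ground-truth labels

    def __post_init__(self) -> None:
        self.variables = tuple(self.variables)
        if len(self.partition) != len(self.windows):
            raise ValueError("partition labels must match the number of windows")
        for w in self.windows:
            if w.W != self.W or w.V != len(self.variables):
                raise ValueError(
                    f"window {w.source} shape {w.values.shape} does not match "
                    f"dataset shape ({self.W}, {len(self.variables)})"
                )

    def __len__(self) -> int:
        return len(self.windows)

    def subset(self, part: str) -> list[SequenceWindow]:
        return [w for w, p in zip(self.windows, self.partition) if p == part]

    def matrix(self, part: str | None = None) -> np.ndarray:
        """Stack windows into an (n, W, V) array, optionally one partition."""
        ws = self.windows if part is None else self.subset(part)
        if not ws:
            return np.empty((0, self.W, len(self.variables)))
        return np.stack([w.values for w in ws])

    @property
    def episode_ids(self) -> list[str]:
        return [w.source[0] for w in self.windows]


# ---------------------------------------------------------------------------
# windowing and normalization
# ---------------------------------------------------------------------------

def windowize(episode: Episode, W: int,
              variables: tuple[str, ...] | list[str] = DEFAULT_VARIABLES,
              ) -> list[SequenceWindow]:
    """Slice an episode into all L-W+1 stride-1 windows of length ``W``.

    Windows end at steps W-1 .. L-1 (one window per step once enough
    history exists).  Values are raw, unnormalized units.  An episode
    shorter than W yields an empty list with a warning.
    """
    if W <= 0:
        raise ValueError("W must be positive")
    L = len(episode)
    if L < W:
        warnings.warn(
            f"episode {episode.episode_id!r} has {L} steps < window {W}; no windows",
            stacklevel=2,
        )
        return []
    vals = episode.values(tuple(variables))
    view = np.lib.stride_tricks.sliding_window_view(vals, W, axis=0)  # (L-W+1, V, W)
    return [
        SequenceWindow(view[i].T.copy(), (episode.episode_id, W - 1 + i))
        for i in range(L - W + 1)
    ]


def fit_norms(dataset: SequenceDataset) -> HomeostatNorms:
    """Fit homeostatic references on the train partition only.

    Mean and population sd are pooled over every train-window entry of
    each variable.
    """
    X = dataset.matrix("train")
    if X.shape[0] == 0:
        raise ValueError("train partition is empty; cannot fit norms")
    flat = X.reshape(-1, X.shape[2])
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0)  # population convention
    for name, s in zip(dataset.variables, sd):
        if s == 0:
            raise ValueError(f"variable {name!r} is constant on the train partition "
                             "(zero variance); cannot z-score")
    return HomeostatNorms(dataset.variables, mean, sd, n_samples=flat.shape[0])


def normalize(window: SequenceWindow, norms: HomeostatNorms,
              variables: tuple[str, ...] | None = None) -> SequenceWindow:
    """z-score a raw window against the homeostatic references."""
    if window.normalized:
        raise ValueError("window is already normalized")
    if variables is not None and tuple(variables) != norms.variables:
        raise ValueError(
            f"variable mismatch: window has {tuple(variables)}, norms have {norms.variables}"
        )
    if window.V != len(norms.variables):
        raise ValueError(
            f"window has {window.V} variables but norms define {len(norms.variables)}"
        )
    z = (window.values - norms.mean) / norms.sd
    return SequenceWindow(z, window.source, normalized=True)


def denormalize(window: SequenceWindow, norms: HomeostatNorms) -> SequenceWindow:
    """Invert :func:`normalize`, restoring raw units."""
    if not window.normalized:
        raise ValueError("window is not normalized")
    raw = window.values * norms.sd + norms.mean
    return SequenceWindow(raw, window.source, normalized=False)


def normalize_dataset(dataset: SequenceDataset) -> SequenceDataset:
    """Return a dataset with every window z-scored against fitted norms."""
    norms = dataset.norms if dataset.norms is not None else fit_norms(dataset)
    windows = [normalize(w, norms) if not w.normalized else w for w in dataset.windows]
    return SequenceDataset(windows, list(dataset.partition), dataset.W,
                           dataset.variables, norms=norms, labels=dataset.labels)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_dataset(dataset: SequenceDataset, test_fraction: float, seed: int,
                  unit: str = "episode") -> SequenceDataset:
    """Assign train/test partition labels, deterministically per seed.

    ``unit='episode'`` (default) keeps all windows of an episode together,
    preventing leakage between overlapping windows; ``unit='window'``
    splits individual windows.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    if unit not in ("episode", "window"):
        raise ValueError(f"unknown split unit {unit!r}")
    rng = np.random.default_rng(seed)
    if unit == "episode":
        units = sorted(set(dataset.episode_ids))
    else:
        units = list(range(len(dataset)))
    if len(units) < 2:
        raise ValueError(f"need at least 2 {unit}s to split, got {len(units)}")
    n_test = int(round(test_fraction * len(units)))
    n_test = min(max(n_test, 1), len(units) - 1)
    perm = rng.permutation(len(units))
    test_units = {units[i] for i in perm[:n_test]}
    if unit == "episode":
        partition = ["test" if eid in test_units else "train"
                     for eid in dataset.episode_ids]
    else:
        partition = ["test" if i in test_units else "train"
                     for i in range(len(dataset))]
    return SequenceDataset(dataset.windows, partition, dataset.W,
                           dataset.variables, norms=dataset.norms,
                           labels=dataset.labels)


# ---------------------------------------------------------------------------
# episode log I/O (CSV and JSON-lines)
# ---------------------------------------------------------------------------

def _episodes_from_frame(df: pd.DataFrame, origin: str) -> list[Episode]:
    required = {"episode_id", "t", "reward", "state_value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{origin}: missing required column(s) {sorted(missing)}")
    extra_cols = [c for c in df.columns if c not in required]
    for col in ("t", "reward", "state_value"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(f"{origin}: malformed or missing {col!r} in row {bad[0] + 2}")
    episodes = []
    for eid, grp in df.groupby("episode_id", sort=False):
        ts = grp["t"].to_numpy(dtype=int)
        if np.any(np.diff(ts) <= 0):
            raise ValueError(f"{origin}: non-monotonic step index in episode {eid!r}")
        steps = []
        for _, row in grp.iterrows():
            extras = {c: float(row[c]) for c in extra_cols if pd.notna(row[c])}
            steps.append(StepRecord(int(row["t"]), float(row["reward"]),
                                    float(row["state_value"]), extras))
        episodes.append(Episode(str(eid), steps))
    return episodes


def read_episode_log(path: str | Path) -> list[Episode]:
    """Read episodes from a CSV or JSON-lines log.

    CSV header: ``episode_id,t,reward,state_value[,extras...]``; JSON-lines
    holds one step object per line with the same keys.
    """
    path = Path(path)
    if path.suffix.lower() in (".jsonl", ".ndjson", ".json"):
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    rows.append(json.loads(line))
                except json.JSONDecodeError as exc:
                    raise ValueError(f"{path}: malformed JSON on line {lineno}: {exc}") from exc
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path, float_precision="round_trip")
    return _episodes_from_frame(df, str(path))


def write_episode_log(episodes: list[Episode], path: str | Path) -> None:
    """Write episodes to CSV or JSON-lines at full float precision."""
    path = Path(path)
    rows = []
    for ep in episodes:
        for s in ep.steps:
            row = {"episode_id": ep.episode_id, "t": s.t,
                   "reward": s.reward, "state_value": s.state_value}
            row.update(s.extras)
            rows.append(row)
    df = pd.DataFrame(rows)
    if path.suffix.lower() in (".jsonl", ".ndjson", ".json"):
        with open(path, "w") as fh:
            for row in rows:
                fh.write(json.dumps(row) + "\n")
    else:
        df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# dataset archive (directory with manifest + per-partition CSVs)
# ---------------------------------------------------------------------------

def write_dataset(dataset: SequenceDataset, path: str | Path) -> None:
    """Persist a dataset as manifest.json + windows.csv."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "W": dataset.W,
        "variables": list(dataset.variables),
        "n_windows": len(dataset),
        "norms": dataset.norms.to_dict() if dataset.norms else None,
        "has_labels": dataset.labels is not None,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    rows = []
    for i, (w, p) in enumerate(zip(dataset.windows, dataset.partition)):
        row: dict = {"episode_id": w.source[0], "end_step": w.source[1],
                     "partition": p, "normalized": int(w.normalized)}
        if dataset.labels is not None:
            row["label"] = dataset.labels[i]
        for j, name in enumerate(dataset.variables):
            for t in range(dataset.W):
                row[f"{name}_{t}"] = w.values[t, j]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path / "windows.csv", index=False, float_format="%.17g")


def read_dataset(path: str | Path) -> SequenceDataset:
    """Load a dataset archive written by :func:`write_dataset`."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    W = manifest["W"]
    variables = tuple(manifest["variables"])
    norms = (HomeostatNorms.from_dict(manifest["norms"])
             if manifest.get("norms") else None)
    df = pd.read_csv(path / "windows.csv", float_precision="round_trip")
    windows, partition, labels = [], [], []
    cols = [[f"{name}_{t}" for name in variables] for t in range(W)]
    for _, row in df.iterrows():
        vals = np.array([[row[c] for c in step_cols] for step_cols in cols])
        windows.append(SequenceWindow(vals, (str(row["episode_id"]), int(row["end_step"])),
                                      normalized=bool(row["normalized"])))
        partition.append(str(row["partition"]))
        if manifest["has_labels"]:
            labels.append(str(row["label"]))
    return SequenceDataset(windows, partition, W, variables, norms=norms,
                           labels=labels if manifest["has_labels"] else None)
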