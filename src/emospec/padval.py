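"""Human-validation statistics for learned emotions on the PAD model.

Learned emotions are validated against human judgement on the
pleasure-arousal-dominance (PAD) dimensions, rated with the
Self-Assessment Manikin on 1-9 scales.  This module provides:

* ICC(2,k) -- intraclass correlation, two-way random effects, absolute
  agreement, average of k raters (Shrout-Fleiss convention) -- the
  survey reliability statistic;
* Hotelling's T-squared two-sample test -- pairwise distinguishability of
  the PAD clouds attributed to different emotions;
* three mapping methods against literature PAD norms (which report only
  means and sds, never covariances): Method 1 treats the reference as an
  independent-dimensions sample (diagonal covariance), Method 2 lends it
  the sample's own covariance, Method 3 compares means by Euclidean
  distance;
* top-k matching per reference source and the cross-source "semantic
  collage" of best-matching terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

PAD_DIMENSIONS = ("pleasure", "arousal", "dominance")


@dataclass
class PADRating:
    pleasure: float
    arousal: float
    dominance: float
    rater_id: str
    video_id: str
    scale: tuple[float, float] = (1.0, 9.0)
    hidden_emotion: str | None = None

    def __post_init__(self) -> None:
        lo, hi = self.scale
        for name in PAD_DIMENSIONS:
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(
                    f"{name}={v} outside declared scale [{lo}, {hi}] "
                    f"(rater {self.rater_id}, video {self.video_id})"
                )

    @property
    def triple(self) -> np.ndarray:
        return np.array([self.pleasure, self.arousal, self.dominance])


@dataclass
class SurveyDataset:
    """Rater x video PAD ratings with optional hidden emotion labels."""

    ratings: pd.DataFrame          # columns: rater_id, video_id, pleasure, arousal, dominance
    video_emotions: dict[str, str] = field(default_factory=dict)
    scale: tuple[float, float] = (1.0, 9.0)

    def __post_init__(self) -> None:
        required = {"rater_id", "video_id", *PAD_DIMENSIONS}
        missing = required - set(self.ratings.columns)
        if missing:
            raise ValueError(f"survey table missing column(s) {sorted(missing)}")
        dup = self.ratings.duplicated(["rater_id", "video_id"])
        if dup.any():
            pair = self.ratings.loc[dup.idxmax(), ["rater_id", "video_id"]].tolist()
            raise ValueError(f"duplicate (rater, video) cell: {pair}")
        if self.scale is not None:
            lo, hi = self.scale
            vals = self.ratings[list(PAD_DIMENSIONS)].to_numpy()
            if vals.min() < lo or vals.max() > hi:
                raise ValueError(f"ratings outside declared scale [{lo}, {hi}]")

    def matrix(self, dimension: str) -> pd.DataFrame:
        """Complete videos x raters table of one dimension (NaN if missing)."""
        return self.ratings.pivot(index="video_id", columns="rater_id",
                                  values=dimension)

    def emotion_sample(self, emotion: str, dimension_scale=None) -> np.ndarray:
        """All (n, 3) PAD triples rated on videos of one hidden emotion."""
        vids = {v for v, e in self.video_emotions.items() if e == emotion}
        if not vids:
            raise KeyError(f"no videos tagged with emotion {emotion!r}")
        sub = self.ratings[self.ratings["video_id"].isin(vids)]
        X = sub[list(PAD_DIMENSIONS)].to_numpy(dtype=float)
        if dimension_scale is not None:
            X = convert_scale(X, self.scale, dimension_scale)
        return X


@dataclass
class PADReference:
    """One literature PAD norm table (term, per-dimension mean and sd, n)."""

    source: str
    table: pd.DataFrame   # term, P_mean, P_sd, A_mean, A_sd, D_mean, D_sd, n
    scale: tuple[float, float] = (-1.0, 1.0)

    REQUIRED = ("term", "P_mean", "P_sd", "A_mean", "A_sd", "D_mean", "D_sd", "n")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise ValueError(f"reference {self.source}: missing column(s) {sorted(missing)}")
        sds = self.table[["P_sd", "A_sd", "D_sd"]].to_numpy()
        if (sds <= 0).any():
            raise ValueError(f"reference {self.source}: non-positive sd")
        if (self.table["n"] < 2).any():
            raise ValueError(f"reference {self.source}: n must be >= 2")

    def filtered(self, exclude: set[str] | list[str]) -> "PADReference":
        ex = {t.strip().lower() for t in exclude}
        keep = self.table[~self.table["term"].str.strip().str.lower().isin(ex)]
        if keep.empty:
            raise ValueError(f"reference {self.source}: empty after exclusion filter")
        return PADReference(self.source, keep.reset_index(drop=True), self.scale)

    @classmethod
    def from_csv(cls, path, source: str | None = None) -> "PADReference":
        df = pd.read_csv(path)
        src = source or (str(df["source"].iloc[0]) if "source" in df.columns
                         else str(path))
        return cls(src, df)


# ---------------------------------------------------------------------------
# scale conversion
# ---------------------------------------------------------------------------

def convert_scale(value, from_scale=(1.0, 9.0), to_scale=(-1.0, 1.0)):
    """Affine bijection between rating scales; endpoints map to endpoints.

    The survey-to-literature default is x -> (x - 5) / 4.
    """
    value = np.asarray(value, dtype=float)
    f_lo, f_hi = from_scale
    t_lo, t_hi = to_scale
    if np.any(value < f_lo) or np.any(value > f_hi):
        raise ValueError(f"value outside source scale [{f_lo}, {f_hi}]")
    out = t_lo + (value - f_lo) * (t_hi - t_lo) / (f_hi - f_lo)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# ICC(2,k)
# ---------------------------------------------------------------------------

def icc2k(matrix) -> float:
    """ICC(2,k): two-way random effects, absolute agreement, average of k raters.

    ``matrix`` is targets x raters for a single dimension, complete (no
    missing cells).  From the two-way ANOVA decomposition with n targets
    and k raters: ICC(2,k) = (MSR - MSE) / (MSR + (MSC - MSE) / n).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("matrix must be 2-dimensional (targets x raters)")
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 targets and 2 raters")
    if np.isnan(X).any():
        i, j = np.argwhere(np.isnan(X))[0]
        raise ValueError(f"missing cell at target {i}, rater {j}; no imputation")
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total == 0:
        raise ValueError("zero total variance: all ratings identical, ICC undefined")
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (msc - mse) / n))


def survey_reliability(survey: SurveyDataset) -> dict[str, float]:
    """ICC(2,k) per PAD dimension over the complete rater x video design.

    Incomplete designs (e.g. split video lists) are analyzed per complete
    sub-matrix: raters that saw every video in a block form one block.
    """
    out = {}
    for dim in PAD_DIMENSIONS:
        M = survey.matrix(dim)
        if M.isna().any().any():
            # analyze the largest complete sub-blocks (per rater coverage set)
            coverage = {}
            for rater in M.columns:
                seen = frozenset(M.index[M[rater].notna()])
                coverage.setdefault(seen, []).append(rater)
            iccs, weights = [], []
            for vids, raters in coverage.items():
                if len(vids) >= 2 and len(raters) >= 2:
                    sub = M.loc[sorted(vids), raters]
                    iccs.append(icc2k(sub.to_numpy()))
                    weights.append(len(vids) * len(raters))
            if not iccs:
                raise ValueError(f"no complete sub-matrix for dimension {dim}")
            out[dim] = float(np.average(iccs, weights=weights))
        else:
            out[dim] = icc2k(M.to_numpy())
    return out


# ---------------------------------------------------------------------------
# Hotelling's T-squared
# ---------------------------------------------------------------------------

@dataclass
class HotellingResult:
    t2: float
    f: float
    df1: int
    df2: int
    p: float


def _hotelling_from_stats(mean1, mean2, S_pooled, n1, n2) -> HotellingResult:
    p = len(mean1)
    df2 = n1 + n2 - p - 1
    if df2 < 1:
        raise ValueError(f"too few samples (n1+n2={n1+n2}) for dimension p={p}")
    diff = np.asarray(mean1) - np.asarray(mean2)
    try:
        sol = np.linalg.solve(S_pooled, diff)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular pooled covariance matrix") from exc
    t2 = float(n1 * n2 / (n1 + n2) * diff @ sol)
    f = t2 * df2 / ((n1 + n2 - 2) * p)
    pval = float(stats.f.sf(f, p, df2))
    return HotellingResult(t2, float(f), p, df2, pval)


def hotelling_two_sample(X: np.ndarray, Y: np.ndarray) -> HotellingResult:
    """Two-sample Hotelling T-squared with the exact F reference distribution.

    T2 = (n1 n2 / (n1+n2)) (x̄-ȳ)' S_pooled^{-1} (x̄-ȳ), with
    F = T2 (n1+n2-p-1) / ((n1+n2-2) p) on (p, n1+n2-p-1) degrees of
    freedom.  Reduces to the squared pooled two-sample t at p = 1.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError("samples must share the dimension p")
    n1, n2 = X.shape[0], Y.shape[0]
    S1 = np.cov(X, rowvar=False, ddof=1) if n1 > 1 else np.zeros((X.shape[1],) * 2)
    S2 = np.cov(Y, rowvar=False, ddof=1) if n2 > 1 else np.zeros((Y.shape[1],) * 2)
    S1, S2 = np.atleast_2d(S1), np.atleast_2d(S2)
    S_pooled = ((n1 - 1) * S1 + (n2 - 1) * S2) / (n1 + n2 - 2)
    return _hotelling_from_stats(X.mean(axis=0), Y.mean(axis=0), S_pooled, n1, n2)


def pairwise_distinguishability(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """Hotelling tests for every unordered pair of emotion PAD samples."""
    names = sorted(samples)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            r = hotelling_two_sample(samples[a], samples[b])
            rows.append({"emotion_a": a, "emotion_b": b, "t2": r.t2,
                         "F": r.f, "df1": r.df1, "df2": r.df2, "p": r.p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mapping methods against literature references
# ---------------------------------------------------------------------------

def _ref_row(ref_mean, ref_sd):
    mean = np.asarray(ref_mean, dtype=float)
    sd = np.asarray(ref_sd, dtype=float)
    if mean.shape != (3,) or sd.shape != (3,):
        raise ValueError("reference mean and sd must be PAD triples")
    return mean, sd


def map_method1(sample: np.ndarray, ref_mean, ref_sd, ref_n: int) -> HotellingResult:
    """Hotelling test treating the reference dimensions as independent.

    The unavailable reference covariance is replaced by diag(sd^2); the
    pooled covariance weighs the two by (n1-1, n2-1).
    """
    X = np.asarray(sample, dtype=float)
    mean, sd = _ref_row(ref_mean, ref_sd)
    if ref_n is None or ref_n < 2:
        raise ValueError("Method 1 requires the reference sample size n >= 2")
    n1, n2 = X.shape[0], int(ref_n)
    S1 = np.cov(X, rowvar=False, ddof=1)
    S_pooled = ((n1 - 1) * S1 + (n2 - 1) * np.diag(sd ** 2)) / (n1 + n2 - 2)
    return _hotelling_from_stats(X.mean(axis=0), mean, S_pooled, n1, n2)


def map_method2(sample: np.ndarray, ref_mean, ref_sd, ref_n: int) -> HotellingResult:
    """Hotelling test lending the sample's covariance to the reference."""
    X = np.asarray(sample, dtype=float)
    mean, _ = _ref_row(ref_mean, ref_sd)
    if ref_n is None or ref_n < 2:
        raise ValueError("Method 2 requires the reference sample size n >= 2")
    n1, n2 = X.shape[0], int(ref_n)
    S1 = np.cov(X, rowvar=False, ddof=1)
    # both samples share S1, so the pooled estimate is S1 itself
    return _hotelling_from_stats(X.mean(axis=0), mean, S1, n1, n2)


def map_method3(sample_mean, ref_mean) -> float:
    """Euclidean distance between mean PAD triples."""
    a = np.asarray(sample_mean, dtype=float)
    b = np.asarray(ref_mean, dtype=float)
    if a.shape != b.shape:
        raise ValueError("mean triples must have the same shape")
    return float(np.linalg.norm(a - b))


# ---------------------------------------------------------------------------
# top matches and the semantic collage
# ---------------------------------------------------------------------------

@dataclass
class Match:
    term: str
    source: str
    score: float       # distance (method 3) or p-value (methods 1/2)
    method: int

    @property
    def sort_key(self):
        # smaller is better for distances; larger p is better for tests
        return self.score if self.method == 3 else -self.score


def top_matches(sample: np.ndarray, reference: PADReference, k: int = 3,
                method: int = 3, exclude=()) -> list[Match]:
    """Rank reference terms against one emotion's PAD sample.

    Method 3 ranks by ascending Euclidean distance of means; methods 1/2
    by descending Hotelling p-value.  ``exclude`` filters out-of-scope
    terms (social/moral/self-conscious affects, non-emotions) before
    ranking.
    """
    if method not in (1, 2, 3):
        raise ValueError("method must be 1, 2 or 3")
    ref = reference.filtered(exclude) if exclude else reference
    X = np.asarray(sample, dtype=float)
    sample_mean = X.mean(axis=0)
    matches = []
    for _, row in ref.table.iterrows():
        mean = row[["P_mean", "A_mean", "D_mean"]].to_numpy(dtype=float)
        sd = row[["P_sd", "A_sd", "D_sd"]].to_numpy(dtype=float)
        if method == 3:
            score = map_method3(sample_mean, mean)
        elif method == 1:
            score = map_method1(X, mean, sd, int(row["n"])).p
        else:
            score = map_method2(X, mean, sd, int(row["n"])).p
        matches.append(Match(str(row["term"]), ref.source, score, method))
    matches.sort(key=lambda m: (m.sort_key, m.term, m.source))
    if k > len(matches):
        warnings.warn(
            f"k={k} exceeds the {len(matches)} terms in {ref.source}; "
            "returning the full ranking", stacklevel=2)
        k = len(matches)
    return matches[:k]


def semantic_collage(per_source_matches: list[list[Match]], k: int = 5) -> list[Match]:
    """Merge per-source top lists and keep the k best overall.

    Output order is independent of the order sources are supplied in
    (ties broken by term then source name).
    """
    pool = [m for lst in per_source_matches for m in lst]
    if not pool:
        raise ValueError("no matches supplied")
    methods = {m.method for m in pool}
    if len(methods) > 1:
        raise ValueError("collage requires matches from a single method")
    pool.sort(key=lambda m: (m.sort_key, m.term, m.source))
    return pool[:min(k, len(pool))]
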