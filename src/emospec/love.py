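"""LOVE interpretability mappings: idealized temporal patterns with emotion terms.

A LOVE ("Latest Observed Values Encoding") mapping is a grid of reference
profiles: one idealized W-step template per combination of per-variable
temporal patterns, expressed in sigma units relative to the homeostatic
reference.  Patterns are either *levels* (positive / average / negative,
constants around 0 or +-1 sigma) or *trends* (linear ramps: increased,
decreased, and for the expectation variable the finer decreased-to-average
vs decreased-to-negative that separates anger from fear).  Each profile
may carry an emotion term; learned cluster prototypes are matched to the
nearest profile to name the learned emotions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory import HomeostatNorms

REWARD_PATTERNS = ("positive", "average", "negative", "increased", "decreased")
EXPECTATION_PATTERNS_5 = REWARD_PATTERNS
EXPECTATION_PATTERNS_6 = ("positive", "average", "negative", "increased",
                          "decreased_to_average", "decreased_to_negative")

LEVEL_LABELS = ("positive", "average", "negative")

#: emotion terms printed in the source framework's Order III tables
BASE_LEXICON: dict[tuple[str, str], str] = {
    ("positive", "positive"): "happiness",
    ("negative", "negative"): "distress",
    ("average", "negative"): "concern",
    ("average", "positive"): "optimism",
    ("average", "increased"): "excitement",
    ("decreased", "average"): "frustration",
    ("average", "decreased_to_average"): "anger",
    ("average", "decreased_to_negative"): "fear",
    ("average", "average"): "neutral",
    ("increased", "decreased_to_average"): "satisfaction",
}

#: intensity- or lean-qualified variants of grid terms
VARIANT_LEXICON: dict[tuple[tuple[str, str], str], str] = {
    (("average", "positive"), "high"): "high optimism",
    (("average", "average"), "low_expectation"): "neutral/slight concern",
}


@dataclass(frozen=True)
class BandConfig:
    """Thresholds (sigma units) deciding level vs trend pattern labels.

    ``tau`` separates average from positive/negative levels; ``high``
    marks high-intensity levels (well beyond +-sigma); ``delta`` is the
    minimum half-window mean shift that counts as a trend.
    """

    tau: float = 0.5
    high: float = 1.5
    delta: float = 0.5
    trend_estimator: str = "half_means"   # or "slope"

    def __post_init__(self) -> None:
        if not 0 < self.tau < self.high:
            raise ValueError("require 0 < tau < high threshold")
        if self.delta <= 0:
            raise ValueError("trend threshold delta must be positive")
        if self.trend_estimator not in ("half_means", "slope"):
            raise ValueError(f"unknown trend estimator {self.trend_estimator!r}")


@dataclass(frozen=True)
class PatternLabel:
    role: str          # "reward" | "expectation"
    label: str
    intensity: str = "normal"   # "normal" | "high" (level labels only)

    def __post_init__(self) -> None:
        # the coarse 5-pattern expectation grid reuses the plain 'decreased'
        legal = (REWARD_PATTERNS if self.role == "reward"
                 else EXPECTATION_PATTERNS_6 + ("decreased",))
        if self.label not in legal:
            raise ValueError(f"illegal {self.role} pattern {self.label!r}")
        if self.intensity == "high" and self.label not in ("positive", "negative"):
            raise ValueError("intensity 'high' applies only to positive/negative levels")


@dataclass
class ReferenceProfile:
    """One cell of a LOVE mapping: templates + labels + optional term."""

    profile_id: str
    labels: tuple[str, ...]
    template: np.ndarray          # W x V, sigma units
    term: str | None = None

    @property
    def is_stable(self) -> bool:
        """Level-only profiles are stable states in coherence scripts."""
        return all(lab in LEVEL_LABELS for lab in self.labels)


def _template_curve(label: str, W: int) -> np.ndarray:
    """Idealized W-step curve (sigma units) for one pattern label."""
    ramp = np.linspace(0.0, 1.0, W)
    if label == "positive":
        return np.ones(W)
    if label == "average":
        return np.zeros(W)
    if label == "negative":
        return -np.ones(W)
    if label == "increased":
        return ramp
    if label in ("decreased", "decreased_to_average"):
        return 1.0 - ramp
    if label == "decreased_to_negative":
        return -ramp
    raise ValueError(f"unknown pattern label {label!r}")


@dataclass
class LOVEMapping:
    """Full profile grid for a pattern-count spec such as ``"2:5x6"``."""

    spec: str
    roles: tuple[str, ...]
    W: int
    band: BandConfig
    profiles: list[ReferenceProfile] = field(default_factory=list)

    @property
    def lexicon(self) -> dict[tuple[str, ...], str]:
        return {p.labels: p.term for p in self.profiles if p.term is not None}

    def all_terms(self) -> set[str]:
        terms = {p.term for p in self.profiles if p.term is not None}
        terms.update(VARIANT_LEXICON.values())
        return terms

    def profile_for(self, labels: tuple[str, ...]) -> ReferenceProfile:
        for p in self.profiles:
            if p.labels == tuple(labels):
                return p
        raise KeyError(f"no profile with labels {labels}")

    def profile_by_term(self, term: str) -> ReferenceProfile:
        term_l = term.strip().lower()
        for p in self.profiles:
            if p.term is not None and p.term.lower() == term_l:
                return p
        # variant terms resolve to their base grid cell
        for (labels, _q), t in VARIANT_LEXICON.items():
            if t.lower() == term_l:
                return self.profile_for(labels)
        raise KeyError(f"no profile named {term!r}")

    def assign_term(self, labels: tuple[str, ...], term: str) -> None:
        """Name one of the (intentionally) unnamed combinations."""
        self.profile_for(labels).term = term

    def term_for(self, labels: tuple[str, ...],
                 means: np.ndarray | None = None) -> str | None:
        """Emotion term for a label tuple, applying variant qualifiers.

        ``means`` (per-variable overall means, sigma units) enables the
        intensity variants: (average, positive) with expectation mean
        beyond the high threshold reads as "high optimism"; (average,
        average) with the expectation leaning below -tau/2 reads as
        "neutral/slight concern".
        """
        labels = tuple(labels)
        if means is not None and len(self.roles) == 2:
            m_exp = float(means[1])
            if labels == ("average", "positive") and m_exp >= self.band.high:
                return VARIANT_LEXICON[(labels, "high")]
            if labels == ("average", "average") and m_exp <= -self.band.tau / 2:
                return VARIANT_LEXICON[(labels, "low_expectation")]
        try:
            return self.profile_for(labels).term
        except KeyError:
            return None


def build_mapping(spec: str, W: int = 20,
                  band: BandConfig | None = None) -> LOVEMapping:
    """Build the full profile grid for a spec like ``"2:5x6"`` or ``"2:5x5"``.

    The two supported variable roles are reward (5 patterns) and
    expectation/state-value (5 or 6 patterns).  Profile count is the
    product of per-variable pattern counts (30 for 2:5x6).
    """
    band = band or BandConfig()
    supported = {"2:5x5": (REWARD_PATTERNS, EXPECTATION_PATTERNS_5),
                 "2:5x6": (REWARD_PATTERNS, EXPECTATION_PATTERNS_6)}
    if spec not in supported:
        raise ValueError(
            f"unsupported mapping spec {spec!r}; supported: {sorted(supported)}"
        )
    reward_pats, exp_pats = supported[spec]
    mapping = LOVEMapping(spec=spec, roles=("reward", "expectation"), W=W, band=band)
    for rp in reward_pats:
        for ep in exp_pats:
            labels = (rp, ep)
            template = np.column_stack([_template_curve(rp, W),
                                        _template_curve(ep, W)])
            term = BASE_LEXICON.get(labels)
            if spec == "2:5x5" and labels == ("average", "decreased"):
                # in the coarse grid a single 'decreased' covers both finer falls
                term = None
            mapping.profiles.append(
                ReferenceProfile(f"{rp}|{ep}", labels, template, term)
            )
    return mapping


# ---------------------------------------------------------------------------
# pattern classification
# ---------------------------------------------------------------------------

def _classify_one(x: np.ndarray, role: str, n_patterns: int,
                  band: BandConfig) -> PatternLabel:
    W = x.shape[0]
    half = W // 2
    m_e = float(x[:half].mean())
    m_l = float(x[half:].mean())
    m = float(x.mean())
    if band.trend_estimator == "half_means":
        # estimated net change over the window: for a linear ramp the
        # half-mean difference is half the total rise
        change = 2.0 * (m_l - m_e)
    else:
        t = np.arange(W)
        slope = float(np.polyfit(t, x, 1)[0])
        change = slope * (W - 1)
    if abs(change) >= band.delta:
        if m_l > m_e:
            return PatternLabel(role, "increased")
        if role == "expectation" and n_patterns == 6:
            if m_l <= -band.tau:
                return PatternLabel(role, "decreased_to_negative")
            if abs(m_l) < band.tau:
                return PatternLabel(role, "decreased_to_average")
            return PatternLabel(role, "decreased_to_average")
        return PatternLabel(role, "decreased")
    if m >= band.tau:
        return PatternLabel(role, "positive",
                            "high" if m >= band.high else "normal")
    if m <= -band.tau:
        return PatternLabel(role, "negative",
                            "high" if m <= -band.high else "normal")
    return PatternLabel(role, "average")


def classify_patterns(values: np.ndarray, band: BandConfig | None = None,
                      roles: tuple[str, ...] = ("reward", "expectation"),
                      pattern_counts: tuple[int, ...] = (5, 6),
                      ) -> tuple[PatternLabel, ...]:
    """Label each variable of a normalized W x V window with its pattern.

    The input must be in sigma units (z-scored).  Trend detection uses
    half-window means: a shift of at least ``delta`` between the early and
    late half-window means reads as a trend, otherwise the overall mean is
    banded into a level at ``+-tau`` (intensity ``high`` beyond the high
    threshold).  Falling expectations split by where they land: within
    ``+-tau`` of average vs at or below ``-tau``.
    """
    band = band or BandConfig()
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != len(roles):
        raise ValueError(
            f"expected a W x {len(roles)} matrix, got shape {values.shape}"
        )
    return tuple(_classify_one(values[:, j], roles[j], pattern_counts[j], band)
                 for j in range(values.shape[1]))


def label_tuple(labels: tuple[PatternLabel, ...]) -> tuple[str, ...]:
    return tuple(lab.label for lab in labels)


# ---------------------------------------------------------------------------
# profile matching
# ---------------------------------------------------------------------------

def match_profile(prototype_mean: np.ndarray, mapping: LOVEMapping,
                  norms: HomeostatNorms | None = None,
                  ) -> list[tuple[ReferenceProfile, float]]:
    """Rank all mapping profiles by distance to a prototype sequence.

    ``prototype_mean`` is the cluster's W x V mean sequence; pass ``norms``
    when it is in raw units so it can be brought to sigma units first.
    Distance is the per-variable mean squared deviation from the template,
    summed over variables.  Ties prefer stable (level-only) profiles, then
    lexicographic profile id.
    """
    seq = np.asarray(prototype_mean, dtype=float)
    if norms is not None:
        seq = (seq - norms.mean) / norms.sd
    if seq.shape != (mapping.W, len(mapping.roles)):
        raise ValueError(
            f"prototype shape {seq.shape} does not match mapping "
            f"({mapping.W}, {len(mapping.roles)})"
        )
    scored = []
    for p in mapping.profiles:
        d = float(np.mean((seq - p.template) ** 2, axis=0).sum())
        scored.append((p, d))
    scored.sort(key=lambda pd: (pd[1], not pd[0].is_stable, pd[0].profile_id))
    return scored


# ---------------------------------------------------------------------------
# sequence-coherence validation
# ---------------------------------------------------------------------------

@dataclass
class CoherenceReport:
    """Outcome of the sequence-coherence test over a script suite."""

    violations: list[str]
    warnings: list[str]
    unused_profiles: list[str]

    @property
    def passed(self) -> bool:
        return not self.violations


def _level_of(label: str) -> str | None:
    return label if label in LEVEL_LABELS else None


def validate_coherence(mapping: LOVEMapping,
                       scripts: list[list[dict]]) -> CoherenceReport:
    """Check that event-annotated emotion scripts form plausible narratives.

    Each script is a list of ``{"state": <term or profile id>, "event": str}``
    steps.  Checks: (a) start in a stable level-only state; (b) no
    beyond-scope transitions (a rise from an already-positive level, or a
    fall from an already-negative level, on the same variable); (c) abrupt
    positive<->negative level jumps are flagged as warnings; (d) end in a
    stable or previously visited state; (e) across the whole suite every
    profile should appear (unused ones are reported).
    """
    violations: list[str] = []
    warns: list[str] = []
    used: set[str] = set()

    def resolve(name: str) -> ReferenceProfile:
        try:
            return mapping.profile_by_term(name)
        except KeyError:
            pass
        for p in mapping.profiles:
            if p.profile_id == name:
                return p
        raise KeyError(f"unknown profile or term {name!r} in coherence script")

    for si, script in enumerate(scripts):
        states = [resolve(step["state"]) for step in script]
        for p in states:
            used.add(p.profile_id)
        tag = f"script {si}"
        if not states:
            violations.append(f"{tag}: empty script")
            continue
        if not states[0].is_stable:
            violations.append(f"{tag}: starts in unstable state {states[0].profile_id}")
        visited = {states[0].profile_id}
        for prev, curr in zip(states, states[1:]):
            for v, role in enumerate(mapping.roles):
                pl, cl = prev.labels[v], curr.labels[v]
                if cl == "increased" and pl == "positive":
                    violations.append(
                        f"{tag}: beyond-scope {role} transition {pl} -> {cl} "
                        f"({prev.profile_id} -> {curr.profile_id})"
                    )
                if cl.startswith("decreased") and pl == "negative":
                    violations.append(
                        f"{tag}: beyond-scope {role} transition {pl} -> {cl} "
                        f"({prev.profile_id} -> {curr.profile_id})"
                    )
                if {_level_of(pl), _level_of(cl)} == {"positive", "negative"}:
                    warns.append(
                        f"{tag}: abrupt {role} jump {pl} -> {cl} "
                        f"({prev.profile_id} -> {curr.profile_id})"
                    )
            visited.add(curr.profile_id)
        last = states[-1]
        if not (last.is_stable or last.profile_id in
                {p.profile_id for p in states[:-1]}):
            violations.append(f"{tag}: ends in unstable unvisited state {last.profile_id}")

    unused = sorted(p.profile_id for p in mapping.profiles
                    if p.profile_id not in used)
    return CoherenceReport(violations, warns, unused)
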