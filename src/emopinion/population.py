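"""Agent populations: static traits and initial emotional states.

Each agent carries five static traits (extroversion, expression ability,
conformity, receptivity, internalization ability) drawn from clipped normal
distributions, and an initial emotion described in the valence-arousal frame:
a basic-emotion type (joy, anger, sadness, fear), a signed pleasure degree in
(-1, 1), and an arousal level that is a fixed function of the emotion type
(sadness 0.6 < joy = anger 0.8 < fear 1.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AROUSAL_TABLE",
    "JOY",
    "ANGER",
    "SADNESS",
    "FEAR",
    "EMOTION_NAMES",
    "TraitSpec",
    "AgentTraits",
    "EmotionState",
    "EventInfo",
    "Population",
    "arousal_of",
    "sample_traits",
    "init_emotions",
    "build_population",
]

JOY, ANGER, SADNESS, FEAR = 1, 2, 3, 4
EMOTION_NAMES = {JOY: "joy", ANGER: "anger", SADNESS: "sadness", FEAR: "fear"}

#: Arousal level per basic emotion (mapped into (0, 1) by rank:
#: sadness < anger = joy < fear).
AROUSAL_TABLE = {JOY: 0.8, ANGER: 0.8, SADNESS: 0.6, FEAR: 1.0}

# Indexable lookup; slot 0 is unused (emotion types are 1-based).
_AROUSAL_ARRAY = np.array([np.nan, 0.8, 0.8, 0.6, 1.0])

_EPS = 1e-6  # nudge applied to keep strict open-interval invariants


def arousal_of(emo_type):
    """Arousal level(s) for emotion type(s) in {1, 2, 3, 4}.

    Accepts a scalar or an integer array; the lookup is total and
    deterministic over the four basic emotions.
    """
    emo_type = np.asarray(emo_type)
    if np.any((emo_type < 1) | (emo_type > 4)):
        raise ValueError("emotion type must be in {1, 2, 3, 4}")
    out = _AROUSAL_ARRAY[emo_type]
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TraitSpec:
    """Clipped-normal sampling specification: N(mean, sd) clipped to [lower, upper]."""

    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if not self.lower < self.upper:
            raise ValueError("lower must be strictly less than upper")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n < 1:
            raise ValueError("n must be at least 1")
        x = rng.normal(self.mean, self.sd, size=n) if self.sd > 0 else np.full(n, float(self.mean))
        return np.clip(x, self.lower, self.upper)


@dataclass(frozen=True)
class AgentTraits:
    """Static parameters of a single agent."""

    alpha: float  # extroversion, [0, 1]
    delta: float  # expression ability, [0, 2] (>1 exaggerates)
    gamma: float  # conformity, [0, 1]
    lam: float  # receptivity, [0, 1]
    zeta: float  # internalization ability, [0, 1]


@dataclass(frozen=True)
class EmotionState:
    """Internal state of a single agent: (type, pleasure, arousal)."""

    emo_type: int
    pleasure: float
    arousal: float


@dataclass(frozen=True)
class EventInfo:
    """Characteristics of the triggering event.

    beta1 is the life relevance of the event (raises willingness to speak),
    beta2 its political sensitivity (restrains expression; enters willingness
    as a divisor and must be positive).
    """

    beta1: float = 0.9
    beta2: float = 0.5

    def __post_init__(self) -> None:
        if self.beta2 <= 0:
            raise ValueError("beta2 must be positive (it appears as a divisor)")


DEFAULT_TRAIT_SPECS: dict[str, TraitSpec] = {
    "alpha": TraitSpec(0.5, 0.15, 0.0, 1.0),
    "delta": TraitSpec(1.0, 0.2, 0.0, 2.0),
    "gamma": TraitSpec(0.5, 0.15, 0.0, 1.0),
    "lam": TraitSpec(0.5, 0.15, 0.0, 1.0),
    "zeta": TraitSpec(0.9, 0.05, 0.0, 1.0),
}

POSITIVE_PLEASURE_SPEC = TraitSpec(0.5, 0.15, 0.0, 1.0)
NEGATIVE_PLEASURE_SPEC = TraitSpec(-0.5, 0.15, -1.0, 0.0)


@dataclass
class Population:
    """Struct-of-arrays container for all agents in a simulation."""

    alpha: np.ndarray
    delta: np.ndarray
    gamma: np.ndarray
    lam: np.ndarray
    zeta: np.ndarray
    emo_type: np.ndarray
    pleasure: np.ndarray
    arousal: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.arousal is None:
            self.arousal = arousal_of(self.emo_type)

    @property
    def n(self) -> int:
        return len(self.alpha)

    def traits_of(self, i: int) -> AgentTraits:
        return AgentTraits(
            float(self.alpha[i]),
            float(self.delta[i]),
            float(self.gamma[i]),
            float(self.lam[i]),
            float(self.zeta[i]),
        )

    def emotion_of(self, i: int) -> EmotionState:
        return EmotionState(int(self.emo_type[i]), float(self.pleasure[i]), float(self.arousal[i]))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "agent_id": np.arange(self.n),
                "alpha": self.alpha,
                "delta": self.delta,
                "gamma": self.gamma,
                "lambda": self.lam,
                "zeta": self.zeta,
                "emo_type": self.emo_type,
                "pleasure": self.pleasure,
                "arousal": self.arousal,
            }
        )


def sample_traits(
    n: int,
    specs: dict[str, TraitSpec] | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Draw ``n`` trait vectors from clipped normal distributions.

    ``specs`` maps trait names (alpha, delta, gamma, lam, zeta) to
    :class:`TraitSpec`; omitted traits use the defaults (all N(0.5, 0.15) on
    [0, 1] except expression ability N(1, 0.2) on [0, 2] and internalization
    N(0.9, 0.05) on [0, 1]). Sampling order is fixed (alpha, delta, gamma,
    lam, zeta) so a seeded generator reproduces byte-identical draws.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng() if rng is None else rng
    merged = dict(DEFAULT_TRAIT_SPECS)
    if specs:
        unknown = set(specs) - set(merged)
        if unknown:
            raise ValueError(f"unknown trait names: {sorted(unknown)}")
        merged.update(specs)
    return {name: merged[name].sample(n, rng) for name in DEFAULT_TRAIT_SPECS}


def _largest_remainder_counts(n: int, proportions: np.ndarray) -> np.ndarray:
    """Integer allocation of n items to proportions, largest remainder first."""
    quotas = n * proportions
    counts = np.floor(quotas).astype(int)
    shortfall = n - counts.sum()
    if shortfall > 0:
        remainders = quotas - counts
        # ties broken toward the lower type index via stable sort
        order = np.argsort(-remainders, kind="stable")
        counts[order[:shortfall]] += 1
    return counts


def init_emotions(
    n: int,
    type_proportions=(0.25, 0.25, 0.25, 0.25),
    pleasure_specs: tuple[TraitSpec, TraitSpec] = (POSITIVE_PLEASURE_SPEC, NEGATIVE_PLEASURE_SPEC),
    rng: np.random.Generator | None = None,
    multinomial: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Initial emotions for ``n`` agents: (emo_type, pleasure, arousal) arrays.

    Emotion types are allocated to the four basic emotions deterministically
    (largest-remainder rounding of ``n * p``), so fixed scenario proportions
    such as 70/10/10/10 are exact; pass ``multinomial=True`` for a random
    multinomial allocation instead. Joy agents draw pleasure from the
    positive-branch spec (default N(0.5, 0.15) on (0, 1)); anger, sadness and
    fear draw from the negative branch (default N(-0.5, 0.15) on (-1, 0)).
    A draw clipped onto 0 is re-drawn once and, if still 0, nudged to +-1e-6:
    an exactly neutral agent would be permanently silent.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    props = np.asarray(type_proportions, dtype=float)
    if props.shape != (4,):
        raise ValueError("type_proportions must have four entries (joy, anger, sadness, fear)")
    if np.any(props < 0):
        raise ValueError("proportions must be non-negative")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    rng = np.random.default_rng() if rng is None else rng

    if multinomial:
        counts = rng.multinomial(n, props)
    else:
        counts = _largest_remainder_counts(n, props)
    emo_type = np.repeat(np.arange(1, 5), counts)
    rng.shuffle(emo_type)

    pos_spec, neg_spec = pleasure_specs
    pleasure = np.empty(n)
    joy_mask = emo_type == JOY
    pleasure[joy_mask] = _draw_signed(pos_spec, int(joy_mask.sum()), rng, sign=+1)
    pleasure[~joy_mask] = _draw_signed(neg_spec, int((~joy_mask).sum()), rng, sign=-1)
    return emo_type, pleasure, arousal_of(emo_type)


def _draw_signed(spec: TraitSpec, n: int, rng: np.random.Generator, sign: int) -> np.ndarray:
    """Draw from spec enforcing a strict sign and |value| < 1."""
    if n == 0:
        return np.empty(0)
    x = spec.sample(n, rng)
    zero = x == 0.0
    if np.any(zero):  # one redraw, then nudge
        x[zero] = spec.sample(int(zero.sum()), rng)
        x[x == 0.0] = sign * _EPS
    # keep strictly inside the open interval (-1, 1)
    return np.clip(x, -1.0 + _EPS if sign < 0 else _EPS, 1.0 - _EPS if sign > 0 else -_EPS)


def build_population(
    n: int,
    trait_specs: dict[str, TraitSpec] | None = None,
    type_proportions=(0.25, 0.25, 0.25, 0.25),
    pleasure_specs=(POSITIVE_PLEASURE_SPEC, NEGATIVE_PLEASURE_SPEC),
    rng: np.random.Generator | None = None,
    multinomial: bool = False,
) -> Population:
    """Sample a full population (traits + initial emotions)."""
    rng = np.random.default_rng() if rng is None else rng
    traits = sample_traits(n, trait_specs, rng)
    emo_type, pleasure, arousal = init_emotions(
        n, type_proportions, pleasure_specs, rng, multinomial=multinomial
    )
    return Population(
        alpha=traits["alpha"],
        delta=traits["delta"],
        gamma=traits["gamma"],
        lam=traits["lam"],
        zeta=traits["zeta"],
        emo_type=emo_type,
        pleasure=pleasure,
        arousal=arousal,
    )
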