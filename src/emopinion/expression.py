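"""Emotion externalization: expression willingness and the emotion-to-attitude map.

An agent's willingness to speak W combines a subjective part WS (driven by
the emotion's pleasure magnitude and arousal, the agent's extroversion, and
the event's life relevance over its political sensitivity) with, once public
opinion has formed, an objective part WO fed back from the opinion field.
The willingness splits the population into silent agents (W < W_part),
cautious partial expressers (W_part <= W < W_full) and full expressers
(W >= W_full); expressed attitudes inherit the emotion type and scale the
pleasure degree by the agent's expression ability delta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .population import AgentTraits, EmotionState, EventInfo

__all__ = [
    "AttitudeState",
    "WillingnessRecord",
    "ExpressionParams",
    "subjective_willingness",
    "objective_willingness",
    "total_willingness",
    "externalize",
    "subjective_willingness_all",
    "externalize_all",
]


@dataclass(frozen=True)
class AttitudeState:
    """Public state of a single agent: attitude type (0 = unexpressed) and value."""

    att_type: int
    value: float


@dataclass(frozen=True)
class WillingnessRecord:
    """Decomposition of an agent's expression willingness."""

    ws: float  # subjective component, >= 0
    wo: float  # objective (public-opinion feedback) component, may be negative
    total: float  # clamp(ws [+ wo]) in [0, 1]


@dataclass(frozen=True)
class ExpressionParams:
    """Willingness thresholds and regulation constants.

    ``w_part``/``w_full`` split silent / partial / full expression; ``k1``
    scales subjective willingness; ``k2`` scales the public-opinion feedback.
    """

    w_part: float = 0.2
    w_full: float = 0.4
    k1: float = 0.7
    k2: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.w_part < self.w_full < 1:
            raise ValueError("thresholds must satisfy 0 < w_part < w_full < 1")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("k1 and k2 must be positive")


def subjective_willingness(
    emotion: EmotionState, traits: AgentTraits, info: EventInfo, k1: float = 0.7
) -> float:
    """WS = |pleasure| * arousal * alpha * (beta1 / beta2) * k1.

    The pleasure degree enters in absolute value: a strongly negative emotion
    motivates expression as much as a strongly positive one.
    """
    if info.beta2 <= 0:
        raise ZeroDivisionError("beta2 must be positive")
    return abs(emotion.pleasure) * emotion.arousal * traits.alpha * (info.beta1 / info.beta2) * k1


def subjective_willingness_all(
    pleasure: np.ndarray,
    arousal: np.ndarray,
    alpha: np.ndarray,
    info: EventInfo,
    k1: float = 0.7,
) -> np.ndarray:
    """Vectorized subjective willingness for a whole population."""
    return np.abs(pleasure) * arousal * alpha * (info.beta1 / info.beta2) * k1


def objective_willingness(p_i: float, n_a: int, n: int, k2: float = 1.0) -> float:
    """WO = k2 * (P_i - 0.25) * N_A / N.

    ``p_i`` is the opinion-field share of the attitude type the agent would
    express; with four basic attitudes, a share above the 25% pivot marks a
    majority view and raises the agent's willingness, a share below it marks
    a minority view and suppresses it. ``n_a`` is the number of agents
    currently expressing, out of ``n`` total.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= p_i <= 1:
        raise ValueError("p_i must be a proportion in [0, 1]")
    if not 0 <= n_a <= n:
        raise ValueError("n_a must be between 0 and n")
    return k2 * (p_i - 0.25) * n_a / n


def total_willingness(ws: float, wo: float = 0.0, opinion_formed: bool = False) -> float:
    """Total willingness: WS before opinion formation, clamp(WS + WO) after.

    The sum can leave [0, 1] (WO may be negative, WS is unbounded above);
    the result is clamped because willingness acts as a probability-like gate.
    """
    w = ws + wo if opinion_formed else ws
    return float(np.clip(w, 0.0, 1.0))


def externalize(
    emotion: EmotionState, w: float, delta: float, params: ExpressionParams
) -> AttitudeState:
    """Map an emotion to a public attitude under willingness ``w`` (single agent).

    Below ``w_part`` the agent stays silent (0, 0). Between the thresholds the
    emotion is partially externalized, scaled by the agent's position within
    the band; at or above ``w_full`` it is fully externalized. Expressed
    attitudes keep the emotion type; values are delta * pleasure (delta > 1
    exaggerates) clamped to [-1, 1]. Boundaries are closed on the left:
    w == w_part expresses partially, w == w_full fully.
    """
    if not 0 <= w <= 1:
        raise ValueError("willingness must be in [0, 1]")
    if w < params.w_part:
        return AttitudeState(0, 0.0)
    if w < params.w_full:
        scale = (w - params.w_part) / (params.w_full - params.w_part)
        value = scale * delta * emotion.pleasure
    else:
        value = delta * emotion.pleasure
    return AttitudeState(emotion.emo_type, float(np.clip(value, -1.0, 1.0)))


def externalize_all(
    emo_type: np.ndarray,
    pleasure: np.ndarray,
    w: np.ndarray,
    delta: np.ndarray,
    params: ExpressionParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized externalization; returns (att_type, value) arrays."""
    silent = w < params.w_part
    partial = (~silent) & (w < params.w_full)
    scale = np.ones_like(w)
    scale[partial] = (w[partial] - params.w_part) / (params.w_full - params.w_part)
    value = np.clip(scale * delta * pleasure, -1.0, 1.0)
    att_type = np.where(silent, 0, emo_type).astype(emo_type.dtype)
    value[silent] = 0.0
    return att_type, value
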