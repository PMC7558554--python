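"""One synchronous round of opinion exchange on the social network.

Each expressing agent perceives its neighbors' attitudes (damped by the
sender's inciting force, the receiver's receptivity and the tie strength),
may switch to the mainstream attitude type of its neighborhood under
conformity pressure, and otherwise nudges its own attitude value toward the
perceived same-type neighborhood average under a bounded-confidence rule:
assimilation happens only when the perceived average lies within the
threshold d1, and it strengthens the attitude's magnitude at rate theta1.
Silent agents (attitude type 0) neither send nor update.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .networks import SocialNetwork

__all__ = [
    "DWParams",
    "PerceptionRecord",
    "NeighborhoodSummary",
    "inciting_force",
    "perceive",
    "type_change_probability",
    "dw_update",
    "summarize_neighborhood",
    "interact_round",
]


@dataclass(frozen=True)
class DWParams:
    """Bounded-confidence update parameters.

    ``d1`` is the assimilation threshold: a perceived average farther than d1
    from the agent's value leaves it unchanged. ``theta1`` is the assimilation
    rate applied to the gap; it strengthens positive values upward and
    negative values downward.
    """

    d1: float = 0.5
    theta1: float = 0.5

    def __post_init__(self) -> None:
        if self.d1 <= 0:
            raise ValueError("d1 must be positive")
        if not 0 < self.theta1 <= 1:
            raise ValueError("theta1 must be in (0, 1]")


@dataclass(frozen=True)
class PerceptionRecord:
    """Perception of one sender by one receiver."""

    inciting_force: float
    perceived_value: float
    adjustment: float


@dataclass(frozen=True)
class NeighborhoodSummary:
    """What an expressing agent sees in its neighborhood in one round.

    Proportions use ALL neighbors (silent ones included) as denominator;
    the weighted averages are perceived-value sums over the mainstream-type
    (resp. same-type) neighbors, normalized by the tie strengths of that same
    neighbor set. ``inert`` flags agents with no expressing neighbors (or no
    neighbors at all), which cannot update this round.
    """

    mainstream_type: int
    pn_iu: float
    pn_i: float
    n_iu: int
    n_i: int
    mainstream_avg: float
    same_type_avg: float
    t_iu: float
    inert: bool = False


def inciting_force(sender_arousal: float, a: float = 1.0) -> float:
    """epsilon = a * arousal: higher-arousal emotions transmit more forcefully."""
    return a * sender_arousal


def perceive(sender_value: float, eps: float, lam_receiver: float, s_edge: float) -> float:
    """O = y * epsilon * lambda * S: the sender's attitude as felt by the receiver."""
    return sender_value * eps * lam_receiver * s_edge


def type_change_probability(pn_iu: float, pn_i: float, gamma: float) -> float:
    """T = |Pn_iu - Pn_i| * gamma: conformity pressure toward the mainstream."""
    return abs(pn_iu - pn_i) * gamma


def dw_update(y: float, avg: float, params: DWParams) -> float:
    """Bounded-confidence value update for an agent that kept its type.

    When the perceived average is within d1 of y, positive attitudes gain
    theta1 * |avg - y| and negative attitudes lose the same amount (the
    attitude magnitude strengthens either way); otherwise y is unchanged.
    The result is clamped to [-1, 1].
    """
    if abs(y - avg) >= params.d1:
        return y
    step = params.theta1 * abs(avg - y)
    y_new = y + step if y > 0 else y - step if y < 0 else y
    return float(np.clip(y_new, -1.0, 1.0))


def summarize_neighborhood(
    i: int,
    att_type: np.ndarray,
    att_value: np.ndarray,
    emo_arousal: np.ndarray,
    net: SocialNetwork,
    gamma_i: float,
    lam_i: float,
    a: float = 1.0,
) -> NeighborhoodSummary:
    """Per-agent neighborhood summary (reference implementation, one node).

    Used for diagnostics and for cross-checking the vectorized round update;
    ``att_type``/``att_value`` are the time-t snapshot for all agents and
    ``emo_arousal`` the senders' emotional arousal levels.
    """
    if att_type[i] == 0:
        raise ValueError("summaries are defined for expressing agents only")
    neighbors = list(net.neighbors(i))
    deg = len(neighbors)
    counts = {k: 0 for k in (1, 2, 3, 4)}
    for j in neighbors:
        tj = int(att_type[j])
        if tj:
            counts[tj] += 1
    n_expressing = sum(counts.values())
    if deg == 0 or n_expressing == 0:
        return NeighborhoodSummary(0, 0.0, 0.0, 0, 0, 0.0, 0.0, 0.0, inert=True)

    u = max(counts, key=lambda k: (counts[k], -k))  # ties -> lowest type index
    own = int(att_type[i])
    n_iu, n_i = counts[u], counts[own]
    pn_iu, pn_i = n_iu / deg, n_i / deg

    def weighted_avg(target_type: int) -> float:
        num = den = 0.0
        for j in neighbors:
            if int(att_type[j]) == target_type:
                s = net.tie_strength(i, j)
                eps = inciting_force(float(emo_arousal[j]), a)
                num += perceive(float(att_value[j]), eps, lam_i, s)
                den += s
        return num / den if den > 0 else 0.0

    return NeighborhoodSummary(
        mainstream_type=u,
        pn_iu=pn_iu,
        pn_i=pn_i,
        n_iu=n_iu,
        n_i=n_i,
        mainstream_avg=weighted_avg(u),
        same_type_avg=weighted_avg(own) if n_i > 0 else 0.0,
        t_iu=type_change_probability(pn_iu, pn_i, gamma_i),
    )


def interact_round(
    att_type: np.ndarray,
    att_value: np.ndarray,
    emo_arousal: np.ndarray,
    net: SocialNetwork,
    gamma: np.ndarray,
    lam: np.ndarray,
    dw: DWParams,
    rng: np.random.Generator,
    a: float = 1.0,
    bernoulli_switch: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One synchronous round; returns (new_type, new_value, switched).

    All updates are computed from the time-t snapshot, so the outcome does
    not depend on agent iteration order. For each expressing agent: if the
    share of same-type neighbors Pn_i exceeds the conformity pressure T_iu
    the type is kept; otherwise the agent switches to the mainstream type,
    taking the perceived mainstream average as its new value. By default the
    switch is deterministic whenever the no-change gate fails (this is what
    produces the one-round collapse to the dominant attitude under a heavily
    skewed emotion mix); with ``bernoulli_switch=True`` the switch instead
    happens with probability T_iu. Agents that keep their type apply the
    bounded-confidence update against the perceived same-type average (no
    same-type neighbors: value unchanged). RNG contract: exactly one uniform
    draw per node, in node order, used as the switch threshold (drawn in
    both modes so trajectories are comparable across modes).
    """
    n = len(att_type)
    draws = rng.random(n)  # one uniform per node, consumed unconditionally

    expressing = att_type > 0
    new_type = att_type.copy()
    new_value = att_value.copy()
    switched = np.zeros(n, dtype=bool)
    if not expressing.any():
        return new_type, new_value, switched

    adj = net.adjacency_matrix
    strengths = net.strength_matrix
    deg = np.asarray(adj.sum(axis=1)).ravel()

    # one-hot (n, 4) masks over attitude types 1..4 at time t
    onehot = np.stack([(att_type == k).astype(float) for k in (1, 2, 3, 4)], axis=1)
    counts = adj @ onehot  # neighbors per type
    send = att_value * inciting_force(emo_arousal, a)  # y_j * eps_j
    num = strengths @ (onehot * send[:, None])  # sum S_ij y_j eps_j per type
    den = strengths @ onehot  # sum S_ij per type

    n_express_nb = counts.sum(axis=1)
    inert = (deg == 0) | (n_express_nb == 0)

    u = np.argmax(counts, axis=1) + 1  # first max -> lowest type index
    own = att_type
    safe_deg = np.where(deg > 0, deg, 1)
    pn_iu = counts[np.arange(n), u - 1] / safe_deg
    own_idx = np.clip(own - 1, 0, 3)
    pn_i = np.where(expressing, counts[np.arange(n), own_idx] / safe_deg, 0.0)
    t_iu = np.abs(pn_iu - pn_i) * gamma

    active = expressing & ~inert
    keep_gate = pn_i > t_iu
    if bernoulli_switch:
        switch = active & ~keep_gate & (draws < t_iu)
    else:
        switch = active & ~keep_gate & (t_iu > 0)

    # switchers adopt the mainstream type and its perceived weighted average
    if switch.any():
        idx = np.flatnonzero(switch)
        u_idx = u[idx] - 1
        avg_u = lam[idx] * num[idx, u_idx] / den[idx, u_idx]
        new_type[idx] = u[idx]
        new_value[idx] = np.clip(avg_u, -1.0, 1.0)
        switched[idx] = True

    # keepers assimilate toward the perceived same-type average
    keep = active & ~switch
    if keep.any():
        idx = np.flatnonzero(keep)
        o_idx = own_idx[idx]
        den_own = den[idx, o_idx]
        has_same = den_own > 0
        idx = idx[has_same]
        if idx.size:
            avg_own = lam[idx] * num[idx, own_idx[idx]] / den_own[has_same]
            y = att_value[idx]
            gap = np.abs(y - avg_own)
            within = gap < dw.d1
            step = dw.theta1 * np.abs(avg_own - y)
            y_new = np.where(y > 0, y + step, np.where(y < 0, y - step, y))
            new_value[idx] = np.where(within, np.clip(y_new, -1.0, 1.0), y)
    return new_type, new_value, switched
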