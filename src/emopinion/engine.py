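"""Two-stage simulation loop: externalize, interact, internalize, re-externalize.

Stage 1: every agent computes its subjective willingness, externalizes its
emotion into an attitude if willing, and the expressing agents exchange views
for t1 synchronous rounds. At the end of stage 1 expressing agents
internalize their (possibly changed) attitude back into emotion, and
public-opinion formation is evaluated: participation share >= P1, steady
attitudes, and at least one attitude type holding >= P2 of the expressers.

Stage 2: willingness is recomputed for all agents -- subjective willingness
from the updated emotions plus, if public opinion formed, the objective
feedback term driven by the opinion-field shares. Silent agents may join,
expressing agents whose willingness dropped below the partial threshold fall
silent (those who remain keep their interacted attitude value), and
interaction continues until the attitudes are steady or a round cap is hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import (
    AttitudeState,
    ExpressionParams,
    externalize_all,
    subjective_willingness_all,
)
from .interaction import DWParams, interact_round
from .networks import SocialNetwork
from .population import EmotionState, EventInfo, Population, arousal_of

__all__ = [
    "SimulationParams",
    "Trajectory",
    "internalize",
    "detect_steady_state",
    "detect_opinion_formation",
    "run_stage1",
    "run_simulation",
]


@dataclass(frozen=True)
class SimulationParams:
    """Schedule and opinion-formation thresholds.

    ``p1`` is the participation share required for public opinion to form,
    ``p2`` the per-type share (among expressers) that marks a dominant
    attitude; ``t1`` is the number of stage-1 interaction rounds before the
    formed opinion feeds back into willingness. Steadiness means
    ``steady_window`` consecutive rounds with no type switch and per-agent
    value changes below ``steady_tol``.
    """

    p1: float = 0.5
    p2: float = 0.3
    t1: int = 30
    max_rounds: int = 200
    steady_tol: float = 1e-3
    steady_window: int = 3
    a: float = 1.0  # perception adjustment coefficient

    def __post_init__(self) -> None:
        if self.t1 < 1 or self.max_rounds < 1:
            raise ValueError("t1 and max_rounds must be at least 1")
        if self.steady_window < 1 or self.steady_tol <= 0:
            raise ValueError("steady_window must be >= 1 and steady_tol > 0")


@dataclass
class Trajectory:
    """Per-round records of a two-stage run plus end-of-run summaries."""

    records: list[dict] = field(default_factory=list)
    stage1_steady_round: int | None = None
    stage2_steady_round: int | None = None
    opinion_formed: bool = False
    dominant_types: tuple[int, ...] = ()
    n_expressing_stage1: int = 0
    n_expressing_stage2: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_records(self.records)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self) -> dict:
        return {
            "opinion_formed": self.opinion_formed,
            "dominant_types": list(self.dominant_types),
            "stage1_steady_round": self.stage1_steady_round,
            "stage2_steady_round": self.stage2_steady_round,
            "n_expressing_stage1": self.n_expressing_stage1,
            "n_expressing_stage2": self.n_expressing_stage2,
        }


def internalize(attitude: AttitudeState, emotion: EmotionState, zeta: float) -> EmotionState:
    """Map an expressed attitude back into emotion (single agent).

    The emotion type becomes the attitude type, the pleasure degree becomes
    zeta * value, and the arousal is re-looked-up for the (possibly new)
    emotion type. Internalizing an unexpressed attitude is a no-op.
    """
    if attitude.att_type == 0:
        return emotion
    return EmotionState(
        emo_type=attitude.att_type,
        pleasure=zeta * attitude.value,
        arousal=arousal_of(attitude.att_type),
    )


def detect_steady_state(
    types: np.ndarray,
    values: np.ndarray,
    steady_tol: float = 1e-3,
    steady_window: int = 3,
) -> int | None:
    """First round after which attitudes stay quiet for ``steady_window`` rounds.

    ``types``/``values`` are (T+1, n) per-round snapshots (row 0 = initial
    state). A round t is quiet when no agent changed type between t-1 and t
    and the largest per-agent value change is below ``steady_tol``. The
    steady round is the round at which the last change lands, provided every
    later round is quiet and at least ``steady_window`` quiet rounds follow
    to confirm it (0 for a trajectory with no changes at all); None if the
    trailing quiet stretch is shorter than the window.
    """
    types = np.asarray(types)
    values = np.asarray(values)
    n_rounds = types.shape[0] - 1
    if n_rounds < steady_window:
        return None
    quiet = np.array(
        [
            (types[t] == types[t - 1]).all()
            and np.max(np.abs(values[t] - values[t - 1]), initial=0.0) < steady_tol
            for t in range(1, n_rounds + 1)
        ]
    )
    loud = np.flatnonzero(~quiet)
    last_change = int(loud[-1]) + 1 if loud.size else 0
    return last_change if n_rounds - last_change >= steady_window else None


def detect_opinion_formation(
    n_expressing: int,
    n_total: int,
    type_shares,
    steady: bool,
    p1: float = 0.5,
    p2: float = 0.3,
) -> tuple[bool, tuple[int, ...]]:
    """Public-opinion formation test.

    Formed iff the participation share N_A / N reaches ``p1``, the attitudes
    are steady, and at least one attitude type's share among expressers
    reaches ``p2``. ``type_shares`` holds the four expresser shares for types
    1..4; the dominant set lists every type at or above ``p2`` (public
    opinion may carry more than one attitude).
    """
    shares = np.asarray(type_shares, dtype=float)
    if n_expressing == 0 or n_total == 0:
        return False, ()
    dominant = tuple(int(k) for k in np.flatnonzero(shares >= p2) + 1)
    formed = (n_expressing / n_total >= p1) and steady and bool(dominant)
    return (formed, dominant) if formed else (False, dominant)


def _type_shares(att_type: np.ndarray) -> tuple[int, np.ndarray]:
    """Expressing count and per-type shares among expressers (types 1..4)."""
    counts = np.bincount(att_type, minlength=5)[1:5]
    n_a = int(counts.sum())
    shares = counts / n_a if n_a else np.zeros(4)
    return n_a, shares


def _record(records: list, stage: int, t: int, att_type, att_value, formed: bool, dominant):
    n_a, shares = _type_shares(att_type)
    row = {"stage": stage, "t": t, "n_expressing": n_a}
    for k in range(1, 5):
        mask = att_type == k
        row[f"prop_type{k}"] = shares[k - 1]
        row[f"mean_value_type{k}"] = float(att_value[mask].mean()) if mask.any() else np.nan
    row["opinion_formed"] = formed
    row["dominant_types"] = ";".join(str(d) for d in dominant)
    records.append(row)


def _run_rounds(
    att_type,
    att_value,
    pop: Population,
    net: SocialNetwork,
    dw: DWParams,
    params: SimulationParams,
    rng: np.random.Generator,
    n_rounds: int,
    stop_when_steady: bool,
):
    """Run interaction rounds, returning snapshot stacks (T+1, n)."""
    types = [att_type.copy()]
    values = [att_value.copy()]
    streak = 0
    for _ in range(n_rounds):
        new_type, new_value, _switched = interact_round(
            types[-1], values[-1], pop.arousal, net, pop.gamma, pop.lam, dw, rng, a=params.a
        )
        quiet = (new_type == types[-1]).all() and np.max(
            np.abs(new_value - values[-1]), initial=0.0
        ) < params.steady_tol
        streak = streak + 1 if quiet else 0
        types.append(new_type)
        values.append(new_value)
        if stop_when_steady and streak >= params.steady_window:
            break
    return np.stack(types), np.stack(values)


def run_stage1(
    pop: Population,
    net: SocialNetwork,
    event: EventInfo,
    expr: ExpressionParams,
    dw: DWParams,
    params: SimulationParams,
    rng: np.random.Generator,
    n_rounds: int | None = None,
    stop_when_steady: bool = False,
):
    """First externalization plus stage-1 interaction rounds.

    Returns (types, values) snapshot stacks of shape (rounds+1, n), where row
    0 is the state right after the initial externalization.
    """
    ws = subjective_willingness_all(pop.pleasure, pop.arousal, pop.alpha, event, expr.k1)
    w = np.clip(ws, 0.0, 1.0)
    att_type, att_value = externalize_all(pop.emo_type, pop.pleasure, w, pop.delta, expr)
    return _run_rounds(
        att_type,
        att_value,
        pop,
        net,
        dw,
        params,
        rng,
        params.t1 if n_rounds is None else n_rounds,
        stop_when_steady,
    )


def run_simulation(
    pop: Population,
    net: SocialNetwork,
    event: EventInfo = EventInfo(),
    expr: ExpressionParams = ExpressionParams(),
    dw: DWParams = DWParams(),
    params: SimulationParams = SimulationParams(),
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Full two-stage run; mutates ``pop``'s emotions at internalization.

    See the module docstring for the loop structure. The returned
    :class:`Trajectory` carries one record per round (stage label, expressing
    count, per-type expresser shares and mean values, formation flag) plus
    end-of-run summaries.
    """
    rng = np.random.default_rng() if rng is None else rng
    traj = Trajectory()

    # ---- stage 1: first externalization + t1 interaction rounds
    types1, values1 = run_stage1(pop, net, event, expr, dw, params, rng)
    steady1 = detect_steady_state(types1, values1, params.steady_tol, params.steady_window)
    att_type, att_value = types1[-1], values1[-1]

    n_a1, shares1 = _type_shares(att_type)
    formed, dominant = detect_opinion_formation(
        n_a1, pop.n, shares1, steady1 is not None, params.p1, params.p2
    )
    for t in range(types1.shape[0]):
        _record(traj.records, 1, t, types1[t], values1[t], False, ())
    traj.records[-1]["opinion_formed"] = formed
    traj.records[-1]["dominant_types"] = ";".join(str(d) for d in dominant)
    traj.stage1_steady_round = steady1
    traj.opinion_formed = formed
    traj.dominant_types = tuple(dominant) if formed else ()
    traj.n_expressing_stage1 = int(np.bincount(types1[0], minlength=5)[1:5].sum())

    # ---- internalization: expressed attitudes map back into emotion
    expressed = att_type > 0
    pop.emo_type = np.where(expressed, att_type, pop.emo_type)
    pop.pleasure = np.where(expressed, pop.zeta * att_value, pop.pleasure)
    pop.arousal = arousal_of(pop.emo_type)

    # ---- secondary externalization under public-opinion feedback
    ws2 = subjective_willingness_all(pop.pleasure, pop.arousal, pop.alpha, event, expr.k1)
    if formed:
        p_agent = shares1[np.clip(pop.emo_type - 1, 0, 3)]
        wo = expr.k2 * (p_agent - 0.25) * n_a1 / pop.n
    else:  # no public opinion to feed back
        wo = np.zeros(pop.n)
    w2 = np.clip(ws2 + wo, 0.0, 1.0)

    new_type, new_value = externalize_all(pop.emo_type, pop.pleasure, w2, pop.delta, expr)
    # agents already expressing keep their interacted value if still willing
    keep = expressed & (w2 >= expr.w_part)
    att_type2 = np.where(keep, att_type, new_type)
    att_value2 = np.where(keep, att_value, new_value)

    # ---- stage 2 interaction until steady or the round cap
    types2, values2 = _run_rounds(
        att_type2, att_value2, pop, net, dw, params, rng, params.max_rounds, stop_when_steady=True
    )
    traj.stage2_steady_round = detect_steady_state(
        types2, values2, params.steady_tol, params.steady_window
    )
    traj.n_expressing_stage2 = int(np.bincount(types2[0], minlength=5)[1:5].sum())
    for t in range(types2.shape[0]):
        _record(traj.records, 2, t, types2[t], values2[t], formed, traj.dominant_types)
    return traj
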