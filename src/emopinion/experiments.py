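"""Scripted Monte-Carlo sweeps with replication over seeds.

Each sweep runs every grid cell for ``replicates`` independent seeds
(spawned from a single base seed) and returns a tidy per-run DataFrame; use
:func:`aggregate` for per-cell means and dispersions. Sweeps cover the three
experiment families: trait / event-information levels (externalized counts),
initial-emotion composition on the simplex (externalized counts), and the
stage schedule t1 crossed with network topologies (stage-1 vs stage-2
participation).
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd

from .config import SimulationConfig, run_from_config
from .engine import run_stage1
from .expression import externalize_all, subjective_willingness_all
from .networks import generate_network, topology_metrics
from .population import DEFAULT_TRAIT_SPECS, TraitSpec, build_population

__all__ = [
    "spawn_seeds",
    "count_externalized",
    "sweep_trait_levels",
    "sweep_emotion_simplex",
    "sweep_t1_and_networks",
    "network_statistics",
    "aggregate",
]


def spawn_seeds(base_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from one base seed."""
    ss = np.random.SeedSequence(base_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def count_externalized(config: SimulationConfig, seed: int) -> int:
    """Number of agents expressing after the initial externalization.

    The initial count depends only on traits, emotions and the event (not on
    the network), so the graph is not generated here.
    """
    rng = np.random.default_rng(seed)
    pop = build_population(
        config.n_agents,
        trait_specs=config.trait_specs,
        type_proportions=config.emotion_proportions,
        pleasure_specs=config.pleasure_specs,
        rng=rng,
        multinomial=config.multinomial_types,
    )
    ws = subjective_willingness_all(
        pop.pleasure, pop.arousal, pop.alpha, config.event, config.expression.k1
    )
    att_type, _ = externalize_all(
        pop.emo_type, pop.pleasure, np.clip(ws, 0, 1), pop.delta, config.expression
    )
    return int((att_type > 0).sum())


def sweep_trait_levels(
    base: SimulationConfig,
    alpha_means=None,
    delta_means=None,
    beta1_values=None,
    beta2_values=None,
    replicates: int = 20,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Externalized counts over a grid of trait means and/or event levels.

    Any combination of the four grids may be given; omitted ones stay at the
    base configuration. Trait grids move the mean of the clipped-normal spec
    while keeping its spread (extroversion levels use sd 0.4, expression
    ability sd 0.2, matching the low/medium/high scenario definitions).
    """
    grids = {
        "alpha_mean": list(alpha_means) if alpha_means is not None else [None],
        "delta_mean": list(delta_means) if delta_means is not None else [None],
        "beta1": list(beta1_values) if beta1_values is not None else [None],
        "beta2": list(beta2_values) if beta2_values is not None else [None],
    }
    seeds = spawn_seeds(base_seed, replicates)
    rows = []
    for alpha_m, delta_m, b1, b2 in product(*grids.values()):
        cfg = base
        traits = dict(cfg.trait_specs)
        if alpha_m is not None:
            traits["alpha"] = TraitSpec(alpha_m, 0.4, 0.0, 1.0)
        if delta_m is not None:
            traits["delta"] = TraitSpec(delta_m, 0.2, 0.0, 2.0)
        cfg = cfg.with_overrides(trait_specs=traits)
        if b1 is not None or b2 is not None:
            ev = cfg.event
            cfg = cfg.with_overrides(
                event=type(ev)(
                    beta1=b1 if b1 is not None else ev.beta1,
                    beta2=b2 if b2 is not None else ev.beta2,
                )
            )
        for rep, seed in enumerate(seeds):
            rows.append(
                {
                    "alpha_mean": alpha_m,
                    "delta_mean": delta_m,
                    "beta1": b1,
                    "beta2": b2,
                    "replicate": rep,
                    "seed": seed,
                    "n_externalized": count_externalized(cfg, seed),
                }
            )
    return pd.DataFrame(rows)


def simplex_grid(zero_emotion: int, step: float = 0.1):
    """Proportion vectors with one emotion at 0 and the other three summing to 1."""
    if zero_emotion not in (1, 2, 3, 4):
        raise ValueError("zero_emotion must be an emotion type in 1..4")
    ticks = np.round(np.arange(0.0, 1.0 + 1e-9, step), 10)
    points = []
    for p, q in product(ticks, repeat=2):
        r = round(1.0 - p - q, 10)
        if r < -1e-9:
            continue
        props = [0.0, 0.0, 0.0, 0.0]
        free = [k for k in range(4) if k != zero_emotion - 1]
        props[free[0]], props[free[1]], props[free[2]] = p, q, max(r, 0.0)
        points.append(tuple(props))
    return points


def sweep_emotion_simplex(
    base: SimulationConfig,
    zero_emotion: int,
    step: float = 0.1,
    replicates: int = 20,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Externalized counts over initial-emotion compositions.

    One basic emotion is held at share 0 and the other three range over a
    simplex grid with the given step, mirroring the four-panel design where
    each panel removes one emotion.
    """
    seeds = spawn_seeds(base_seed, replicates)
    rows = []
    for props in simplex_grid(zero_emotion, step):
        cfg = base.with_overrides(emotion_proportions=props)
        for rep, seed in enumerate(seeds):
            rows.append(
                {
                    "prop_joy": props[0],
                    "prop_anger": props[1],
                    "prop_sadness": props[2],
                    "prop_fear": props[3],
                    "replicate": rep,
                    "seed": seed,
                    "n_externalized": count_externalized(cfg, seed),
                }
            )
    return pd.DataFrame(rows)


def sweep_t1_and_networks(
    base: SimulationConfig,
    t1_values=None,
    network_kinds=None,
    replicates: int = 20,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Two-stage participation over a grid of t1 values and network families."""
    t1_values = list(t1_values) if t1_values is not None else [base.sim.t1]
    network_kinds = list(network_kinds) if network_kinds is not None else [base.network_kind]
    seeds = spawn_seeds(base_seed, replicates)
    rows = []
    for t1, kind in product(t1_values, network_kinds):
        cfg = base.with_overrides(
            sim=base.sim.__class__(
                p1=base.sim.p1,
                p2=base.sim.p2,
                t1=int(t1),
                max_rounds=base.sim.max_rounds,
                steady_tol=base.sim.steady_tol,
                steady_window=base.sim.steady_window,
                a=base.sim.a,
            ),
            network_kind=kind,
            network_params={},
        )
        for rep, seed in enumerate(seeds):
            traj = run_from_config(cfg, seed)
            rows.append(
                {
                    "t1": int(t1),
                    "network": kind,
                    "replicate": rep,
                    "seed": seed,
                    "n_stage1": traj.n_expressing_stage1,
                    "n_stage2": traj.n_expressing_stage2,
                    "opinion_formed": traj.opinion_formed,
                    "stage1_steady_round": traj.stage1_steady_round,
                    "stage2_steady_round": traj.stage2_steady_round,
                }
            )
    return pd.DataFrame(rows)


def steady_rounds(
    base: SimulationConfig,
    emotion_proportions,
    replicates: int = 20,
    base_seed: int = 0,
    horizon: int = 80,
) -> pd.DataFrame:
    """Stage-1 steady-state round per replicate for a fixed emotion mix.

    Runs stage 1 alone for up to ``horizon`` rounds (stopping once the quiet
    window is confirmed) and records the round of the last attitude change.
    """
    from .engine import detect_steady_state

    cfg = base.with_overrides(emotion_proportions=tuple(emotion_proportions))
    rows = []
    for rep, seed in enumerate(spawn_seeds(base_seed, replicates)):
        rng = np.random.default_rng(seed)
        from .config import build_simulation

        pop, net = build_simulation(cfg, rng)
        types, values = run_stage1(
            pop, net, cfg.event, cfg.expression, cfg.dw, cfg.sim, rng,
            n_rounds=horizon, stop_when_steady=True,
        )
        rows.append(
            {
                "replicate": rep,
                "seed": seed,
                "steady_round": detect_steady_state(
                    types, values, cfg.sim.steady_tol, cfg.sim.steady_window
                ),
                "n_externalized": int((types[0] > 0).sum()),
            }
        )
    return pd.DataFrame(rows)


def network_statistics(
    kinds=("ba", "ws", "er", "complete"),
    n: int = 1000,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Topology metrics per network family at the default parameters."""
    rows = []
    for i, kind in enumerate(kinds):
        rng = np.random.default_rng(spawn_seeds(base_seed, len(kinds))[i])
        net = generate_network(kind, n, rng=rng)
        m = topology_metrics(net)
        rows.append(
            {
                "network": kind,
                "n_nodes": n,
                "avg_path_length": m.avg_path_length,
                "clustering_coefficient": m.clustering_coefficient,
                "avg_degree": m.avg_degree,
            }
        )
    return pd.DataFrame(rows)


def aggregate(df: pd.DataFrame, by, value_cols=None) -> pd.DataFrame:
    """Per-cell mean/std/count; a pure function of the per-run table."""
    if value_cols is None:
        value_cols = [
            c
            for c in df.columns
            if c not in set(by) | {"replicate", "seed"} and pd.api.types.is_numeric_dtype(df[c])
        ]
    out = df.groupby(list(by), dropna=False)[value_cols].agg(["mean", "std", "count"])
    out.columns = ["_".join(c) for c in out.columns]
    return out.reset_index()
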