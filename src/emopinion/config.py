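"""Structured run configuration: YAML in, assembled simulation objects out."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

from .engine import SimulationParams, Trajectory, run_simulation
from .expression import ExpressionParams
from .interaction import DWParams
from .networks import DEFAULT_TIE_SPEC, SocialNetwork, generate_network
from .population import (
    DEFAULT_TRAIT_SPECS,
    NEGATIVE_PLEASURE_SPEC,
    POSITIVE_PLEASURE_SPEC,
    EventInfo,
    Population,
    TraitSpec,
    build_population,
)

__all__ = ["SimulationConfig", "load_config", "build_simulation", "run_from_config"]


@dataclass(frozen=True)
class SimulationConfig:
    """Complete description of one run; defaults are the baseline scenario.

    Baseline: 1000 agents on a scale-free (BA, m=10) network; extroversion,
    conformity and receptivity ~ N(0.5, 0.15) on [0, 1]; expression ability
    ~ N(1, 0.2) on [0, 2]; internalization ~ N(0.9, 0.05) on [0, 1]; equal
    25% shares of joy/anger/sadness/fear with pleasure ~ +-N(0.5, 0.15);
    event with life relevance 0.9 and political sensitivity 0.5.
    """

    n_agents: int = 1000
    network_kind: str = "ba"
    network_params: dict = field(default_factory=dict)
    trait_specs: dict = field(default_factory=dict)  # name -> TraitSpec overrides
    emotion_proportions: tuple = (0.25, 0.25, 0.25, 0.25)
    pleasure_specs: tuple = (POSITIVE_PLEASURE_SPEC, NEGATIVE_PLEASURE_SPEC)
    tie_spec: TraitSpec = DEFAULT_TIE_SPEC
    multinomial_types: bool = False
    event: EventInfo = EventInfo()
    expression: ExpressionParams = ExpressionParams()
    dw: DWParams = DWParams()
    sim: SimulationParams = SimulationParams()
    seed: int | None = None

    def with_overrides(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["trait_specs"] = {k: asdict(v) if isinstance(v, TraitSpec) else v
                            for k, v in self.trait_specs.items()}
        d["pleasure_specs"] = [asdict(s) for s in self.pleasure_specs]
        d["tie_spec"] = asdict(self.tie_spec)
        return d


def _trait_spec_from(d: dict, default: TraitSpec) -> TraitSpec:
    return TraitSpec(
        mean=float(d.get("mean", default.mean)),
        sd=float(d.get("sd", default.sd)),
        lower=float(d.get("lower", default.lower)),
        upper=float(d.get("upper", default.upper)),
    )


def config_from_dict(raw: dict) -> SimulationConfig:
    """Build a config from a plain (YAML-loaded) mapping; missing keys default."""
    raw = dict(raw or {})
    trait_specs = {}
    for name, d in (raw.get("traits") or {}).items():
        key = "lam" if name == "lambda" else name
        if key not in DEFAULT_TRAIT_SPECS:
            raise ValueError(f"unknown trait {name!r}")
        trait_specs[key] = _trait_spec_from(d, DEFAULT_TRAIT_SPECS[key])

    emotions = raw.get("emotions") or {}
    props = tuple(emotions.get("proportions", (0.25, 0.25, 0.25, 0.25)))
    pos = _trait_spec_from(emotions.get("positive_pleasure", {}), POSITIVE_PLEASURE_SPEC)
    neg = _trait_spec_from(emotions.get("negative_pleasure", {}), NEGATIVE_PLEASURE_SPEC)

    network = raw.get("network") or {}
    kind = network.get("kind", "ba")
    net_params = {k: v for k, v in network.items() if k != "kind"}

    event = raw.get("event") or {}
    expression = raw.get("expression") or {}
    inter = raw.get("interaction") or {}
    engine = raw.get("engine") or {}

    return SimulationConfig(
        n_agents=int(raw.get("n_agents", 1000)),
        network_kind=kind,
        network_params=net_params,
        trait_specs=trait_specs,
        emotion_proportions=props,
        pleasure_specs=(pos, neg),
        tie_spec=_trait_spec_from(raw.get("tie_strength", {}), DEFAULT_TIE_SPEC),
        multinomial_types=bool(emotions.get("multinomial", False)),
        event=EventInfo(
            beta1=float(event.get("beta1", 0.9)), beta2=float(event.get("beta2", 0.5))
        ),
        expression=ExpressionParams(
            w_part=float(expression.get("w_part", 0.2)),
            w_full=float(expression.get("w_full", 0.4)),
            k1=float(expression.get("k1", 0.7)),
            k2=float(expression.get("k2", 1.0)),
        ),
        dw=DWParams(
            d1=float(inter.get("d1", 0.5)), theta1=float(inter.get("theta1", 0.5))
        ),
        sim=SimulationParams(
            p1=float(engine.get("p1", 0.5)),
            p2=float(engine.get("p2", 0.3)),
            t1=int(engine.get("t1", 30)),
            max_rounds=int(engine.get("max_rounds", 200)),
            steady_tol=float(engine.get("steady_tol", 1e-3)),
            steady_window=int(engine.get("steady_window", 3)),
            a=float(inter.get("a", 1.0)),
        ),
        seed=raw.get("seed"),
    )


def load_config(path) -> SimulationConfig:
    """Load a YAML configuration file."""
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def build_simulation(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[Population, SocialNetwork]:
    """Sample the population and generate the network described by ``config``."""
    pop = build_population(
        config.n_agents,
        trait_specs=config.trait_specs,
        type_proportions=config.emotion_proportions,
        pleasure_specs=config.pleasure_specs,
        rng=rng,
        multinomial=config.multinomial_types,
    )
    net = generate_network(
        config.network_kind,
        config.n_agents,
        config.network_params,
        rng=rng,
        tie_spec=config.tie_spec,
    )
    return pop, net


def run_from_config(config: SimulationConfig, seed: int | None = None) -> Trajectory:
    """One full two-stage run from a configuration (seed overrides config)."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    pop, net = build_simulation(config, rng)
    return run_simulation(
        pop, net, config.event, config.expression, config.dw, config.sim, rng
    )
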