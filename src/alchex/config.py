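"""YAML run configuration with schema validation.

Defaults mirror the study conditions used throughout: T0 = 300 K,
Tmax = 600 K, REST radius 0.5 nm, 200 bootstrap resamples, convergence
threshold 0.1 kcal/mol per time unit, 12 alchemical states for
charge-preserving mutations and 24 for charge-changing ones.  Unknown
keys are rejected.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FixtureConfig(_Strict):
    kind: str = "harmonic_ladder"   # harmonic_ladder | lj_mutation | double_well | insertion
    path: str | None = None         # load a fixture JSON instead of generating
    n_particles: int = 3
    k_old: float = 1.0
    k_new: float = 7.38905609893065
    cluster_size: int = 2
    delta_sigma: float = 0.03
    delta_epsilon: float = 0.0
    delta_charge: float = 0.0
    barrier: float = 4.5
    well_offset_coupling: float = 5.0
    counter_charge: float | None = None
    reverse: bool = False


class ProtocolConfig(_Strict):
    n_states: int | None = None     # default: 12, or 24 for charge mutations
    lambdas: list[float] | None = None


class AlchemicalConfig(_Strict):
    w_lifting: float = 0.4
    screening_alpha: float = 0.0
    cutoff: float | None = None


class RestConfig(_Strict):
    enabled: bool = False
    radius: float = 0.5
    tmax: float = 600.0
    inter_exponent: float = 0.5     # sqrt(alpha) on inter interactions


class SamplerConfig(_Strict):
    temperature: float = 300.0
    n_iterations: int = 500
    steps_per_iteration: int = 25
    dt: float | None = None         # None: stability pre-check chooses
    friction: float = 1.0
    store_positions: bool = False
    restrain_selection: str | None = None
    restraint_force_constant: float = 50.0   # kcal/mol/A^2


class EstimationConfig(_Strict):
    burn_in: float = 0.1
    n_bootstrap: int = 200
    n_time_points: int = 10


class DiagnosticsConfig(_Strict):
    threshold: float = 0.1
    window: float | None = None
    eigen_threshold: float = 0.995


class RunConfig(_Strict):
    fixture: FixtureConfig = Field(default_factory=FixtureConfig)
    method: str = "arex"            # arex | arest
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    alchemical: AlchemicalConfig = Field(default_factory=AlchemicalConfig)
    rest: RestConfig = Field(default_factory=RestConfig)
    sampler: SamplerConfig = Field(default_factory=SamplerConfig)
    estimation: EstimationConfig = Field(default_factory=EstimationConfig)
    diagnostics: DiagnosticsConfig = Field(default_factory=DiagnosticsConfig)
    seed: int = 0
    output_dir: str = "alchex_out"


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def build_fixture(cfg: FixtureConfig, seed: int, temperature: float):
    from . import systems
    if cfg.path is not None:
        pair = systems.load_pair(cfg.path)
    elif cfg.kind == "harmonic_ladder":
        pair = systems.make_harmonic_ladder(cfg.n_particles, cfg.k_old, cfg.k_new,
                                            temperature, seed)
    elif cfg.kind == "lj_mutation":
        pair = systems.make_lj_mutation(cfg.cluster_size, cfg.delta_sigma,
                                        cfg.delta_epsilon, cfg.delta_charge, seed)
        if cfg.counter_charge is not None:
            pair = systems.make_charge_change_mutation(pair, cfg.counter_charge)
    elif cfg.kind == "double_well":
        pair = systems.make_double_well_mutation(cfg.barrier, cfg.well_offset_coupling,
                                                 temperature, seed)
    elif cfg.kind == "insertion":
        pair = systems.make_insertion_mutation(cfg.cluster_size, seed)
    else:
        raise ValueError(f"unknown fixture kind {cfg.kind!r}")
    return pair.reversed() if cfg.reverse else pair


def default_n_states(pair) -> int:
    """12 states for charge-preserving, 24 for charge-changing mutations
    (counter-balanced pairs have zero net change but are still charge
    mutations, recorded in their metadata)."""
    is_charge = (pair.net_charge_change != 0
                 or pair.meta.get("kind") == "charge_change")
    return 24 if is_charge else 12


def write_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
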