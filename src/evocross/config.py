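"""Configuration containers for the simulator.

Every tunable of the model lives in one of the dataclasses below.  Defaults
reproduce the reference experimental conditions: batch-like ("periodic") or
chemostat-like ("continuous") resource dynamics on a toroidal grid, with the
primary resource being metabolite #10 supplied at 10.0 ACU per spot every 333
time-steps (periodic) or 0.03 ACU per spot per time-step (continuous).

Configs serialize to/from a flat ``key = value`` text dialect so that runs can
be driven from a plain parameter file.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any


@dataclass
class GenomeConfig:
    """Sampling ranges for the attributes of freshly generated genomic units."""

    kcat_min: float = 1e-3          # magnitude bounds of kcat, per centi-time-step
    kcat_max: float = 1e-1
    ratio_min: float = 1e-5         # bounds of kcat/KM
    ratio_max: float = 1e-3
    beta_min: float = 0.0
    beta_max: float = 1.0
    tag_init_min: int = 1           # initial sampling range for metabolite tags
    tag_init_max: int = 10
    allow_kcat_sign_flip: bool = False  # point mutation may not reverse a pump by default

    def __post_init__(self) -> None:
        if not (0 < self.kcat_min <= self.kcat_max):
            raise ValueError("kcat range must satisfy 0 < min <= max")
        if not (0 < self.ratio_min <= self.ratio_max):
            raise ValueError("kcat/KM range must satisfy 0 < min <= max")
        if self.tag_init_min < 1 or self.tag_init_max < self.tag_init_min:
            raise ValueError("tag range must satisfy 1 <= min <= max")


@dataclass
class MutationRates:
    """Per-replication mutation rates of the genome."""

    point_rate: float = 1e-3              # per attribute per replication
    transition_rate: float = 1e-3         # per unit per replication
    rearrangement_rate: float = 1e-3      # per unit per replication, per rearrangement type
    breakpoint_exchange_rate: float = 1e-3  # per attribute per breakpoint
    mutation_sd: float = 0.1              # sd of the normal increments (log10 / beta space)

    def __post_init__(self) -> None:
        for name in ("point_rate", "transition_rate", "rearrangement_rate",
                     "breakpoint_exchange_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @classmethod
    def zero(cls) -> "MutationRates":
        return cls(point_rate=0.0, transition_rate=0.0, rearrangement_rate=0.0,
                   breakpoint_exchange_rate=0.0)


@dataclass
class OdeConfig:
    """Numerical parameters of the per-organism kinetic system."""

    phi: float = 0.1            # protein degradation rate, per centi-time-step
    centi_steps: int = 100      # centi-time-steps integrated per ecological time-step
    rel_tol: float = 1e-6
    abs_tol: float = 1e-9
    initial_step: float = 0.1   # initial trial step, centi-time-steps
    conc_floor: float = 1e-6    # negativity beyond this magnitude is an integrator failure

    def __post_init__(self) -> None:
        if not 0.0 < self.phi <= 1.0:
            raise ValueError("phi must lie in (0, 1]")
        if self.centi_steps < 1:
            raise ValueError("centi_steps must be >= 1")


@dataclass
class EcologyConfig:
    """Grid-level ecological parameters."""

    width: int = 32
    height: int = 32
    D: float = 0.1                    # diffusion fraction to each of the 8 neighbours
    Dg: float = 0.0                   # external degradation fraction per time-step
    p_death: float = 0.02             # random death probability per organism per time-step
    poisson_death: bool = False       # if True use P(Poisson(p_death) >= 1) instead of p_death
    toxicity_threshold: float = 1.0   # ACU, lethal internal concentration
    min_division_score: float = 1e-3  # ACU, minimum score to compete for an empty spot
    migration_rate: float = 0.0       # fraction of spot pairs swapped per time-step
    well_mixed: bool = False          # if True, fully permute occupancy every step
    diffusion_before_divisions: bool = False  # sensitivity switch for the phase order

    def __post_init__(self) -> None:
        if 8.0 * self.D > 1.0 + 1e-12:
            raise ValueError("8*D must be <= 1 for the diffusion stencil to be stable")
        if not 0.0 <= self.Dg <= 1.0:
            raise ValueError("Dg must lie in [0, 1]")
        if not 0.0 <= self.p_death <= 1.0:
            raise ValueError("p_death must lie in [0, 1]")

    @property
    def n_spots(self) -> int:
        return self.width * self.height


@dataclass
class ProtocolConfig:
    """Environmental regime: batch-like, chemostat-like, or randomized batch."""

    variant: str = "periodic"       # periodic | continuous | random_periodic
    m_exo: int = 10                 # tag of the exogenously supplied primary resource
    f_in: float = 10.0              # ACU per spot at each periodic refresh
    delta_t: int = 333              # refresh period (mean, for random_periodic), time-steps
    delta_f_in: float = 0.03        # ACU per spot per time-step in the continuous regime
    Dg: float | None = None         # regime degradation; None -> 0 (periodic), 0.003 (continuous)
    random_interval_law: str = "poisson"  # poisson | exponential, for random_periodic

    def __post_init__(self) -> None:
        if self.variant not in ("periodic", "continuous", "random_periodic"):
            raise ValueError(f"unknown protocol variant {self.variant!r}")
        if self.delta_t < 1:
            raise ValueError("delta_t must be >= 1")
        if self.m_exo < 1:
            raise ValueError("m_exo must be a positive metabolite tag")

    @property
    def effective_Dg(self) -> float:
        if self.Dg is not None:
            return self.Dg
        return 0.003 if self.variant == "continuous" else 0.0


@dataclass
class SimulationConfig:
    """Bundle of every parameter set needed to run a world."""

    genome: GenomeConfig = field(default_factory=GenomeConfig)
    mutation: MutationRates = field(default_factory=MutationRates)
    ode: OdeConfig = field(default_factory=OdeConfig)
    ecology: EcologyConfig = field(default_factory=EcologyConfig)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    init_n_units: int = 50
    init_n_promoters: int = 10
    init_n_enzymes: int = 10
    flux_threshold: float = 1e-10   # ACU per time-step, activity bit threshold
    viability_fraction: float = 0.49  # viable-seeding threshold as a fraction of grid spots

    @property
    def viability_threshold(self) -> int:
        return math.ceil(self.viability_fraction * self.ecology.n_spots)

    # -- flat key=value (de)serialization ------------------------------------

    def to_flat(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for group in ("genome", "mutation", "ode", "ecology", "protocol"):
            sub = getattr(self, group)
            for f in dataclasses.fields(sub):
                out[f"{group}.{f.name}"] = getattr(sub, f.name)
        for f in dataclasses.fields(self):
            if f.name in ("genome", "mutation", "ode", "ecology", "protocol"):
                continue
            out[f.name] = getattr(self, f.name)
        return out

    def dumps(self) -> str:
        lines = [f"{k} = {v}" for k, v in sorted(self.to_flat().items())]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_flat(cls, flat: dict[str, Any]) -> "SimulationConfig":
        cfg = cls()
        for key, raw in flat.items():
            if "." in key:
                group, name = key.split(".", 1)
                sub = getattr(cfg, group)
            else:
                sub, name = cfg, key
            if not hasattr(sub, name):
                raise KeyError(f"unknown config key {key!r}")
            current = getattr(sub, name)
            setattr(sub, name, _coerce(raw, current))
        # re-validate
        for group in ("genome", "mutation", "ode", "ecology", "protocol"):
            sub = getattr(cfg, group)
            sub.__post_init__()
        return cfg

    @classmethod
    def loads(cls, text: str) -> "SimulationConfig":
        flat: dict[str, str] = {}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"cannot parse config line {line!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            flat[key] = value
        return cls.from_flat(flat)

    @classmethod
    def load(cls, path: str) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.loads(fh.read())


def _coerce(raw: Any, template: Any) -> Any:
    """Coerce a raw (possibly string) value to the type of the existing field."""
    if isinstance(raw, str):
        s = raw.strip()
        if template is None or isinstance(template, float):
            return None if s.lower() in ("none", "null", "") else float(s)
        if isinstance(template, bool):
            return s.lower() in ("1", "true", "yes", "on")
        if isinstance(template, int):
            return int(s)
        return s
    if template is None or isinstance(template, float):
        return None if raw is None else float(raw)
    return type(template)(raw) if not isinstance(raw, type(template)) else raw
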