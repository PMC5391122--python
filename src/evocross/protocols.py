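"""Environmental regimes and the viable-population seeding procedure.

Three resource dynamics are supported for the single primary resource
``m_exo`` (tag #10 by default):

* ``periodic`` — batch-like: every ``delta_t`` time-steps all external
  metabolites are removed and ``m_exo`` is set to ``f_in`` ACU in every spot
  (internal metabolites are untouched); no degradation within a cycle;
* ``continuous`` — chemostat-like: ``delta_f_in`` ACU of ``m_exo`` is added to
  every spot every time-step and external metabolites degrade at ``Dg``;
* ``random_periodic`` — as periodic, but the interval between resets is drawn
  from a Poisson law of mean ``delta_t`` (an exponential law is available).

Seeding fills the grid with independent random genomes, evolves the population
for 500 time-steps under the target protocol, and accepts it when at least a
fixed fraction of the grid (0.49, i.e. 500 organisms on the reference 32x32
grid) is still alive; the procedure repeats with fresh random populations
until acceptance or ``max_trials``.
"""

from __future__ import annotations

import numpy as np

from .config import ProtocolConfig, SimulationConfig
from .genome import random_genome
from .grid import World, step


class SeedingError(RuntimeError):
    """Raised when no viable population was found within max_trials."""

    def __init__(self, max_trials: int, best_survivors: int):
        super().__init__(
            f"no viable population in {max_trials} trials "
            f"(best trial kept {best_survivors} survivors)")
        self.best_survivors = best_survivors


def apply_protocol(world: World, protocol: ProtocolConfig | None = None,
                   rng: np.random.Generator | None = None) -> World:
    """Apply the regime's influx/refresh event for the current time-step."""
    protocol = protocol or world.config.protocol
    rng = rng or world.rng
    slot = protocol.m_exo - 1
    world.ensure_tag(protocol.m_exo)
    if protocol.variant == "periodic":
        if world.t % protocol.delta_t == 0:
            world.external[:, :, :] = 0.0
            world.external[:, :, slot] = protocol.f_in
    elif protocol.variant == "continuous":
        world.external[:, :, slot] += protocol.delta_f_in
    elif protocol.variant == "random_periodic":
        nxt = world.protocol_state.get("next_reset", world.t)
        if world.t >= nxt:
            world.external[:, :, :] = 0.0
            world.external[:, :, slot] = protocol.f_in
            if protocol.random_interval_law == "exponential":
                interval = max(1, int(round(rng.exponential(protocol.delta_t))))
            else:
                interval = max(1, int(rng.poisson(protocol.delta_t)))
            world.protocol_state["next_reset"] = world.t + interval
    return world


def initialize_world(config: SimulationConfig,
                     seed: int | np.random.SeedSequence) -> World:
    """Create an empty world with the regime's initial external field.

    All external concentrations start at 0 except the primary resource.  In
    the periodic regimes the t=0 refresh provides it; the continuous regime
    starts at its steady-state concentration ``delta_f_in / Dg``.
    """
    world = World(config, seed=seed)
    if config.protocol.variant == "continuous":
        dg = config.protocol.effective_Dg
        level = config.protocol.delta_f_in / dg if dg > 0 else config.protocol.f_in
        world.external[:, :, config.protocol.m_exo - 1] = level
    return world


def fill_random(world: World) -> World:
    """Fill every spot with an organism carrying an independent random genome."""
    cfg = world.config
    for pos in world.positions():
        g = random_genome(world.rng, cfg.init_n_units, cfg.init_n_promoters,
                          cfg.init_n_enzymes, cfg.genome)
        world.add_organism(g, pos)
    return world


def seed_viable_population(config: SimulationConfig,
                           seed: int | np.random.SeedSequence,
                           max_trials: int = 300,
                           n_burnin_steps: int = 500) -> tuple[World, int]:
    """Search for a viable founder population under the target protocol.

    Each trial fills the grid with fresh random genomes, evolves it for
    ``n_burnin_steps`` and accepts when the survivor count reaches the
    viability threshold (0.49 of the grid).  Returns ``(world, trial_index)``.
    """
    if max_trials < 1:
        raise ValueError("max_trials must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    threshold = config.viability_threshold
    best = 0
    for trial in range(max_trials):
        sub = ss.spawn(1)[0]
        world = initialize_world(config, sub)
        fill_random(world)
        for _ in range(n_burnin_steps):
            step(world, record=False)
            if not world.grid:
                break
        survivors = world.population_size()
        best = max(best, survivors)
        if survivors >= threshold:
            world.phylo.prune()
            return world, trial
    raise SeedingError(max_trials, best)
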