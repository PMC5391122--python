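"""Deterministic hand-built genomes and worlds.

These are engineered strains, constructed (not evolved) so that their kinetics
are analytically predictable; they are used by the test-suite and the
command-line ``fixture`` command.

* ``two_gene_genome`` — the minimal importer/converter: one pump bringing
  metabolite #10 into the cell and one enzyme converting #10 to #7 (the
  classic five-equation system).
* ``steady_strain_genome`` — a slow metabolizer of the primary resource that
  holds a stable, sub-toxic score over a whole batch cycle: weak uptake of
  #10, conversion to the essential metabolites #7 and #3, and fast venting of
  both.  Useful for demographic calibration (its deaths are purely random).
* ``seasonal_a_genome`` / ``seasonal_b_genome`` — a cross-feeding pair for
  competition assays.  A consumes #10 quickly (depleting it within the first
  part of a cycle), stores #7/#3 and vents them as by-products; its score
  collapses once the resource is exhausted.  B ignores #10, feeds on the
  released #7, converts part of it to #5 and vents #5; its score peaks in the
  by-product season.
"""

from __future__ import annotations

import numpy as np

from .config import SimulationConfig
from .genome import Genome, GenomicUnit
from .grid import World
from .protocols import initialize_world


def _P(beta: float) -> GenomicUnit:
    return GenomicUnit("P", beta, 1, 1, 0.01, 1e-4)


def _enzyme(s: int, p: int, kcat: float, ratio: float) -> GenomicUnit:
    return GenomicUnit("E", 0.0, s, p, kcat, ratio)


def _pump(tag: int, kcat: float, ratio: float) -> GenomicUnit:
    # s == p marks a pump; kcat > 0 imports, kcat < 0 exports
    return GenomicUnit("E", 0.0, tag, tag, kcat, ratio)


def _NC() -> GenomicUnit:
    return GenomicUnit("NC", 0.0, 1, 1, 0.01, 1e-4)


def two_gene_genome(beta_pump: float = 0.08, beta_enzyme: float = 0.08) -> Genome:
    """One importer of #10 and one enzyme #10 -> #7, each in its own region."""
    return Genome.from_units([
        _P(beta_pump), _pump(10, 0.01, 1e-4),
        _NC(),
        _P(beta_enzyme), _enzyme(10, 7, 0.05, 1e-3),
        _NC(),
    ])


def steady_strain_genome() -> Genome:
    """Slow importer of #10 with fast conversion and venting; score ~0.05 ACU.

    Uptake is weak enough that the primary resource outlasts a 333-step cycle,
    so the score never collapses and internal pools stay far below the 1.0 ACU
    toxicity threshold.
    """
    return Genome.from_units([
        _P(0.5),
        _pump(10, 0.001, 1e-5),        # import #10: ~0.045 ACU/time-step at 10 ACU
        _enzyme(10, 7, 0.1, 1e-3),     # fast conversion keeps [#10] low
        _enzyme(10, 3, 0.1, 1e-3),
        _pump(7, -0.1, 1e-3),          # vent both essentials quickly
        _pump(3, -0.1, 1e-3),
        _NC(),
    ])


def seasonal_a_genome() -> Genome:
    """Primary-resource specialist: fast uptake of #10, by-product release.

    The fast #7/#3 paths give a high score while the resource lasts and leak
    by-products; the slow #5 side path decays over ~200 steps, keeping the
    strain above the division threshold through the famine season without
    accumulating to toxicity.
    """
    return Genome.from_units([
        _P(0.5),
        _pump(10, 0.01, 1e-4),         # ~0.05*[ext] ACU/time-step uptake
        _enzyme(10, 7, 0.1, 1e-3),
        _enzyme(10, 3, 0.1, 1e-3),
        _pump(7, -0.1, 1e-3),          # fast vents: feast score, famine decay
        _pump(3, -0.1, 1e-3),
        _enzyme(10, 5, 0.004, 4e-5),   # slow persistent-stock path
        _pump(5, -0.004, 4e-5),
        _NC(),
    ])


def seasonal_b_genome() -> Genome:
    """By-product specialist: feeds on released #7, never touches #10."""
    return Genome.from_units([
        _P(0.1),
        _pump(7, 0.001, 1e-5),         # slow uptake of the by-product
        _NC(),
        _P(0.5),
        _enzyme(7, 5, 0.02, 2e-4),     # moderate conversion of the food stock
        _pump(5, -0.1, 1e-3),          # vent the end product
        _NC(),
    ])


def clonal_world(genome: Genome, config: SimulationConfig,
                 seed: int | np.random.SeedSequence = 0,
                 initial_internal: dict[int, float] | None = None) -> World:
    """A world saturated with copies of one genome (proteins at beta/phi)."""
    world = initialize_world(config, seed)
    for pos in world.positions():
        org = world.add_organism(genome.copy(), pos)
        if initial_internal is not None:
            for tag, conc in initial_internal.items():
                world.ensure_tag(tag)
                org.internal[tag - 1] = conc
    return world


def ab_world(config: SimulationConfig, freq_b: float = 0.5,
             seed: int | np.random.SeedSequence = 0) -> World:
    """A world of the seasonal cross-feeding pair at a given B frequency.

    Founders carry a small internal stock of their score metabolite so that
    both ecotypes can compete from the first time-step of a fresh cycle.
    """
    if not 0.0 < freq_b < 1.0:
        raise ValueError("freq_b must lie strictly between 0 and 1")
    world = initialize_world(config, seed)
    ga, gb = seasonal_a_genome(), seasonal_b_genome()
    for pos in world.positions():
        if world.rng.random() < freq_b:
            org = world.add_organism(gb.copy(), pos, lineage_tag="B")
            org.internal[7 - 1] = 0.3
        else:
            org = world.add_organism(ga.copy(), pos, lineage_tag="A")
            org.internal[5 - 1] = 0.4
    return world


def diffusion_test_world(config: SimulationConfig | None = None) -> World:
    """Empty 3x3 world with 1.0 ACU of metabolite #1 at the center spot."""
    config = config or SimulationConfig()
    config.ecology.width = 3
    config.ecology.height = 3
    world = World(config, seed=0)
    world.external[1, 1, 0] = 1.0
    return world
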