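"""Toroidal world: occupancy, external metabolite fields, and the time-step.

Each spot of the torus holds at most one organism and a vector of external
metabolite concentrations.  One ecological time-step executes, in order:

1. protocol influx/refresh events (see :mod:`evocross.protocols`);
2. per-organism kinetic integration over 100 centi-time-steps (spot-local
   external concentrations are part of each organism's system);
3. score update and trophic-profile recording;
4. deaths (lethal internal toxicity, plus random death at ``p_death``); the
   dead cell's internal metabolites are released into its spot;
5. divisions: for every empty spot, the best-scoring eligible Moore neighbour
   divides; daughters inherit half of each metabolite and protein amount and
   one independently mutated replicate of the parental genome each;
6. optional migration mixing;
7. metabolite diffusion to the 8 neighbours;  8. external degradation.

A (seed, config) pair fully determines the trajectory: all randomness flows
from two named generator streams (``rng`` for mutational/death draws,
``rng_tiebreak`` for spot ordering and score ties).
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import analysis
from .analysis import PhyloTree, classify_group, trophic_profile
from .config import MutationRates, SimulationConfig
from .genome import Genome, replicate
from .metabolism import (CellState, IntegrationError, OdeSystem, build_ode,
                         express, score, toxicity_exceeded)

MOORE = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


class Organism:
    """One occupant of a grid spot."""

    __slots__ = ("id", "parent_id", "birth_step", "generation", "genome",
                 "proteins", "ode", "protein_conc", "internal", "current_score",
                 "divided_this_step", "lineage_tag", "profile", "group",
                 "last_fluxes")

    def __init__(self, org_id: int, genome: Genome, birth_step: int,
                 parent_id: int | None = None, generation: int = 0,
                 lineage_tag: str | None = None):
        self.id = org_id
        self.parent_id = parent_id
        self.birth_step = birth_step
        self.generation = generation
        self.genome = genome
        self.proteins = express(genome)
        self.ode: OdeSystem | None = None
        self.protein_conc = np.zeros(len(self.proteins))
        self.internal = np.zeros(0)
        self.current_score = 0.0
        self.divided_this_step = False
        self.lineage_tag = lineage_tag
        self.profile = None
        self.group = None
        self.last_fluxes: CellState | None = None

    def max_expressed_tag(self) -> int:
        if not self.proteins:
            return 0
        return max(max(sp.s, sp.p) for sp in self.proteins)

    def cell_state(self, external_local: np.ndarray) -> CellState:
        return CellState(proteins=self.protein_conc.copy(),
                         internal=self.internal.copy(),
                         external_local=external_local)


class World:
    """The toroidal grid, its external fields, and the global clock."""

    def __init__(self, config: SimulationConfig, seed: int | np.random.SeedSequence = 0):
        self.config = config
        eco = config.ecology
        self.height = eco.height
        self.width = eco.width
        self.max_tag = max(config.protocol.m_exo, config.genome.tag_init_max)
        self.external = np.zeros((self.height, self.width, self.max_tag))
        self.grid: dict[tuple[int, int], Organism] = {}
        self.t = 0
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        s_main, s_tie = ss.spawn(2)
        self.rng = np.random.Generator(np.random.PCG64(s_main))
        self.rng_tiebreak = np.random.Generator(np.random.PCG64(s_tie))
        self.next_id = 0
        self.phylo = PhyloTree()
        self.protocol_state: dict = {}
        self.history: list[dict] = []
        self.division_count = 0
        self.death_count = 0

    # -- bookkeeping -----------------------------------------------------------

    @property
    def n_spots(self) -> int:
        return self.height * self.width

    def organisms(self) -> list[Organism]:
        return [self.grid[pos] for pos in sorted(self.grid)]

    def positions(self) -> Iterator[tuple[int, int]]:
        for r in range(self.height):
            for c in range(self.width):
                yield (r, c)

    def population_size(self) -> int:
        return len(self.grid)

    def ensure_tag(self, tag: int) -> None:
        """Grow the metabolite tag universe to include ``tag``."""
        if tag <= self.max_tag:
            return
        extra = tag - self.max_tag
        self.external = np.concatenate(
            [self.external, np.zeros((self.height, self.width, extra))], axis=2)
        for org in self.grid.values():
            org.internal = np.concatenate([org.internal, np.zeros(extra)])
        self.max_tag = tag

    def new_id(self) -> int:
        i = self.next_id
        self.next_id += 1
        return i

    def add_organism(self, genome: Genome, pos: tuple[int, int],
                     parent_id: int | None = None, generation: int = 0,
                     lineage_tag: str | None = None, founder: bool = True,
                     at_equilibrium: bool = True) -> Organism:
        """Place a new organism; proteins start at beta/phi, metabolites at 0."""
        if pos in self.grid:
            raise ValueError(f"spot {pos} already occupied")
        org = Organism(self.new_id(), genome, self.t, parent_id, generation,
                       lineage_tag)
        self.ensure_tag(org.max_expressed_tag())
        org.internal = np.zeros(self.max_tag)
        if at_equilibrium:
            org.protein_conc = np.asarray([sp.beta for sp in org.proteins]) \
                / self.config.ode.phi if org.proteins else np.zeros(0)
        org.ode = OdeSystem(org.proteins, max_tag=self.max_tag, config=self.config.ode)
        self.grid[pos] = org
        if founder:
            self.phylo.add_root(org.id, self.t)
        return org

    def find(self, org_id: int) -> tuple[tuple[int, int], Organism] | None:
        for pos, org in self.grid.items():
            if org.id == org_id:
                return pos, org
        return None

    def neighbors(self, pos: tuple[int, int]) -> list[tuple[int, int]]:
        r, c = pos
        return [((r + dr) % self.height, (c + dc) % self.width) for dr, dc in MOORE]

    def total_mass(self, include_internal: bool = True) -> float:
        """Total metabolite amount over the whole system (all tags)."""
        total = float(self.external.sum())
        if include_internal:
            total += float(sum(org.internal.sum() for org in self.grid.values()))
        return total

    def per_tag_mass(self) -> np.ndarray:
        total = self.external.sum(axis=(0, 1))
        for org in self.grid.values():
            total = total + org.internal
        return total

    def system_max_tag(self) -> int:
        """Largest tag present in the system: nonzero concentration anywhere,
        or referenced by an expressed protein of a living organism."""
        floor = 1e-300
        present = np.flatnonzero(self.external.sum(axis=(0, 1)) > floor)
        best = int(present[-1]) + 1 if present.size else 0
        for org in self.grid.values():
            nz = np.flatnonzero(org.internal > floor)
            if nz.size:
                best = max(best, int(nz[-1]) + 1)
            best = max(best, org.max_expressed_tag())
        return max(best, 1)


# -- field operators --------------------------------------------------------------


def diffuse(world: World) -> World:
    """Simultaneous 8-neighbour diffusion; mass is conserved exactly."""
    D = world.config.ecology.D
    if D == 0.0 or world.external.size == 0:
        return world
    f = world.external
    acc = (1.0 - 8.0 * D) * f
    for dr, dc in MOORE:
        acc = acc + D * np.roll(np.roll(f, dr, axis=0), dc, axis=1)
    world.external = acc
    return world


def degrade(world: World, Dg: float | None = None) -> World:
    """Multiply every external concentration by (1 - Dg)."""
    if Dg is None:
        Dg = world.config.ecology.Dg
    if Dg:
        world.external *= (1.0 - Dg)
    return world


# -- demography --------------------------------------------------------------------


def apply_deaths(world: World, rng: np.random.Generator | None = None) -> World:
    """Toxicity deaths plus random deaths; content is released locally."""
    rng = rng or world.rng
    eco = world.config.ecology
    p = eco.p_death
    if eco.poisson_death:
        p = 1.0 - math.exp(-eco.p_death)
    for pos in sorted(world.grid):
        org = world.grid[pos]
        u = rng.random()
        toxic = bool(np.any(org.internal >= eco.toxicity_threshold))
        if toxic or u < p:
            world.external[pos[0], pos[1], :] += org.internal
            del world.grid[pos]
            world.phylo.record_death(org.id, world.t)
            world.death_count += 1
    return world


def _divide(world: World, parent_pos: tuple[int, int], empty_pos: tuple[int, int],
            rates: MutationRates) -> None:
    parent = world.grid[parent_pos]
    g1 = replicate(parent.genome, world.rng, rates, world.config.genome)
    g2 = replicate(parent.genome, world.rng, rates, world.config.genome)
    d1 = Organism(world.new_id(), g1, world.t, parent.id, parent.generation + 1,
                  parent.lineage_tag)
    d2 = Organism(world.new_id(), g2, world.t, parent.id, parent.generation + 1,
                  parent.lineage_tag)
    world.ensure_tag(max(d1.max_expressed_tag(), d2.max_expressed_tag()))
    # half of each metabolite amount
    half = parent.internal / 2.0
    # half of each protein amount, matched by species attribute tuple
    pool: dict[tuple, list[float]] = {}
    for sp, conc in zip(parent.proteins, parent.protein_conc):
        pool.setdefault(sp.signature(), []).append(conc / 2.0)
    for d in (d1, d2):
        d.internal = half.copy()
        taken: dict[tuple, int] = {}
        conc = np.zeros(len(d.proteins))
        for j, sp in enumerate(d.proteins):
            sig = sp.signature()
            k = taken.get(sig, 0)
            vals = pool.get(sig)
            if vals is not None and k < len(vals):
                conc[j] = vals[k]
                taken[sig] = k + 1
        d.protein_conc = conc
        d.ode = OdeSystem(d.proteins, max_tag=world.max_tag, config=world.config.ode)
        d.current_score = score(CellState(conc, d.internal, d.internal * 0.0))
        d.divided_this_step = True
    world.phylo.record_division(parent.id, d1.id, d2.id, world.t)
    del world.grid[parent_pos]
    world.grid[parent_pos] = d1
    world.grid[empty_pos] = d2
    world.division_count += 1


def resolve_divisions(world: World, rng: np.random.Generator | None = None,
                      mutation_rates: MutationRates | None = None) -> World:
    """Fill empty spots with daughters of the best-scoring eligible neighbour."""
    tie = rng or world.rng_tiebreak
    rates = mutation_rates if mutation_rates is not None else world.config.mutation
    min_score = world.config.ecology.min_division_score
    empties = [pos for pos in world.positions() if pos not in world.grid]
    if not empties:
        return world
    order = tie.permutation(len(empties))
    for k in order:
        pos = empties[k]
        if pos in world.grid:  # filled by an earlier division this phase
            continue
        candidates = []
        for npos in world.neighbors(pos):
            org = world.grid.get(npos)
            if org is None or org.divided_this_step:
                continue
            if org.current_score >= min_score:
                candidates.append((npos, org))
        if not candidates:
            continue
        best = max(org.current_score for _, org in candidates)
        top = [npos for npos, org in candidates if org.current_score == best]
        choice = top[int(tie.integers(0, len(top)))] if len(top) > 1 else top[0]
        _divide(world, choice, pos, rates)
    return world


def mix_population(world: World, rng: np.random.Generator | None = None) -> World:
    """Swap occupants (including emptiness) of random spot pairs."""
    rng = rng or world.rng
    eco = world.config.ecology
    if eco.well_mixed:
        spots = list(world.positions())
        occupants = [world.grid.pop(p, None) for p in spots]
        perm = rng.permutation(len(spots))
        for p, k in zip(spots, perm):
            if occupants[k] is not None:
                world.grid[p] = occupants[k]
        return world
    rate = eco.migration_rate
    if rate <= 0.0:
        return world
    n = world.n_spots
    n_pairs = n * (n - 1) // 2
    k = rng.binomial(n_pairs, rate)
    spots = list(world.positions())
    for _ in range(k):
        i = int(rng.integers(0, n))
        j = int(rng.integers(0, n - 1))
        if j >= i:
            j += 1
        a, b = spots[i], spots[j]
        oa, ob = world.grid.pop(a, None), world.grid.pop(b, None)
        if oa is not None:
            world.grid[b] = oa
        if ob is not None:
            world.grid[a] = ob
    return world


# -- the full time-step -------------------------------------------------------------


def integrate_population(world: World) -> World:
    """Phase 2-3: per-organism kinetics, score update, profile recording."""
    cfg = world.config
    sys_max_tag = None
    for pos in sorted(world.grid):
        org = world.grid[pos]
        r, c = pos
        cell = org.cell_state(world.external[r, c, :].copy())
        try:
            new_cell = org.ode.integrate(cell, organism_id=org.id)
        except IntegrationError:
            raise
        org.protein_conc = new_cell.proteins
        org.internal = new_cell.internal
        world.external[r, c, :] = new_cell.external_local
        org.last_fluxes = new_cell
        org.current_score = score(new_cell)
    # profiles use the largest tag present in the system at time t
    if world.grid:
        sys_max_tag = world.system_max_tag()
        for org in world.grid.values():
            org.profile = trophic_profile(org.last_fluxes, sys_max_tag,
                                          cfg.flux_threshold)
            org.group = classify_group(org.profile, cfg.protocol.m_exo)
    return world


def record_history(world: World) -> None:
    scores = [org.current_score for org in world.grid.values()]
    groups = [org.group for org in world.grid.values()]
    profiles = {org.profile.text() for org in world.grid.values()
                if org.profile is not None}
    richness = int(np.sum(world.external.sum(axis=(0, 1)) > 1e-10))
    world.history.append({
        "t": world.t,
        "population": len(world.grid),
        "mean_score": float(np.mean(scores)) if scores else 0.0,
        "max_score": float(np.max(scores)) if scores else 0.0,
        "environmental_richness": richness,
        "group_A": sum(1 for g in groups if g == analysis.GROUP_A),
        "group_B": sum(1 for g in groups if g == analysis.GROUP_B),
        "n_profiles": len(profiles),
        "divisions": world.division_count,
        "deaths": world.death_count,
    })


def step(world: World, protocol=None, mutation_rates: MutationRates | None = None,
         record: bool = True) -> World:
    """Advance the world by one full ecological time-step."""
    from .protocols import apply_protocol  # local import to avoid a cycle

    eco = world.config.ecology
    if protocol is None:
        protocol = world.config.protocol
    apply_protocol(world, protocol, world.rng)
    integrate_population(world)
    apply_deaths(world)
    if eco.diffusion_before_divisions:
        diffuse(world)
        resolve_divisions(world, mutation_rates=mutation_rates)
        mix_population(world)
    else:
        resolve_divisions(world, mutation_rates=mutation_rates)
        mix_population(world)
        diffuse(world)
    degrade(world, protocol.effective_Dg)
    if record:
        record_history(world)
    world.t += 1
    for org in world.grid.values():
        org.divided_this_step = False
    return world


def run(world: World, n_steps: int, protocol=None,
        mutation_rates: MutationRates | None = None, record: bool = True) -> World:
    for _ in range(n_steps):
        step(world, protocol=protocol, mutation_rates=mutation_rates, record=record)
    return world
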