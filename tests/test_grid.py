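"""World mechanics: diffusion, degradation, deaths, divisions, full steps."""

import numpy as np
import pytest
from scipy.signal import convolve2d

from evocross import SimulationConfig
from evocross.config import MutationRates
from evocross.fixtures import (diffusion_test_world, steady_strain_genome,
                               clonal_world, two_gene_genome)
from evocross.genome import random_genome
from evocross.grid import (World, apply_deaths, degrade, diffuse,
                           mix_population, resolve_divisions, step)


def empty_world(w=8, h=8, **eco):
    cfg = SimulationConfig()
    cfg.ecology.width, cfg.ecology.height = w, h
    for k, v in eco.items():
        setattr(cfg.ecology, k, v)
    return World(cfg, seed=0)


# -- diffusion -----------------------------------------------------------------


def test_diffusion_three_by_three_point_source():
    world = diffusion_test_world()
    diffuse(world)
    field = world.external[:, :, 0]
    assert field[1, 1] == pytest.approx(0.2)
    off = field[np.arange(3) != 1][:, :]  # everything except the center row
    assert np.allclose(np.delete(field.ravel(), 4), 0.1)
    assert field.sum() == pytest.approx(1.0, rel=1e-14)


def test_diffusion_uniform_field_is_stationary():
    world = empty_world(5, 5)
    world.external[:, :, :] = 0.37
    diffuse(world)
    assert np.allclose(world.external, 0.37)


def test_diffusion_conserves_mass_and_smooths(rng):
    world = empty_world(8, 8)
    world.external[:, :, :3] = rng.uniform(0, 5, (8, 8, 3))
    totals0 = world.external.sum(axis=(0, 1))
    variances = [world.external[:, :, 0].var()]
    kernel = np.full((3, 3), 0.1)
    kernel[1, 1] = 1 - 8 * 0.1
    expected = world.external[:, :, 0].copy()
    for _ in range(50):
        diffuse(world)
        expected = convolve2d(expected, kernel, mode="same", boundary="wrap")
        variances.append(world.external[:, :, 0].var())
    totals = world.external.sum(axis=(0, 1))
    assert np.allclose(totals, totals0, rtol=1e-12)
    # convolution oracle
    assert np.allclose(world.external[:, :, 0], expected, atol=1e-12)
    # field converges toward uniform
    assert all(b <= a + 1e-15 for a, b in zip(variances, variances[1:]))
    assert variances[-1] < variances[0] / 10


# -- degradation ----------------------------------------------------------------


def test_degrade_fraction():
    world = empty_world(3, 3)
    world.external[:, :, 0] = 1.0
    degrade(world, 0.003)
    assert np.allclose(world.external[:, :, 0], 0.997)
    degrade(world, 0.0)
    assert np.allclose(world.external[:, :, 0], 0.997)


def test_degrade_geometric_decay():
    world = empty_world(2, 2)
    world.external[:, :, 1] = 2.0
    total0 = world.external.sum()
    for _ in range(10):
        degrade(world, 0.01)
    assert world.external.sum() == pytest.approx(total0 * 0.99 ** 10)


# -- deaths --------------------------------------------------------------------


def test_toxic_organism_dies_and_releases(rng):
    world = empty_world(3, 3, p_death=0.0)
    org = world.add_organism(random_genome(world.rng, 5, 0, 0), (1, 1))
    org.internal[7 - 1] = 1.2
    before = world.external[1, 1, 6]
    apply_deaths(world)
    assert (1, 1) not in world.grid
    assert world.external[1, 1, 6] == pytest.approx(before + 1.2)


def test_no_deaths_when_rate_zero(rng):
    world = empty_world(4, 4, p_death=0.0)
    for pos in world.positions():
        world.add_organism(random_genome(world.rng, 5, 0, 0), pos)
    apply_deaths(world)
    assert world.population_size() == 16


def test_random_death_rate_recovery():
    """Death frequency over many organism-steps within 3 sigma of p_death."""
    world = empty_world(16, 16, p_death=0.02)
    total_steps = deaths = 0
    for _ in range(40):
        for pos in list(world.positions()):
            if pos not in world.grid:
                world.add_organism(random_genome(world.rng, 3, 0, 0), pos,
                                   founder=True)
        n0 = world.population_size()
        apply_deaths(world)
        total_steps += n0
        deaths += n0 - world.population_size()
    expected = total_steps * 0.02
    sigma = np.sqrt(total_steps * 0.02 * 0.98)
    assert abs(deaths - expected) <= 3 * sigma


# -- divisions ------------------------------------------------------------------


def make_scored_world(scores, empty_pos=(1, 1)):
    """3x3 world, all spots but one filled, organisms given fixed scores."""
    world = empty_world(3, 3, p_death=0.0)
    it = iter(scores)
    for pos in world.positions():
        if pos == empty_pos:
            continue
        org = world.add_organism(steady_strain_genome(), pos)
        org.current_score = next(it)
    return world


def test_best_scorer_divides(zero_rates):
    world = make_scored_world([0.5, 0.2] + [0.0] * 6)
    resolve_divisions(world, mutation_rates=zero_rates)
    assert (1, 1) in world.grid
    winner_children = [o for o in world.grid.values() if o.divided_this_step]
    assert len(winner_children) == 2
    assert all(o.parent_id == 0 for o in winner_children)  # the 0.5 organism


def test_min_division_score_enforced(zero_rates):
    world = make_scored_world([5e-4] * 8)
    resolve_divisions(world, mutation_rates=zero_rates)
    assert (1, 1) not in world.grid


def test_division_halves_content_exactly(zero_rates):
    world = make_scored_world([0.5] + [0.0] * 7)
    parent = world.grid[(0, 0)]
    parent.internal[6] = 0.4
    parent.protein_conc[:] = 0.6
    internal_total = parent.internal.copy()
    protein_total = parent.protein_conc.copy()
    resolve_divisions(world, mutation_rates=zero_rates)
    daughters = [o for o in world.grid.values() if o.divided_this_step]
    assert len(daughters) == 2
    assert np.array_equal(daughters[0].internal, daughters[1].internal)
    assert np.array_equal(daughters[0].internal + daughters[1].internal,
                          internal_total)
    assert np.array_equal(daughters[0].protein_conc + daughters[1].protein_conc,
                          protein_total)
    assert daughters[0].genome == parent.genome  # zero-rate replication


def test_at_most_two_daughters_per_step(zero_rates):
    # two empty spots adjacent to one dominant organism: it divides once only
    world = empty_world(3, 3, p_death=0.0)
    org = world.add_organism(steady_strain_genome(), (0, 0))
    org.current_score = 1.0
    filler = world.add_organism(steady_strain_genome(), (2, 2))
    filler.current_score = 0.01
    resolve_divisions(world, mutation_rates=zero_rates)
    kids = [o for o in world.grid.values() if o.parent_id == org.id]
    assert len(kids) == 2  # one division -> two daughters, then blocked


# -- migration ------------------------------------------------------------------


def test_mix_population_preserves_organisms(rng):
    world = empty_world(4, 4, migration_rate=0.3)
    ids = set()
    for k, pos in enumerate(world.positions()):
        if k % 2 == 0:
            ids.add(world.add_organism(random_genome(world.rng, 4, 0, 0), pos).id)
    mix_population(world)
    assert {o.id for o in world.grid.values()} == ids


def test_well_mixed_permutation(rng):
    world = empty_world(4, 4, well_mixed=True)
    for pos in world.positions():
        world.add_organism(random_genome(world.rng, 4, 0, 0), pos)
    before = {o.id for o in world.grid.values()}
    mix_population(world)
    assert {o.id for o in world.grid.values()} == before
    assert world.population_size() == 16


def test_migration_rate_zero_is_identity(rng):
    world = empty_world(4, 4, migration_rate=0.0)
    org = world.add_organism(random_genome(world.rng, 4, 0, 0), (2, 3))
    mix_population(world)
    assert world.grid[(2, 3)] is org


# -- full step -------------------------------------------------------------------


def closed_config(w=6, h=6):
    """Config with no protocol influx and no degradation: a closed system."""
    cfg = SimulationConfig()
    cfg.ecology.width, cfg.ecology.height = w, h
    cfg.protocol.variant = "continuous"
    cfg.protocol.delta_f_in = 0.0
    cfg.protocol.Dg = 0.0
    return cfg


def test_empty_world_step_only_updates_fields():
    cfg = closed_config(4, 4)
    world = World(cfg, seed=0)
    world.external[0, 0, 0] = 1.0
    step(world)
    assert world.t == 1 and world.population_size() == 0
    assert world.external.sum() == pytest.approx(1.0, rel=1e-12)


def test_step_conserves_mass_closed_system():
    """One nonviable organism, no influx, Dg=0: per-metabolite mass constant."""
    cfg = closed_config(4, 4)
    world = World(cfg, seed=2)
    org = world.add_organism(two_gene_genome(), (1, 1))
    org.internal[9] = 0.3
    world.external[:, :, 9] = 1.0
    per_tag0 = world.per_tag_mass().copy()
    total0 = per_tag0.sum()
    for _ in range(10):
        step(world)
    per_tag = world.per_tag_mass()
    assert per_tag.sum() == pytest.approx(total0, rel=1e-9)
    # tags not touched by any reaction unchanged exactly
    untouched = [i for i in range(world.max_tag) if i not in (6, 9)]
    assert np.allclose(per_tag[untouched], per_tag0[untouched], rtol=1e-12)


def test_step_determinism(small_config):
    runs = []
    for _ in range(2):
        world = clonal_world(steady_strain_genome(), small_config, seed=7)
        for _ in range(30):
            step(world)
        runs.append(world)
    a, b = runs
    assert np.array_equal(a.external, b.external)
    assert sorted(o.id for o in a.grid.values()) == sorted(o.id for o in b.grid.values())
    for pos in a.grid:
        assert np.array_equal(a.grid[pos].internal, b.grid[pos].internal)
        assert a.grid[pos].genome == b.grid[pos].genome


def test_occupancy_and_flags_after_step(small_config):
    world = clonal_world(steady_strain_genome(), small_config, seed=9)
    for _ in range(5):
        step(world)
    assert world.population_size() <= world.n_spots
    assert all(not o.divided_this_step for o in world.grid.values())
    # group counts partition the population
    h = world.history[-1]
    unclassified = h["population"] - h["group_A"] - h["group_B"]
    assert unclassified >= 0
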