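"""Experiment drivers: campaigns, competition assays, transfers, backups.

* :func:`run_campaign` — independent repetitions of viable seeding followed by
  long-term evolution under one resource regime, with periodic world snapshots
  and a per-step summary table.
* :func:`run_competition` — short-term competition assays: a grid seeded from
  two strain pools at a chosen initial B frequency, propagated for a number of
  batch cycles, reporting per-step lineage counts and per-cycle log-fitness of
  B (mutation can be disabled for pure ecological assays).
* :func:`run_transfer` — stability assays: an evolved two-ecotype population is
  propagated under another regime; the polymorphism counts as lost at the
  first step where one of the two founder MRCA subtrees has no living
  descendant.
* :func:`save_backup` / :func:`load_backup` — lossless, versioned world
  serialization (JSON text), including RNG streams, so that load-and-continue
  reproduces an uninterrupted run bit for bit.
"""

from __future__ import annotations

import copy
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import TrophicProfile, log_fitness, PhyloTree, newick_export
from .config import MutationRates, SimulationConfig
from .genome import Genome
from .grid import Organism, World, step
from .protocols import SeedingError, initialize_world, seed_viable_population

BACKUP_VERSION = 1


# -- world serialization -----------------------------------------------------------


class BackupError(RuntimeError):
    pass


def world_to_dict(world: World) -> dict:
    organisms = []
    for pos in sorted(world.grid):
        org = world.grid[pos]
        organisms.append({
            "pos": list(pos),
            "id": org.id,
            "parent_id": org.parent_id,
            "birth_step": org.birth_step,
            "generation": org.generation,
            "lineage_tag": org.lineage_tag,
            "genome": org.genome.to_dict(),
            "protein_conc": org.protein_conc.tolist(),
            "internal": org.internal.tolist(),
            "current_score": float(org.current_score),
            "divided_this_step": bool(org.divided_this_step),
            "group": org.group,
            "profile": ([org.profile.uptake, org.profile.production,
                         org.profile.release] if org.profile is not None else None),
        })
    return {
        "version": BACKUP_VERSION,
        "config": world.config.to_flat(),
        "t": world.t,
        "next_id": world.next_id,
        "max_tag": world.max_tag,
        "height": world.height,
        "width": world.width,
        "external": world.external.tolist(),
        "organisms": organisms,
        "phylo": world.phylo.to_dict(),
        "rng_state": world.rng.bit_generator.state,
        "rng_tiebreak_state": world.rng_tiebreak.bit_generator.state,
        "protocol_state": dict(world.protocol_state),
        "division_count": world.division_count,
        "death_count": world.death_count,
    }


def world_from_dict(d: dict) -> World:
    if d.get("version") != BACKUP_VERSION:
        raise BackupError(f"unsupported backup version {d.get('version')!r}")
    config = SimulationConfig.from_flat(d["config"])
    world = World(config, seed=0)
    world.t = int(d["t"])
    world.next_id = int(d["next_id"])
    world.max_tag = int(d["max_tag"])
    world.external = np.asarray(d["external"], dtype=np.float64)
    if world.external.shape != (world.height, world.width, world.max_tag):
        raise BackupError("external field shape does not match header")
    world.phylo = PhyloTree.from_dict(d["phylo"])
    world.rng.bit_generator.state = d["rng_state"]
    world.rng_tiebreak.bit_generator.state = d["rng_tiebreak_state"]
    world.protocol_state = dict(d["protocol_state"])
    world.division_count = int(d["division_count"])
    world.death_count = int(d["death_count"])
    from .metabolism import OdeSystem
    for od in d["organisms"]:
        org = Organism(int(od["id"]), Genome.from_dict(od["genome"]),
                       int(od["birth_step"]),
                       od["parent_id"], int(od["generation"]), od["lineage_tag"])
        org.protein_conc = np.asarray(od["protein_conc"], dtype=np.float64)
        if len(org.protein_conc) != len(org.proteins):
            raise BackupError(f"organism {org.id}: protein vector does not match genome")
        org.internal = np.asarray(od["internal"], dtype=np.float64)
        org.current_score = float(od["current_score"])
        org.divided_this_step = bool(od["divided_this_step"])
        org.group = od.get("group")
        if od.get("profile"):
            up, pr, rl = od["profile"]
            org.profile = TrophicProfile(up, pr, rl)
        org.ode = OdeSystem(org.proteins, max_tag=world.max_tag, config=config.ode)
        world.grid[tuple(od["pos"])] = org
    return world


def save_backup(world: World, path: str) -> None:
    """Write a lossless, versioned world snapshot as JSON text."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(world_to_dict(world), fh, sort_keys=True, separators=(",", ":"))


def load_backup(path: str) -> World:
    """Restore a world snapshot; raises BackupError on version mismatch or damage."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            d = json.load(fh)
    except (json.JSONDecodeError, OSError) as exc:
        raise BackupError(f"cannot read backup {path!r}: {exc}") from exc
    if not isinstance(d, dict) or "version" not in d:
        raise BackupError(f"{path!r} is not a world backup")
    return world_from_dict(d)


def copy_world(world: World) -> World:
    """Deep copy through the backup representation (exact, including RNG)."""
    return world_from_dict(copy.deepcopy(world_to_dict(world)))


# -- campaigns ----------------------------------------------------------------------


@dataclass
class CampaignSpec:
    config: SimulationConfig
    n_repetitions: int = 12
    n_steps: int = 500_000
    seed: int = 0
    snapshot_every: int = 1_000
    max_seeding_trials: int = 300

    def __post_init__(self) -> None:
        if self.n_repetitions < 1 or self.n_steps < 0:
            raise ValueError("invalid campaign spec")


def run_campaign(spec: CampaignSpec, outdir: str) -> pd.DataFrame:
    """Run independent repetitions; returns the concatenated summary table.

    Per repetition: viable seeding, then ``n_steps`` ecological time-steps
    with world snapshots every ``snapshot_every`` steps.  A seeding failure is
    reported for that repetition without aborting the campaign.
    """
    os.makedirs(outdir, exist_ok=True)
    ss = np.random.SeedSequence(spec.seed)
    frames = []
    for rep, sub in enumerate(ss.spawn(spec.n_repetitions)):
        rep_dir = os.path.join(outdir, f"rep{rep:02d}")
        os.makedirs(rep_dir, exist_ok=True)
        try:
            world, trial = seed_viable_population(
                copy.deepcopy(spec.config), sub, spec.max_seeding_trials)
        except SeedingError as exc:
            with open(os.path.join(rep_dir, "FAILED_SEEDING.txt"), "w") as fh:
                fh.write(str(exc) + "\n")
            continue
        save_backup(world, os.path.join(rep_dir, "seeded.json"))
        world.history.clear()
        for i in range(spec.n_steps):
            step(world)
            if spec.snapshot_every and (i + 1) % spec.snapshot_every == 0:
                world.phylo.prune()
                save_backup(world, os.path.join(rep_dir, f"snapshot_{world.t:08d}.json"))
        df = pd.DataFrame(world.history)
        df.insert(0, "repetition", rep)
        df.to_csv(os.path.join(rep_dir, "summary.csv"), index=False)
        world.phylo.prune()
        if world.grid:
            groups = {org.id: org.group for org in world.grid.values()}
            with open(os.path.join(rep_dir, "final_tree.nwk"), "w") as fh:
                fh.write(newick_export(world.phylo, groups, t_now=world.t) + "\n")
        frames.append(df)
    result = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    result.to_csv(os.path.join(outdir, "campaign_summary.csv"), index=False)
    return result


# -- competition assays --------------------------------------------------------------


def pool_from_world(world: World, by: str = "lineage_tag") -> dict[str, list[dict]]:
    """Extract strain pools (genome + saved cell state) keyed by lineage or group."""
    pools: dict[str, list[dict]] = {}
    for org in world.organisms():
        key = org.lineage_tag if by == "lineage_tag" else org.group
        if key is None:
            continue
        pools.setdefault(key, []).append({
            "genome": org.genome.copy(),
            "internal": org.internal.copy(),
            "protein_conc": org.protein_conc.copy(),
        })
    return pools


def seed_competition(pool_a: list[dict], pool_b: list[dict], freq_b: float,
                     config: SimulationConfig,
                     seed: int | np.random.SeedSequence = 0) -> World:
    """Fill a fresh grid from two strain pools at initial B frequency ``freq_b``.

    Each spot receives an organism sampled with replacement from the B pool
    with probability ``freq_b``, else from the A pool; sampled organisms carry
    their saved internal state verbatim.  The environment is reset to a cycle
    start (only the primary resource, at ``f_in``).
    """
    if not pool_a or not pool_b:
        raise ValueError("both strain pools must be non-empty")
    if not 0.0 < freq_b < 1.0:
        raise ValueError("freq_b must lie strictly in (0, 1)")
    world = World(config, seed=seed)
    world.external[:, :, :] = 0.0
    world.external[:, :, config.protocol.m_exo - 1] = config.protocol.f_in
    for pos in world.positions():
        if world.rng.random() < freq_b:
            pool, tag = pool_b, "B"
        else:
            pool, tag = pool_a, "A"
        sample = pool[int(world.rng.integers(0, len(pool)))]
        org = world.add_organism(sample["genome"].copy(), pos, lineage_tag=tag,
                                 at_equilibrium=False)
        world.ensure_tag(len(sample["internal"]))
        org.internal = np.zeros(world.max_tag)
        org.internal[:len(sample["internal"])] = sample["internal"]
        org.protein_conc = sample["protein_conc"].copy()
    return world


@dataclass
class AssaySpec:
    config: SimulationConfig
    pool_a: list[dict] = field(default_factory=list)
    pool_b: list[dict] = field(default_factory=list)
    freqs_b: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
    repetitions: int = 10
    n_cycles: int = 1
    mutation: bool = True
    seed: int = 0


def _lineage_counts(world: World) -> tuple[int, int]:
    a = sum(1 for o in world.grid.values() if o.lineage_tag == "A")
    b = sum(1 for o in world.grid.values() if o.lineage_tag == "B")
    return a, b


def run_competition(spec: AssaySpec) -> pd.DataFrame:
    """Run the frequency grid of competition assays.

    Returns one row per (initial frequency, repetition, cycle) with the A/B
    lineage counts at the cycle boundaries and the log-fitness of B over the
    cycle; per-step counts are available in the ``trajectory`` column.
    """
    rates = spec.config.mutation if spec.mutation else MutationRates.zero()
    delta_t = spec.config.protocol.delta_t
    ss = np.random.SeedSequence(spec.seed)
    rows = []
    for freq in spec.freqs_b:
        for rep in range(spec.repetitions):
            sub = ss.spawn(1)[0]
            world = seed_competition(spec.pool_a, spec.pool_b, freq,
                                     copy.deepcopy(spec.config), sub)
            a_traj, b_traj = [], []
            a0, b0 = _lineage_counts(world)
            ai, bi = a0, b0
            for cycle in range(spec.n_cycles):
                for _ in range(delta_t):
                    step(world, mutation_rates=rates, record=False)
                    a, b = _lineage_counts(world)
                    a_traj.append(a)
                    b_traj.append(b)
                af, bf = _lineage_counts(world)
                lf = (log_fitness(bi, bf, ai, af)
                      if bi > 0 and ai > 0 else float("nan"))
                rows.append({
                    "freq_b": freq, "repetition": rep, "cycle": cycle,
                    "A_initial": ai, "B_initial": bi,
                    "A_final": af, "B_final": bf,
                    "log_fitness_B": lf,
                    "trajectory": (list(a_traj), list(b_traj)),
                })
                ai, bi = af, bf
    return pd.DataFrame(rows)


# -- transfer experiments -------------------------------------------------------------


@dataclass
class TransferSpec:
    source: World
    target_protocol_variant: str = "continuous"
    n_steps: int = 500_000
    repetitions: int = 10
    seed: int = 0
    check_every: int = 1


def founder_subtrees(world: World) -> dict[int, list[int]]:
    """Map each living organism id to its MRCA-subtree side; raises if not two."""
    assignment = world.phylo.subtree_of_living()
    sides = sorted(set(assignment.values()))
    if len(sides) != 2:
        raise ValueError("source population must have two living MRCA subtrees")
    return assignment


def run_transfer(spec: TransferSpec) -> pd.DataFrame:
    """Propagate a two-ecotype population under a target regime.

    Per repetition reports whether the polymorphism persisted, the failure
    time (first step at which one founder MRCA subtree has no living
    descendant) and which trophic group went extinct.
    """
    assignment = founder_subtrees(spec.source)
    sides = sorted(set(assignment.values()))
    side_groups: dict[int, str] = {}
    for side in sides:
        groups = [org.group for org in spec.source.grid.values()
                  if assignment.get(org.id) == side and org.group]
        side_groups[side] = (max(set(groups), key=groups.count) if groups else "?")
    ss = np.random.SeedSequence(spec.seed)
    rows = []
    for rep in range(spec.repetitions):
        world = copy_world(spec.source)
        sub = ss.spawn(1)[0]
        s_main, s_tie = sub.spawn(2)
        world.rng = np.random.Generator(np.random.PCG64(s_main))
        world.rng_tiebreak = np.random.Generator(np.random.PCG64(s_tie))
        world.config.protocol.variant = spec.target_protocol_variant
        world.config.protocol.Dg = None
        world.t = 0
        world.protocol_state = {}
        for org in world.grid.values():
            org.lineage_tag = str(assignment[org.id])
        failure_t = None
        extinct_side = None
        for i in range(spec.n_steps):
            step(world, record=False)
            if (i + 1) % spec.check_every:
                continue
            counts = {str(s): 0 for s in sides}
            for org in world.grid.values():
                counts[org.lineage_tag] += 1
            empty = [s for s, c in counts.items() if c == 0]
            if empty:
                failure_t = world.t
                extinct_side = empty[0] if len(empty) == 1 else "both"
                break
        rows.append({
            "repetition": rep,
            "persisted": failure_t is None,
            "failure_time": failure_t,
            "extinct_group": (None if extinct_side is None else
                              "both" if extinct_side == "both" else
                              side_groups[int(extinct_side)]),
        })
    return pd.DataFrame(rows)
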