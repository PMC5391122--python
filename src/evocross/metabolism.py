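"""Genome expression, per-organism kinetics, score and toxicity.

A genome compiles into a set of protein species (one per enzyme-coding unit
inside a functional region).  Each species either catalyzes a cytoplasmic
Michaelis-Menten reaction s -> p, or — when s = p — acts as a membrane pump
moving that metabolite between the cell and its grid spot (inward when kcat is
positive, outward when negative, using |kcat|).  Protein production follows
d[E]/dt = beta - phi*[E], with beta inherited from the region's promoter.

One ecological time-step integrates the resulting ODE system over 100
centi-time-steps with the adaptive Cash-Karp method.  The score of an organism
is the summed internal concentration of "essential" metabolites (those with a
prime tag); any internal concentration at or above the toxicity threshold is
lethal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from sympy import isprime

from ._kinetics import STATUS_OK, integrate_rkck
from .config import OdeConfig
from .genome import E, Genome, functional_regions


class IntegrationError(RuntimeError):
    """Raised when the adaptive integrator fails (step underflow or blow-up)."""

    def __init__(self, message: str, organism_id: int | None = None):
        super().__init__(message)
        self.organism_id = organism_id


@dataclass
class ProteinSpecies:
    """An expressed gene product (cytoplasmic enzyme or membrane pump)."""

    source_unit: int
    beta: float
    s: int
    p: int
    kcat: float           # signed; magnitude used in the rate law
    km: float             # derived: |kcat| / (kcat/KM)
    concentration: float = 0.0

    @property
    def is_pump(self) -> bool:
        return self.s == self.p

    @property
    def direction(self) -> str | None:
        if not self.is_pump:
            return None
        return "in" if self.kcat > 0 else "out"

    def signature(self) -> tuple:
        """Attribute tuple identifying a species across a faithful replication."""
        return (self.beta, self.s, self.p, self.kcat, self.km)


@dataclass
class CellState:
    """Concentrations of one organism: proteins, internal and spot-local pools.

    ``internal`` and ``external_local`` are dense arrays indexed by
    ``tag - 1``.  After integration the per-time-step integrated fluxes
    (uptake, production, release; same indexing) are attached.
    """

    proteins: np.ndarray
    internal: np.ndarray
    external_local: np.ndarray
    uptake: np.ndarray | None = field(default=None)
    production: np.ndarray | None = field(default=None)
    release: np.ndarray | None = field(default=None)

    @property
    def max_tag(self) -> int:
        return len(self.internal)


def express(genome: Genome) -> list[ProteinSpecies]:
    """Compile a genome into its protein species.

    One species per E unit inside a functional region; each receives the full
    beta of its region's promoter (operon members are not diluted).  E units
    outside any region are silent.
    """
    species: list[ProteinSpecies] = []
    for region in functional_regions(genome):
        beta = float(genome.beta[region.promoter_index])
        for i in region.enzyme_indices:
            kcat = float(genome.kcat[i])
            ratio = float(genome.kcat_over_km[i])
            species.append(ProteinSpecies(
                source_unit=i, beta=beta, s=int(genome.s[i]), p=int(genome.p[i]),
                kcat=kcat, km=abs(kcat) / ratio))
    return species


def is_essential(tag: int) -> bool:
    """A metabolite is essential iff its tag is prime (1 is not prime)."""
    if tag < 1:
        raise ValueError(f"metabolite tag must be >= 1, got {tag}")
    return bool(isprime(int(tag)))


@lru_cache(maxsize=None)
def essential_mask(max_tag: int) -> np.ndarray:
    """Boolean mask over tags 1..max_tag (index tag-1), True for primes."""
    mask = np.zeros(max_tag, dtype=bool)
    for t in range(2, max_tag + 1):
        mask[t - 1] = isprime(t)
    mask.setflags(write=False)
    return mask


class OdeSystem:
    """The compiled kinetic system of one organism.

    Identical protein species (same beta, reaction and kinetics — e.g. exact
    gene copies created by duplications) are merged for integration: the
    merged concentration obeys d[S]/dt = k*beta - phi*S and carries the summed
    flux, which leaves every metabolite trajectory unchanged (flux
    additivity).  Per-copy concentrations are recovered exactly afterwards
    from the closed form beta/phi + (c0 - beta/phi)*exp(-phi*t), since protein
    dynamics are linear and independent of the metabolites.

    State layout: ``[merged proteins | internal(active tags) |
    external(active tags) | uptake acc | production acc | release acc]``.
    Only tags touched by the organism's proteins enter the state; all other
    pools are constant over a time-step.
    """

    def __init__(self, proteins: list[ProteinSpecies], max_tag: int,
                 config: OdeConfig | None = None):
        self.config = config or OdeConfig()
        self.proteins = proteins
        self.max_tag = max_tag
        tags = sorted({sp.s for sp in proteins} | {sp.p for sp in proteins})
        if tags and tags[-1] > max_tag:
            raise ValueError("protein references a tag beyond the tag universe")
        self.active_tags = np.asarray(tags, dtype=np.int64)
        m = len(tags)
        self._tag_slot = {t: k for k, t in enumerate(tags)}

        groups: dict[tuple, list[int]] = {}
        for j, sp in enumerate(proteins):
            groups.setdefault(sp.signature(), []).append(j)
        self.group_members: list[list[int]] = list(groups.values())
        reps = [proteins[members[0]] for members in self.group_members]
        n = len(reps)
        self.n_groups = n
        self.n_active = m
        self.n_pools = n + 2 * m
        self.n_state = n + 5 * m

        self.beta_per_copy = np.asarray([sp.beta for sp in reps], dtype=np.float64)
        self.copy_counts = np.asarray([len(ms) for ms in self.group_members],
                                      dtype=np.float64)
        self.beta = self.beta_per_copy * self.copy_counts  # merged production
        prot_idx = np.arange(n, dtype=np.int64)
        sub_idx = np.zeros(n, dtype=np.int64)
        prod_idx = np.zeros(n, dtype=np.int64)
        acc_idx = np.zeros(n, dtype=np.int64)
        for j, sp in enumerate(reps):
            s_slot = self._tag_slot[sp.s]
            p_slot = self._tag_slot[sp.p]
            if sp.is_pump:
                if sp.kcat > 0:  # inflow: external -> internal
                    sub_idx[j] = n + m + s_slot
                    prod_idx[j] = n + s_slot
                    acc_idx[j] = n + 2 * m + s_slot          # uptake accumulator
                else:            # outflow: internal -> external
                    sub_idx[j] = n + s_slot
                    prod_idx[j] = n + m + s_slot
                    acc_idx[j] = n + 4 * m + s_slot          # release accumulator
            else:
                sub_idx[j] = n + s_slot
                prod_idx[j] = n + p_slot
                acc_idx[j] = n + 3 * m + p_slot              # production accumulator
        self.prot_idx = prot_idx
        self.sub_idx = sub_idx
        self.prod_idx = prod_idx
        self.acc_idx = acc_idx
        self.kcat_mag = np.asarray([abs(sp.kcat) for sp in reps], dtype=np.float64)
        self.km = np.asarray([sp.km for sp in reps], dtype=np.float64)

    # -- state packing --------------------------------------------------------

    def pack(self, cell: CellState) -> np.ndarray:
        y = np.zeros(self.n_state)
        n, m = self.n_groups, self.n_active
        for j, members in enumerate(self.group_members):
            y[j] = sum(cell.proteins[i] for i in members)
        if m:
            slots = self.active_tags - 1
            y[n:n + m] = cell.internal[slots]
            y[n + m:n + 2 * m] = cell.external_local[slots]
        return y

    def _per_copy_proteins(self, cell: CellState, t_total: float) -> np.ndarray:
        """Exact per-copy protein concentrations after ``t_total``."""
        phi = self.config.phi
        decay = math.exp(-phi * t_total)
        out = np.empty(len(self.proteins))
        for j, members in enumerate(self.group_members):
            eq = self.beta_per_copy[j] / phi
            for i in members:
                out[i] = eq + (cell.proteins[i] - eq) * decay
        return out

    def unpack(self, y: np.ndarray, cell: CellState, t_total: float) -> CellState:
        n, m = self.n_groups, self.n_active
        mt = cell.max_tag
        internal = cell.internal.copy()
        external = cell.external_local.copy()
        uptake = np.zeros(mt)
        production = np.zeros(mt)
        release = np.zeros(mt)
        if m:
            slots = self.active_tags - 1
            internal[slots] = y[n:n + m]
            external[slots] = y[n + m:n + 2 * m]
            uptake[slots] = y[n + 2 * m:n + 3 * m]
            production[slots] = y[n + 3 * m:n + 4 * m]
            release[slots] = y[n + 4 * m:n + 5 * m]
        return CellState(proteins=self._per_copy_proteins(cell, t_total),
                         internal=internal, external_local=external,
                         uptake=uptake, production=production, release=release)

    # -- dynamics -------------------------------------------------------------

    def derivative(self, y: np.ndarray) -> np.ndarray:
        """Time derivative of the packed (merged) state (pure-python reference)."""
        dy = np.zeros_like(y)
        dy[:self.n_groups] = self.beta - self.config.phi * y[:self.n_groups]
        for j in range(len(self.kcat_mag)):
            s = max(y[self.sub_idx[j]], 0.0)
            flux = self.kcat_mag[j] * y[self.prot_idx[j]] * s / (self.km[j] + s)
            dy[self.sub_idx[j]] -= flux
            dy[self.prod_idx[j]] += flux
            dy[self.acc_idx[j]] += flux
        return dy

    def _any_flux_possible(self, y: np.ndarray) -> bool:
        """Reachability check: can any reaction ever carry flux from this state?"""
        if self.n_groups == 0:
            return False
        nonzero = y[:self.n_pools] > 0.0
        # a protein with positive production is eventually nonzero
        prot_on = nonzero[:self.n_groups] | (self.beta > 0.0)
        pools_on = nonzero[self.n_groups:self.n_pools].copy()
        n = self.n_groups
        for _ in range(len(self.kcat_mag) + 1):
            changed = False
            for j in range(len(self.kcat_mag)):
                if prot_on[j] and pools_on[self.sub_idx[j] - n] \
                        and not pools_on[self.prod_idx[j] - n]:
                    pools_on[self.prod_idx[j] - n] = True
                    changed = True
            if not changed:
                break
        for j in range(len(self.kcat_mag)):
            if prot_on[j] and pools_on[self.sub_idx[j] - n]:
                return True
        return False

    def integrate(self, cell: CellState, organism_id: int | None = None) -> CellState:
        """Advance the cell by one ecological time-step (100 centi-time-steps)."""
        cfg = self.config
        t_total = float(cfg.centi_steps)
        y0 = self.pack(cell)
        if not self._any_flux_possible(y0):
            # proteins relax in closed form; metabolites untouched
            return self.unpack(y0, cell, t_total)
        y, status = integrate_rkck(
            y0, t_total, self.beta, cfg.phi, self.prot_idx, self.sub_idx,
            self.prod_idx, self.acc_idx, self.kcat_mag, self.km,
            cfg.rel_tol, cfg.abs_tol, cfg.initial_step, cfg.conc_floor,
            self.n_pools)
        if status != STATUS_OK:
            raise IntegrationError(
                f"kinetic integration failed with status {status}",
                organism_id=organism_id)
        return self.unpack(y, cell, t_total)


def build_ode(proteins: list[ProteinSpecies], cell_state: CellState,
              config: OdeConfig | None = None) -> OdeSystem:
    """Compile the protein set of an organism into its kinetic system."""
    return OdeSystem(proteins, max_tag=cell_state.max_tag, config=config)


def integrate_time_step(ode_system: OdeSystem, cell_state: CellState,
                        config: OdeConfig | None = None,
                        organism_id: int | None = None) -> CellState:
    """Advance a cell state by one time-step under its kinetic system."""
    if config is not None:
        ode_system.config = config
    return ode_system.integrate(cell_state, organism_id=organism_id)


def score(cell_state: CellState) -> float:
    """Sum of internal concentrations of essential (prime-tag) metabolites."""
    mask = essential_mask(cell_state.max_tag)
    return float(cell_state.internal[mask].sum())


def toxicity_exceeded(cell_state: CellState, threshold: float) -> bool:
    """True iff any internal concentration reaches the lethal threshold."""
    if threshold <= 0:
        raise ValueError("toxicity threshold must be positive")
    if len(cell_state.internal) == 0:
        return False
    return bool(np.any(cell_state.internal >= threshold))
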