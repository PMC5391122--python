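"""Circular coarse-grained genome and its mutational operators.

A genome is a circular sequence of typed units: non-coding (NC), promoter (P)
and enzyme-coding (E).  Every unit carries the full attribute tuple
``(unit_type, beta, s, p, kcat, kcat_over_km)`` whatever its type; attributes
irrelevant to the current type mutate neutrally and become functional again if
the type later changes.  A promoter followed by one or more contiguous E units
forms a functional region (an operon); the first non-E unit interrupts it.

At replication the genome undergoes, in this order, chromosomal rearrangements
(duplications, deletions, translocations, inversions, each with a
Binomial(length, rate) event count) and then point mutations (per-attribute
perturbations plus unit-type transitions).  Rearrangement breakpoints "break"
the two units flanking them: each attribute of the flanking pair is swapped
with a small probability, mimicking breakpoints falling inside genes.

Internally a genome is a struct-of-arrays (one numpy column per attribute),
which keeps the mutation operators vectorized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import GenomeConfig, MutationRates

# unit type codes
NC, P, E = 0, 1, 2
TYPE_NAMES = {NC: "NC", P: "P", E: "E"}
TYPE_CODES = {v: k for k, v in TYPE_NAMES.items()}


@dataclass
class GenomicUnit:
    """One genomic unit with the full attribute tuple (API view of a row)."""

    unit_type: str
    beta: float
    s: int
    p: int
    kcat: float
    kcat_over_km: float


@dataclass(frozen=True)
class FunctionalRegion:
    """A maximal P-(E)+ run on the circular sequence."""

    promoter_index: int
    enzyme_indices: tuple[int, ...]


class Genome:
    """Circular sequence of genomic units, stored column-wise."""

    __slots__ = ("unit_type", "beta", "s", "p", "kcat", "kcat_over_km")

    def __init__(self, unit_type, beta, s, p, kcat, kcat_over_km):
        self.unit_type = np.asarray(unit_type, dtype=np.int8)
        self.beta = np.asarray(beta, dtype=np.float64)
        self.s = np.asarray(s, dtype=np.int64)
        self.p = np.asarray(p, dtype=np.int64)
        self.kcat = np.asarray(kcat, dtype=np.float64)
        self.kcat_over_km = np.asarray(kcat_over_km, dtype=np.float64)
        n = {len(self.unit_type), len(self.beta), len(self.s), len(self.p),
             len(self.kcat), len(self.kcat_over_km)}
        if len(n) != 1:
            raise ValueError("all attribute columns must share one length")
        if np.any(self.s < 1) or np.any(self.p < 1):
            raise ValueError("metabolite tags s and p must be >= 1")

    # -- construction ---------------------------------------------------------

    @classmethod
    def empty(cls) -> "Genome":
        z = np.zeros(0)
        return cls(z, z, np.zeros(0, dtype=np.int64) + 1, np.zeros(0, dtype=np.int64) + 1, z, z)

    @classmethod
    def from_units(cls, units: list[GenomicUnit]) -> "Genome":
        return cls(
            [TYPE_CODES[u.unit_type] for u in units],
            [u.beta for u in units],
            [u.s for u in units],
            [u.p for u in units],
            [u.kcat for u in units],
            [u.kcat_over_km for u in units],
        )

    def copy(self) -> "Genome":
        return Genome(self.unit_type.copy(), self.beta.copy(), self.s.copy(),
                      self.p.copy(), self.kcat.copy(), self.kcat_over_km.copy())

    # -- basic protocol -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.unit_type)

    def unit(self, i: int) -> GenomicUnit:
        i = i % len(self)
        return GenomicUnit(TYPE_NAMES[int(self.unit_type[i])], float(self.beta[i]),
                           int(self.s[i]), int(self.p[i]), float(self.kcat[i]),
                           float(self.kcat_over_km[i]))

    def units(self) -> list[GenomicUnit]:
        return [self.unit(i) for i in range(len(self))]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return (len(self) == len(other)
                and np.array_equal(self.unit_type, other.unit_type)
                and np.array_equal(self.beta, other.beta)
                and np.array_equal(self.s, other.s)
                and np.array_equal(self.p, other.p)
                and np.array_equal(self.kcat, other.kcat)
                and np.array_equal(self.kcat_over_km, other.kcat_over_km))

    def __hash__(self):  # mutable container
        raise TypeError("Genome is not hashable")

    def _take(self, idx: np.ndarray) -> "Genome":
        return Genome(self.unit_type[idx], self.beta[idx], self.s[idx],
                      self.p[idx], self.kcat[idx], self.kcat_over_km[idx])

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "unit_type": self.unit_type.tolist(),
            "beta": self.beta.tolist(),
            "s": self.s.tolist(),
            "p": self.p.tolist(),
            "kcat": self.kcat.tolist(),
            "kcat_over_km": self.kcat_over_km.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Genome":
        return cls(d["unit_type"], d["beta"], d["s"], d["p"], d["kcat"], d["kcat_over_km"])


# -- generation ---------------------------------------------------------------


def random_genome(rng: np.random.Generator, n_units: int, n_promoters: int,
                  n_enzymes: int, config: GenomeConfig | None = None) -> Genome:
    """Generate a random genome with the requested type composition.

    Types occupy uniformly random positions; every unit of every type receives
    attributes drawn uniformly within their ranges (|kcat| and kcat/KM
    log-uniform, kcat sign uniform, tags uniform over the initial tag range).
    """
    config = config or GenomeConfig()
    if n_promoters + n_enzymes > n_units:
        raise ValueError("n_promoters + n_enzymes must not exceed n_units")
    types = np.full(n_units, NC, dtype=np.int8)
    pos = rng.permutation(n_units)
    types[pos[:n_promoters]] = P
    types[pos[n_promoters:n_promoters + n_enzymes]] = E

    beta = rng.uniform(config.beta_min, config.beta_max, n_units)
    s = rng.integers(config.tag_init_min, config.tag_init_max + 1, n_units)
    p = rng.integers(config.tag_init_min, config.tag_init_max + 1, n_units)
    mag = 10.0 ** rng.uniform(np.log10(config.kcat_min), np.log10(config.kcat_max), n_units)
    sign = np.where(rng.random(n_units) < 0.5, 1.0, -1.0)
    ratio = 10.0 ** rng.uniform(np.log10(config.ratio_min), np.log10(config.ratio_max), n_units)
    return Genome(types, beta, s, p, mag * sign, ratio)


# -- functional-region detection -----------------------------------------------


def functional_regions(genome: Genome) -> list[FunctionalRegion]:
    """Return every maximal P-(E)+ run, scanning the circle with wrap-around."""
    L = len(genome)
    if L == 0:
        return []
    types = genome.unit_type
    regions: list[FunctionalRegion] = []
    for i in np.flatnonzero(types == P):
        enz: list[int] = []
        j = (i + 1) % L
        while types[j] == E and len(enz) < L - 1:
            enz.append(int(j))
            j = (j + 1) % L
        if enz:
            regions.append(FunctionalRegion(int(i), tuple(enz)))
    return regions


# -- point mutations ------------------------------------------------------------


def point_mutate(genome: Genome, rng: np.random.Generator, rates: MutationRates,
                 config: GenomeConfig | None = None) -> Genome:
    """Apply per-attribute point mutations and unit-type transitions.

    Each of the five attributes of each unit mutates independently with
    probability ``rates.point_rate``: tags move +/-1 (reflected at the lower
    bound 1), beta gains a N(0, sd^2) increment clamped to [0, 1], and the
    decimal logs of |kcat| and kcat/KM gain N(0, sd^2) increments clamped to
    their ranges (the sign of kcat is preserved).  Independently, each unit
    switches to one of the two other types with probability
    ``rates.transition_rate``.
    """
    config = config or GenomeConfig()
    g = genome.copy()
    L = len(g)
    if L == 0:
        return g
    hits = rng.random((L, 5)) < rates.point_rate  # beta, s, p, kcat, ratio

    idx = np.flatnonzero(hits[:, 0])
    if idx.size:
        g.beta[idx] = np.clip(g.beta[idx] + rng.normal(0.0, rates.mutation_sd, idx.size),
                              config.beta_min, config.beta_max)

    for col, arr in ((1, g.s), (2, g.p)):
        idx = np.flatnonzero(hits[:, col])
        if idx.size:
            step = rng.integers(0, 2, idx.size) * 2 - 1
            new = arr[idx] + step
            new[new < 1] = 2  # decrement at 1 reflects to an increment
            arr[idx] = new

    idx = np.flatnonzero(hits[:, 3])
    if idx.size:
        logmag = np.log10(np.abs(g.kcat[idx])) + rng.normal(0.0, rates.mutation_sd, idx.size)
        logmag = np.clip(logmag, np.log10(config.kcat_min), np.log10(config.kcat_max))
        sign = np.sign(g.kcat[idx])
        if config.allow_kcat_sign_flip:
            flip = rng.random(idx.size) < 0.5
            sign = np.where(flip, -sign, sign)
        g.kcat[idx] = sign * 10.0 ** logmag

    idx = np.flatnonzero(hits[:, 4])
    if idx.size:
        logr = np.log10(g.kcat_over_km[idx]) + rng.normal(0.0, rates.mutation_sd, idx.size)
        g.kcat_over_km[idx] = 10.0 ** np.clip(logr, np.log10(config.ratio_min),
                                              np.log10(config.ratio_max))

    trans = np.flatnonzero(rng.random(L) < rates.transition_rate)
    if trans.size:
        shift = rng.integers(1, 3, trans.size)  # uniformly one of the two other types
        g.unit_type[trans] = (g.unit_type[trans] + shift) % 3
    return g


# -- rearrangements -------------------------------------------------------------

_EXCHANGE_FIELDS = ("unit_type", "beta", "s", "p", "kcat", "kcat_over_km")


def _exchange_at_gaps(g: Genome, gaps: list[int], rng: np.random.Generator,
                      rate: float) -> None:
    """Swap attributes between the two units flanking each breakpoint gap.

    Gap ``k`` lies between units ``k-1`` and ``k`` on the circle.  For each
    attribute independently, the flanking pair exchanges its values with
    probability ``rate``.
    """
    L = len(g)
    if L < 2 or rate <= 0.0:
        return
    for gap in gaps:
        i = (gap - 1) % L
        j = gap % L
        if i == j:
            continue
        swap = rng.random(len(_EXCHANGE_FIELDS)) < rate
        for field, do in zip(_EXCHANGE_FIELDS, swap):
            if do:
                col = getattr(g, field)
                col[i], col[j] = col[j], col[i]


def _segment(L: int, b1: int, b2: int) -> np.ndarray:
    """Indices of the circular segment [b1, b2); empty when b1 == b2."""
    seglen = (b2 - b1) % L
    return (b1 + np.arange(seglen)) % L


def invert_segment(genome: Genome, b1: int, b2: int) -> Genome:
    """Reverse the unit order of the circular segment [b1, b2) in place.

    Pure structural operation (no breakpoint attribute exchange); applying it
    twice with the same breakpoints restores the original genome.
    """
    g = genome.copy()
    seg = _segment(len(g), b1, b2)
    if seg.size > 1:
        rev = seg[::-1]
        for field in _EXCHANGE_FIELDS:
            col = getattr(g, field)
            col[seg] = col[rev].copy()
    return g


def rearrange(genome: Genome, rng: np.random.Generator, rates: MutationRates,
              config: GenomeConfig | None = None,
              event_log: list | None = None) -> Genome:
    """Apply duplications, deletions, translocations and inversions.

    For each type the event count is Binomial(length, rearrangement_rate),
    with the length taken at entry; events are then applied sequentially
    (duplications, deletions, translocations, inversions).  Each event draws
    two uniform breakpoints delimiting a circular segment; equal breakpoints
    give a size-0 no-op.  At every breakpoint the flanking units may exchange
    attributes (see :func:`_exchange_at_gaps`).
    """
    g = genome.copy()
    L0 = len(g)
    if L0 == 0:
        return g
    counts = {kind: rng.binomial(L0, rates.rearrangement_rate)
              for kind in ("duplication", "deletion", "translocation", "inversion")}
    events = [kind for kind in ("duplication", "deletion", "translocation",
                                "inversion") for _ in range(counts[kind])]
    if not events:
        return g
    # interleave event types so that consecutive duplications do not compound
    # on the grown intermediate before any deletion applies
    order = rng.permutation(len(events))
    xr = rates.breakpoint_exchange_rate

    for k in order:
        kind = events[k]
        L = len(g)
        if L == 0:
            break
        b1, b2 = int(rng.integers(0, L)), int(rng.integers(0, L))
        if event_log is not None:
            event_log.append((kind, b1, b2, (b2 - b1) % L))

        if kind == "duplication":
            ins = int(rng.integers(0, L))
            gaps = [b1, ins] if b1 == b2 else [b1, b2, ins]
            _exchange_at_gaps(g, gaps, rng, xr)
            seg = _segment(L, b1, b2)
            if seg.size:
                take = np.concatenate([np.arange(0, ins), seg, np.arange(ins, L)])
                g = g._take(take)

        elif kind == "deletion":
            gaps = [b1] if b1 == b2 else [b1, b2]
            _exchange_at_gaps(g, gaps, rng, xr)
            seg = _segment(L, b1, b2)
            if seg.size:
                keep = np.ones(L, dtype=bool)
                keep[seg] = False
                g = g._take(np.flatnonzero(keep))

        elif kind == "translocation":
            seg = _segment(L, b1, b2)
            if seg.size == 0 or seg.size == L:
                _exchange_at_gaps(g, [b1] if b1 == b2 else [b1, b2], rng, xr)
                continue
            _exchange_at_gaps(g, [b1, b2], rng, xr)
            keep = np.ones(L, dtype=bool)
            keep[seg] = False
            rem_idx = np.flatnonzero(keep)
            segment = g._take(seg)
            remainder = g._take(rem_idx)
            Lr = len(remainder)
            # closure junction where the excision gap sealed: in the remainder
            # the units formerly flanking the segment are now adjacent, at gap
            # index = number of kept units before b1 on the linearization
            closure_gap = int(np.searchsorted(rem_idx, b1))
            _exchange_at_gaps(remainder, [closure_gap], rng, xr)
            ins = int(rng.integers(0, Lr)) if Lr else 0
            _exchange_at_gaps(remainder, [ins], rng, xr)
            g = Genome(*(
                np.concatenate([getattr(remainder, f)[:ins], getattr(segment, f),
                                getattr(remainder, f)[ins:]])
                for f in _EXCHANGE_FIELDS))

        else:  # inversion
            gaps = [b1] if b1 == b2 else [b1, b2]
            _exchange_at_gaps(g, gaps, rng, xr)
            g = invert_segment(g, b1, b2)
    return g


def replicate(genome: Genome, rng: np.random.Generator, rates: MutationRates,
              config: GenomeConfig | None = None) -> Genome:
    """Produce one daughter genome: rearrangements first, then point mutations.

    The parent is never modified; call twice with independent draws for the
    two daughters of a division.
    """
    return point_mutate(rearrange(genome, rng, rates, config), rng, rates, config)
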