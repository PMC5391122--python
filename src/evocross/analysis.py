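"""Trophic profiles, trophic groups, phylogeny and population statistics.

The trophic profile of an organism is three bit strings (uptake | production |
release) over metabolite tags 1..max_tag, a bit being set when the
corresponding time-step-integrated flux exceeded a small threshold.  Group A
organisms pump in the primary resource (and possibly other metabolites);
group B organisms pump in other metabolites — by-products — but not the
primary resource.

Division history is recorded exhaustively: every division turns a living leaf
into an internal node with two children, so the tree is binary.  The most
recent common ancestor (MRCA) age of the living population and the
phylogenetic structure score PS = |f1 - f2| (difference in group-B frequency
between the two MRCA subtrees) summarize the stability and the ecological
structuring of the polymorphism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genome import functional_regions
from .metabolism import CellState, essential_mask


# -- trophic profiles -----------------------------------------------------------


@dataclass(frozen=True)
class TrophicProfile:
    """Binary activity signature over tags 1..len(uptake) (leftmost = tag 1)."""

    uptake: str
    production: str
    release: str

    def text(self) -> str:
        return f"|{self.uptake}|{self.production}|{self.release}|"

    def uptake_tags(self) -> set[int]:
        return {i + 1 for i, b in enumerate(self.uptake) if b == "1"}

    def production_tags(self) -> set[int]:
        return {i + 1 for i, b in enumerate(self.production) if b == "1"}

    def release_tags(self) -> set[int]:
        return {i + 1 for i, b in enumerate(self.release) if b == "1"}


def _bits(values: np.ndarray, max_tag: int, threshold: float) -> str:
    v = np.zeros(max_tag)
    n = min(len(values), max_tag)
    v[:n] = values[:n]
    return "".join("1" if x > threshold else "0" for x in v)


def trophic_profile(organism_fluxes: CellState, max_tag: int,
                    flux_threshold: float = 1e-10) -> TrophicProfile:
    """Build the activity signature from time-step-integrated fluxes.

    Uptake and release bits use the *net* pump flux per metabolite (inflow
    minus outflow and vice versa); production bits use the *gross* enzymatic
    creation flux.  ``max_tag`` is the largest tag present in the system.
    """
    up = organism_fluxes.uptake if organism_fluxes.uptake is not None else np.zeros(0)
    pr = organism_fluxes.production if organism_fluxes.production is not None else np.zeros(0)
    rl = organism_fluxes.release if organism_fluxes.release is not None else np.zeros(0)
    n = max(len(up), len(rl), 0)
    upd = np.zeros(n)
    rld = np.zeros(n)
    upd[:len(up)] = up
    rld[:len(rl)] = rl
    net_in = upd - rld
    return TrophicProfile(
        uptake=_bits(net_in, max_tag, flux_threshold),
        production=_bits(pr, max_tag, flux_threshold),
        release=_bits(-net_in, max_tag, flux_threshold),
    )


GROUP_A = "A"
GROUP_B = "B"
UNCLASSIFIED = "unclassified"


def classify_group(profile: TrophicProfile, m_exo: int) -> str:
    """A if the profile uptakes the primary resource, B if it uptakes anything
    else but not the primary resource, unclassified when it uptakes nothing."""
    tags = profile.uptake_tags()
    if m_exo in tags:
        return GROUP_A
    if tags:
        return GROUP_B
    return UNCLASSIFIED


# -- phylogeny -------------------------------------------------------------------


@dataclass
class PhyloNode:
    id: int
    parent_id: int | None
    birth_step: int
    children: list[int] = field(default_factory=list)
    end_step: int | None = None   # division time (internal) or death time (leaf)
    group: str | None = None      # trophic group at sampling
    collapsed_divisions: int = 0  # divisions absorbed by unary-chain contraction

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_living(self) -> bool:
        return self.is_leaf and self.end_step is None


class PhyloError(ValueError):
    pass


class PhyloTree:
    """Exhaustive binary division-history tree of a population."""

    def __init__(self) -> None:
        self.nodes: dict[int, PhyloNode] = {}
        self.roots: list[int] = []

    def add_root(self, node_id: int, birth_step: int, group: str | None = None) -> None:
        if node_id in self.nodes:
            raise PhyloError(f"node {node_id} already recorded")
        self.nodes[node_id] = PhyloNode(node_id, None, birth_step, group=group)
        self.roots.append(node_id)

    def record_division(self, parent_id: int, child1_id: int, child2_id: int,
                        t: int) -> None:
        parent = self.nodes.get(parent_id)
        if parent is None:
            raise PhyloError(f"unknown parent {parent_id}")
        if not parent.is_living:
            raise PhyloError(f"parent {parent_id} is not a living leaf")
        if child1_id in self.nodes or child2_id in self.nodes:
            raise PhyloError("child id already recorded")
        parent.end_step = t
        for cid in (child1_id, child2_id):
            self.nodes[cid] = PhyloNode(cid, parent_id, t)
            parent.children.append(cid)

    def record_death(self, node_id: int, t: int) -> None:
        node = self.nodes.get(node_id)
        if node is None:
            raise PhyloError(f"unknown node {node_id}")
        if not node.is_living:
            raise PhyloError(f"node {node_id} is not a living leaf")
        node.end_step = t

    # -- queries ---------------------------------------------------------------

    def living_leaves(self) -> list[int]:
        return [n.id for n in self.nodes.values() if n.is_living]

    def ancestors(self, node_id: int) -> list[int]:
        """Path from ``node_id`` (inclusive) up to its root."""
        path = []
        cur: int | None = node_id
        while cur is not None:
            path.append(cur)
            cur = self.nodes[cur].parent_id
        return path

    def _living_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for leaf in self.living_leaves():
            for nid in self.ancestors(leaf):
                counts[nid] = counts.get(nid, 0) + 1
        return counts

    def mrca(self) -> int:
        """Id of the most recent node ancestral to every living leaf."""
        living = self.living_leaves()
        if not living:
            raise PhyloError("no living organism: MRCA undefined")
        counts = self._living_counts()
        n = len(living)
        for nid in self.ancestors(living[0]):
            if counts[nid] == n:
                return nid
        raise PhyloError("living leaves do not share a common ancestor")

    def mrca_age(self, t: int) -> int:
        return t - self.nodes[self.mrca()].birth_step

    def subtree_of_living(self) -> dict[int, int]:
        """Map each living leaf to the MRCA child subtree containing it."""
        m = self.mrca()
        children = set(self.nodes[m].children)
        out: dict[int, int] = {}
        for leaf in self.living_leaves():
            if leaf == m:
                continue
            for nid in self.ancestors(leaf):
                if nid in children:
                    out[leaf] = nid
                    break
        return out

    # -- pruning ---------------------------------------------------------------

    def prune(self) -> None:
        """Drop extinct subtrees and contract unary chains.

        Along-lineage division counts are preserved on the surviving child via
        ``collapsed_divisions``.
        """
        counts = self._living_counts()
        # remove nodes with no living descendants
        dead = [nid for nid in self.nodes if counts.get(nid, 0) == 0]
        for nid in dead:
            node = self.nodes.pop(nid)
            if node.parent_id is not None and node.parent_id in self.nodes:
                parent = self.nodes[node.parent_id]
                if nid in parent.children:
                    parent.children.remove(nid)
            if nid in self.roots:
                self.roots.remove(nid)
        # contract unary internal nodes
        for nid in list(self.nodes):
            node = self.nodes.get(nid)
            if node is None or len(node.children) != 1:
                continue
            child = self.nodes[node.children[0]]
            child.parent_id = node.parent_id
            child.collapsed_divisions += node.collapsed_divisions + 1
            if node.parent_id is None:
                self.roots[self.roots.index(nid)] = child.id
            else:
                parent = self.nodes[node.parent_id]
                parent.children[parent.children.index(nid)] = child.id
            del self.nodes[nid]

    def divisions_from_root(self, node_id: int) -> int:
        """Divisions along the line of descent from the root to ``node_id``."""
        total = 0
        path = self.ancestors(node_id)
        for nid in path[1:]:  # every strict ancestor divided once on the path
            total += 1 + self.nodes[nid].collapsed_divisions
        total += self.nodes[node_id].collapsed_divisions
        return total

    # -- export ----------------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "roots": list(self.roots),
            "nodes": [
                {"id": n.id, "parent": n.parent_id, "birth": n.birth_step,
                 "end": n.end_step, "children": list(n.children), "group": n.group,
                 "collapsed": n.collapsed_divisions}
                for n in self.nodes.values()
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhyloTree":
        tree = cls()
        tree.roots = list(d["roots"])
        for nd in d["nodes"]:
            tree.nodes[nd["id"]] = PhyloNode(
                nd["id"], nd["parent"], nd["birth"], list(nd["children"]),
                nd["end"], nd.get("group"), nd.get("collapsed", 0))
        return tree


def record_division(tree: PhyloTree, parent_id: int, child1_id: int,
                    child2_id: int, t: int) -> PhyloTree:
    tree.record_division(parent_id, child1_id, child2_id, t)
    return tree


def record_death(tree: PhyloTree, node_id: int, t: int) -> PhyloTree:
    tree.record_death(node_id, t)
    return tree


def mrca_age(tree: PhyloTree, t: int) -> int:
    return tree.mrca_age(t)


def ps_score(tree: PhyloTree, groups: dict[int, str]) -> float:
    """PS = |f1 - f2|, the group-B frequency difference between MRCA subtrees.

    ``groups`` maps living leaf ids to "A"/"B" (anything else is excluded from
    both numerator and denominator).  Raises when the MRCA has fewer than two
    living subtrees or when a subtree carries no classified leaf.
    """
    assignment = tree.subtree_of_living()
    sides = sorted(set(assignment.values()))
    if len(sides) != 2:
        raise PhyloError("PS score needs two living MRCA subtrees")
    freqs = []
    for side in sides:
        leaves = [leaf for leaf, s in assignment.items() if s == side]
        classified = [leaf for leaf in leaves if groups.get(leaf) in (GROUP_A, GROUP_B)]
        if not classified:
            raise PhyloError("PS score undefined: a subtree has no classified leaf")
        n_b = sum(1 for leaf in classified if groups[leaf] == GROUP_B)
        freqs.append(n_b / len(classified))
    return abs(freqs[0] - freqs[1])


def newick_export(tree: PhyloTree, annotations: dict[int, str] | None = None,
                  t_now: int | None = None) -> str:
    """Serialize (a pruned) tree to Newick; one tree per root, concatenated.

    Branch lengths are in time-steps; leaf labels carry the organism id and,
    when provided, its trophic group.
    """
    annotations = annotations or {}

    def node_time(n: PhyloNode) -> int:
        if n.end_step is not None:
            return n.end_step
        if t_now is None:
            raise PhyloError("t_now required to export living leaves")
        return t_now

    def label(n: PhyloNode) -> str:
        g = annotations.get(n.id, n.group)
        return f"{n.id}_{g}" if g else str(n.id)

    out: list[str] = []
    for root_id in tree.roots:
        # iterative post-order build
        pieces: dict[int, str] = {}
        stack: list[tuple[int, bool]] = [(root_id, False)]
        while stack:
            nid, expanded = stack.pop()
            node = tree.nodes[nid]
            if node.is_leaf:
                if node.parent_id is None:
                    length = node_time(node) - node.birth_step
                else:
                    length = node_time(node) - tree.nodes[node.parent_id].end_step
                pieces[nid] = f"{label(node)}:{length}"
            elif not expanded:
                stack.append((nid, True))
                for cid in node.children:
                    stack.append((cid, False))
            else:
                inner = ",".join(pieces[cid] for cid in node.children)
                if node.parent_id is None:
                    length = 0
                else:
                    length = node.end_step - tree.nodes[node.parent_id].end_step
                pieces[nid] = f"({inner}){label(node)}:{length}"
        out.append(pieces[root_id] + ";")
    return "\n".join(out)


# -- population statistics -------------------------------------------------------


@dataclass
class PopulationStats:
    """The five genome/metabolism summary statistics (means over organisms)."""

    genome_size: float
    noncoding: float
    metabolic_redundancy: float
    uptake_diversity: float
    production_diversity: float
    n_organisms: int

    def to_dict(self) -> dict:
        return {
            "genome_size": self.genome_size,
            "noncoding": self.noncoding,
            "metabolic_redundancy": self.metabolic_redundancy,
            "uptake_diversity": self.uptake_diversity,
            "production_diversity": self.production_diversity,
            "n_organisms": self.n_organisms,
        }


def population_stats(world, group_filter: str | None = None) -> PopulationStats:
    """Compute mean genome/metabolism statistics over the living population.

    ``group_filter`` restricts to organisms of one trophic group ("A"/"B").
    Diversities use realized activity (the current trophic profile) restricted
    to essential (prime) tags; redundancy uses encoded expressed copies.
    """
    organisms = [o for o in world.organisms()
                 if group_filter is None or o.group == group_filter]
    if not organisms:
        raise ValueError("population_stats: empty selection")
    sizes, noncod, redund, updiv, proddiv = [], [], [], [], []
    for org in organisms:
        g = org.genome
        sizes.append(len(g))
        in_regions = 0
        for region in functional_regions(g):
            in_regions += 1 + len(region.enzyme_indices)
        noncod.append(len(g) - in_regions)
        reactions: dict[tuple, int] = {}
        for sp in org.proteins:
            key = (sp.s, sp.p, "pump_" + (sp.direction or "") if sp.is_pump else "enz")
            reactions[key] = reactions.get(key, 0) + 1
        redund.append(float(np.mean(list(reactions.values()))) if reactions else 0.0)
        if org.profile is not None:
            mt = len(org.profile.uptake)
            mask = essential_mask(mt) if mt else np.zeros(0, dtype=bool)
            primes = {i + 1 for i in range(mt) if mask[i]}
            updiv.append(len(org.profile.uptake_tags() & primes))
            proddiv.append(len(org.profile.production_tags() & primes))
        else:
            updiv.append(0)
            proddiv.append(0)
    return PopulationStats(
        genome_size=float(np.mean(sizes)),
        noncoding=float(np.mean(noncod)),
        metabolic_redundancy=float(np.mean(redund)),
        uptake_diversity=float(np.mean(updiv)),
        production_diversity=float(np.mean(proddiv)),
        n_organisms=len(organisms),
    )


def log_fitness(countsB_initial: float, countsB_final: float,
                countsA_initial: float, countsA_final: float) -> float:
    """Log ratio of fold-growths of ecotype B relative to ecotype A.

    Zero when both ecotypes grow by the same factor; positive when B outgrows
    A.  Extinct B at the start is undefined; extinct B at the end returns the
    -inf sentinel (censored).
    """
    if countsB_initial <= 0 or countsA_initial <= 0:
        raise ValueError("initial counts must be positive")
    if countsB_final <= 0:
        return float("-inf")
    if countsA_final <= 0:
        return float("inf")
    return math.log((countsB_final / countsB_initial)
                    / (countsA_final / countsA_initial))
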