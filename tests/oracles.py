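"""Brute-force oracles shared by the analysis and acceptance tests."""

import numpy as np

from evocross.analysis import GROUP_A, GROUP_B, PhyloTree


def random_tree(rng, max_leaves=64, n_events=200):
    """Random division/death history plus an independently tracked living set."""
    tree = PhyloTree()
    tree.add_root(0, birth_step=0)
    living = {0}
    next_id = 1
    for t in range(1, n_events):
        if living and rng.random() < 0.4:
            victim = sorted(living)[int(rng.integers(0, len(living)))]
            tree.record_death(victim, t)
            living.discard(victim)
        if living and len(living) < max_leaves and rng.random() < 0.6:
            parent = sorted(living)[int(rng.integers(0, len(living)))]
            c1, c2 = next_id, next_id + 1
            next_id += 2
            tree.record_division(parent, c1, c2, t)
            living.discard(parent)
            living.update((c1, c2))
        if not living:
            break
    return tree, living, n_events


def brute_force_mrca(tree):
    living = tree.living_leaves()
    ancestor_sets = [set(tree.ancestors(leaf)) for leaf in living]
    common = set.intersection(*ancestor_sets)
    return max(common, key=lambda nid: (tree.nodes[nid].birth_step,
                                        -len(tree.ancestors(nid))))


def descendant_living_leaves(tree, nid):
    out, stack = [], [nid]
    while stack:
        cur = stack.pop()
        node = tree.nodes[cur]
        if node.is_living:
            out.append(cur)
        stack.extend(node.children)
    return out


def brute_force_ps(tree, groups):
    m = brute_force_mrca(tree)
    freqs = []
    for child in tree.nodes[m].children:
        leaves = [l for l in descendant_living_leaves(tree, child)
                  if groups.get(l) in (GROUP_A, GROUP_B)]
        if not leaves:
            return None
        freqs.append(sum(1 for l in leaves if groups[l] == GROUP_B) / len(leaves))
    if len(freqs) != 2:
        return None
    return abs(freqs[0] - freqs[1])


def brute_force_founder_extinction(tree, founder_sides):
    """Which founder-subtree sides have no living descendant."""
    return [side for side in founder_sides
            if not descendant_living_leaves(tree, side)]
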