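"""Tree-evaluation statistics: resolution, support bins, monophyly, congruence.

These quantify how much of a community phylogeny's structure is realized
(resolution), how strongly its nodes are supported (cumulative support
bins), whether named taxa come out as exclusive clades (monophyly), and how
many orders sit where the reference backbone says they should (misplaced
orders, a maximum-agreement-subset computation on the ordinally reduced
tree).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .seqio_taxonomy import CommunityTaxonomy
from .trees import Tree

SUPPORT_BIN_LABELS = ("<50", ">50", "50-70", ">70", "70-85", ">85")


def resolution_fraction(tree: Tree) -> float:
    """Percentage of possible internal structure realized: 100 (I-1)/(n-2).

    I counts internal nodes including the root; a fully binary rooted tree
    has I = n-1 (100%), a star has I = 1 (0%).
    """
    n = len(tree.leaf_names())
    if n < 3:
        raise ValueError("resolution undefined for fewer than 3 tips")
    internal = len(tree.internal_nodes(include_root=True))
    return 100.0 * (internal - 1) / (n - 2)


@dataclass
class SupportBinTable:
    """Cumulative/overlapping support-category percentages for one tree.

    Boundary convention: ``<50`` is strict; ``>50``, ``>70`` and ``>85``
    include their boundary (>=); ``50-70`` is [50, 70) and ``70-85`` is
    [70, 85). Consequently (<50)+( >50) = 100 and (50-70)+(>70) = (>50).
    """

    percentages: dict[str, float]
    n_nodes: int

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(self.percentages[k] for k in SUPPORT_BIN_LABELS)


def support_bins(tree: Tree) -> SupportBinTable:
    """Bin internal-node supports into the six overlapping categories."""
    nodes = tree.internal_nodes(include_root=False)
    unsupported = [n for n in nodes if n.support is None]
    if unsupported:
        raise ValueError(f"{len(unsupported)} internal node(s) carry no support; "
                         "build a consensus first")
    s = np.array([n.support for n in nodes], dtype=float)
    k = len(s)
    if k == 0:
        return SupportBinTable({lab: 0.0 for lab in SUPPORT_BIN_LABELS}, 0)
    pct = {
        "<50": (s < 50).mean(),
        ">50": (s >= 50).mean(),
        "50-70": ((s >= 50) & (s < 70)).mean(),
        ">70": (s >= 70).mean(),
        "70-85": ((s >= 70) & (s < 85)).mean(),
        ">85": (s >= 85).mean(),
    }
    return SupportBinTable({lab: round(100.0 * v, 1) for lab, v in pct.items()}, k)


# ---------------------------------------------------------------- monophyly


@dataclass
class MonophylyReport:
    rank: str
    status: dict[str, str]  # taxon -> monophyletic | non-monophyletic | singleton

    def non_monophyletic(self) -> list[str]:
        return sorted(t for t, s in self.status.items() if s == "non-monophyletic")

    def count(self, status: str) -> int:
        return sum(1 for s in self.status.values() if s == status)


def monophyly_report(tree: Tree, taxonomy: CommunityTaxonomy, rank: str) -> MonophylyReport:
    """Monophyly status per taxon at ``rank`` among the tree's tips.

    A taxon is monophyletic iff the smallest clade containing all its tips
    contains no other tips; single-tip taxa are reported as singletons.
    """
    tips = tree.leaf_names()
    missing = [t for t in tips if t not in taxonomy]
    if missing:
        raise ValueError(f"tips absent from taxonomy: {sorted(missing)}")
    groups: dict[str, set[str]] = {}
    for tip in tips:
        groups.setdefault(taxonomy.rank_of(tip, rank), set()).add(tip)
    clade_sets = {m for m in tree.node_clade_map().values()}
    status = {}
    for name, members in groups.items():
        if len(members) == 1:
            status[name] = "singleton"
        elif frozenset(members) in clade_sets:
            status[name] = "monophyletic"
        else:
            status[name] = "non-monophyletic"
    return MonophylyReport(rank, status)


# ---------------------------------------------------------- ordinal congruence


def _reduce_to_orders(tree: Tree, taxonomy: CommunityTaxonomy) -> tuple[Tree, set[str]]:
    """One exemplar tip per order, relabelled to order names.

    For a non-monophyletic order the exemplar is the tip topologically
    closest to the order's MRCA (ties broken lexicographically) and the
    order is flagged as inherently misplaced.
    """
    tips = tree.leaf_names()
    orders: dict[str, list[str]] = {}
    for t in tips:
        orders.setdefault(taxonomy.rank_of(t, "order"), []).append(t)
    clade_map = tree.node_clade_map()
    clade_sets = set(clade_map.values())
    forced: set[str] = set()
    exemplar: dict[str, str] = {}
    for order, members in orders.items():
        if len(members) == 1:
            exemplar[order] = members[0]
            continue
        if frozenset(members) not in clade_sets:
            forced.add(order)
        mrca = tree.mrca(members)
        ranked = []  # (edge-count depth below the MRCA, tip label)
        stack = [(mrca, 0)]
        while stack:
            node, d = stack.pop()
            if node.is_leaf and node.label in members:
                ranked.append((d, node.label))
            stack.extend((c, d + 1) for c in node.children)
        exemplar[order] = min(ranked)[1]
    reduced = tree.prune_to(exemplar.values())
    rename = {tip: order for order, tip in exemplar.items()}
    for leaf in reduced.leaves():
        leaf.label = rename[leaf.label]
    return reduced, forced


def _restricted_clades(tree: Tree, subset: frozenset) -> frozenset:
    out = set()
    for c in tree.clades(nontrivial=False):
        r = c & subset
        if len(r) >= 2 and r != subset:
            out.add(r)
    return frozenset(out)


def _topologies_match(t1: Tree, t2: Tree, subset: frozenset) -> bool:
    return _restricted_clades(t1, subset) == _restricted_clades(t2, subset)


def misplaced_orders(tree: Tree, backbone: Tree,
                     taxonomy: CommunityTaxonomy, seed: int = 0,
                     exhaustive_limit: int = 12) -> tuple[int, set[str]]:
    """How many orders sit inconsistently with the reference backbone.

    The tree is reduced to one exemplar per order; the largest subset of
    orders whose induced rooted topology agrees between the reduced tree
    and the (pruned) backbone is found — exhaustively up to
    ``exhaustive_limit`` orders, by seeded simulated annealing above. The
    complement of that subset is the misplaced set; non-monophyletic orders
    are misplaced by definition.
    """
    reduced, forced = _reduce_to_orders(tree, taxonomy)
    present = frozenset(reduced.leaf_names())
    missing = present - set(backbone.leaf_names())
    if missing:
        raise ValueError(f"orders absent from backbone: {sorted(missing)}")
    bb = backbone.prune_to(present) if set(backbone.leaf_names()) != present else backbone
    candidates = sorted(present - forced)

    def agrees(subset: frozenset) -> bool:
        return _topologies_match(reduced, bb, subset)

    if len(candidates) <= exhaustive_limit:
        best = frozenset()
        for size in range(len(candidates), 0, -1):
            found = None
            for combo in itertools.combinations(candidates, size):
                if agrees(frozenset(combo)):
                    found = frozenset(combo)
                    break
            if found is not None:
                best = found
                break
        keep = best
    else:
        keep = _anneal_agreement(candidates, agrees, seed)
    mis = set(present) - set(keep)
    return len(mis), mis


def _anneal_agreement(candidates: list[str], agrees, seed: int,
                      steps: int = 2000) -> frozenset:
    """Seeded annealing over inclusion vectors, maximizing agreeing-set size."""
    rng = np.random.default_rng(seed)
    cur = [True] * len(candidates)

    def valid_size(flags) -> int:
        sub = frozenset(c for c, f in zip(candidates, flags) if f)
        if len(sub) >= 2 and not agrees(sub):
            return -1
        return len(sub)

    # start from a greedy valid configuration
    while valid_size(cur) < 0:
        on = [i for i, f in enumerate(cur) if f]
        cur[on[int(rng.integers(len(on)))]] = False
    best = list(cur)
    cur_size, best_size = valid_size(cur), valid_size(cur)
    for step in range(steps):
        temp = max(0.01, 1.0 - step / steps)
        i = int(rng.integers(len(candidates)))
        cur[i] = not cur[i]
        size = valid_size(cur)
        if size >= 0 and (size >= cur_size or rng.random() < np.exp((size - cur_size) / temp)):
            cur_size = size
            if size > best_size:
                best, best_size = list(cur), size
        else:
            cur[i] = not cur[i]
    return frozenset(c for c, f in zip(candidates, best) if f)
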