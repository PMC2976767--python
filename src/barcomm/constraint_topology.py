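"""Ordinal constraint trees and candidate-tree compatibility.

The constraint carries only between-order structure: an accepted ordinal
backbone (tips = order names) is expanded so each order becomes a polytomy
over its sampled species. A candidate tree is compatible when it refines
the constraint, i.e. every non-trivial constraint clade appears among the
candidate's clades (rooted semantics; the backbone supplies the root).
"""

from __future__ import annotations

from typing import Iterable

from .seqio_taxonomy import CommunityTaxonomy
from .trees import Node, Tree


def build_constraint(backbone: Tree, taxonomy: CommunityTaxonomy,
                     included_species: Iterable[str]) -> Tree:
    """Expand backbone order tips into species polytomies.

    Orders with no included species are pruned; an order with one species
    becomes a pendant tip. Order names are kept as internal node labels
    for readability; they are ignored by compatibility checks.
    """
    included = sorted(set(included_species))
    by_order: dict[str, list[str]] = {}
    backbone_orders = set(backbone.leaf_names())
    for sp in included:
        order = taxonomy.rank_of(sp, "order")
        if order not in backbone_orders:
            raise ValueError(f"species {sp!r} has order {order!r} absent from backbone")
        by_order.setdefault(order, []).append(sp)

    pruned = backbone.prune_to(by_order.keys())
    for leaf in pruned.leaves():
        members = by_order[leaf.label]
        if len(members) == 1:
            leaf.label = members[0]
        else:
            order_name = leaf.label
            leaf.label = order_name  # becomes internal label
            for sp in members:
                leaf.add_child(Node(label=sp))
    # a single-order community collapses to a bare star
    pruned.suppress_unifurcations()
    return pruned


def is_compatible(candidate: Tree, constraint: Tree) -> bool:
    """True iff the candidate contains every non-trivial constraint clade."""
    cand_tips = set(candidate.leaf_names())
    cons_tips = set(constraint.leaf_names())
    if cand_tips != cons_tips:
        diff = sorted(cand_tips.symmetric_difference(cons_tips))
        raise ValueError(f"tip sets differ; symmetric difference: {diff}")
    cand_clades = candidate.clades(nontrivial=True)
    return all(c in cand_clades for c in constraint.clades(nontrivial=True))


def contract_to_orders(tree: Tree, taxonomy: CommunityTaxonomy) -> Tree:
    """Collapse each order's (monophyletic) species clade to one order tip."""
    orders: dict[str, set[str]] = {}
    for tip in tree.leaf_names():
        orders.setdefault(taxonomy.rank_of(tip, "order"), set()).add(tip)
    clade_map = tree.node_clade_map()
    out = tree.copy()
    out_map = out.node_clade_map()
    by_set = {out_map[id(n)]: n for n in out.postorder()}
    for order, tips in orders.items():
        want = frozenset(tips)
        if len(tips) == 1:
            node = by_set[want]
        else:
            if want not in by_set:
                raise ValueError(f"order {order!r} is not monophyletic; cannot contract")
            node = by_set[want]
        node.children = []
        node.label = order
    out.suppress_unifurcations()
    return out
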