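"""Maximum-parsimony scoring and constrained tree search with a parsimony ratchet.

Characters are encoded as 4-bit state sets (A=1, C=2, G=4, T=8); IUPAC
ambiguity codes are partial sets and ``?``/``-``/``N`` the full set, so
gaps and missing data are interchangeable for scoring. Tree length is the
Fitch set count at binary nodes and Hartigan's majority-vote generalization
at polytomies; both are exact for unit-cost unordered characters.

The search is a parsimony ratchet: from each random-addition starting tree,
hill-climbing (NNI, optionally SPR) alternates between the original column
weights and a seeded perturbation in which a random fraction of columns is
upweighted, which lets the search escape local optima while the constraint
filter keeps every visited tree compatible with the ordinal backbone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .constraint_topology import is_compatible
from .supermatrix import SuperMatrix
from .trees import Node, Tree, enumerate_binary_refinements

_STATE_BITS = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8, "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15, "?": 15, "-": 15, "X": 15,
}
_BIT_COLS = np.array([[1], [2], [4], [8]], dtype=np.uint8)


# ----------------------------------------------------------------- encoding


def _matrix_rows(matrix) -> tuple[list[str], list[str]]:
    if isinstance(matrix, SuperMatrix):
        return matrix.species, matrix.rows
    # duck-typed Alignment
    return list(matrix.taxa), list(matrix.rows)


def encode_matrix(matrix, taxa: Optional[Sequence[str]] = None) -> tuple[np.ndarray, dict[str, int]]:
    """Encode rows as a (ntax, ncols) uint8 state-set array."""
    all_taxa, rows = _matrix_rows(matrix)
    if taxa is None:
        taxa = all_taxa
    lookup = dict(zip(all_taxa, rows))
    missing = [t for t in taxa if t not in lookup]
    if missing:
        raise ValueError(f"taxa absent from matrix: {sorted(missing)}")
    try:
        enc = np.array([[_STATE_BITS[c] for c in lookup[t].upper()] for t in taxa],
                       dtype=np.uint8)
    except KeyError as e:
        raise ValueError(f"unknown character state {e.args[0]!r}") from None
    return enc, {t: i for i, t in enumerate(taxa)}


def _compress(enc: np.ndarray, weights: Optional[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Collapse duplicate columns, summing weights; drops nothing else."""
    if weights is None:
        weights = np.ones(enc.shape[1], dtype=np.int64)
    cols, inverse = np.unique(enc.T, axis=0, return_inverse=True)
    w = np.bincount(inverse.ravel(), weights=weights).astype(np.int64)
    return cols.T.copy(), w


def _node_cost_mask(children: list[np.ndarray], weights: np.ndarray) -> tuple[int, np.ndarray]:
    if len(children) == 2:
        a, b = children
        inter = a & b
        disjoint = inter == 0
        cost = int(weights[disjoint].sum())
        return cost, np.where(disjoint, a | b, inter)
    stack = np.stack(children)
    votes = np.stack([((stack >> b) & 1).sum(axis=0) for b in range(4)])
    mx = votes.max(axis=0)
    cost = int((weights * (len(children) - mx)).sum())
    mask = ((votes == mx).astype(np.uint8) * _BIT_COLS).sum(axis=0).astype(np.uint8)
    return cost, mask


def _score_tree(tree: Tree, enc: np.ndarray, tindex: dict[str, int],
                weights: np.ndarray) -> int:
    total = 0
    masks: dict[int, np.ndarray] = {}
    for n in tree.postorder():
        if n.is_leaf:
            masks[id(n)] = enc[tindex[n.label]]
        else:
            cost, mask = _node_cost_mask([masks[id(c)] for c in n.children], weights)
            total += cost
            masks[id(n)] = mask
    return total


def parsimony_length(tree: Tree, matrix, weights: Optional[Sequence[int]] = None) -> int:
    """Minimum number of state changes for ``matrix`` on ``tree``.

    ``weights`` are optional non-negative integer column weights. Tips must
    be a subset of the matrix's species; columns are compared only across
    the tree's tips, so taxa absent from the tree are ignored.
    """
    tips = tree.leaf_names()
    enc, tindex = encode_matrix(matrix, taxa=tips)
    w = None if weights is None else np.asarray(weights, dtype=np.int64)
    if w is not None and len(w) != enc.shape[1]:
        raise ValueError("weights length does not match column count")
    cenc, cw = _compress(enc, w)
    return _score_tree(tree, cenc, tindex, cw)


# ------------------------------------------------------------ search config


@dataclass
class SearchConfig:
    """Knobs for the constrained ratchet search.

    ``n_addition_replicates`` random-addition starts, each followed by
    ``ratchet_iterations`` perturb/restore cycles. ``perturb_fraction`` of
    columns get their weight multiplied by ``perturb_weight`` during the
    perturbed phase. ``spr_sample`` caps the number of SPR rearrangements
    examined per sweep (None = the full neighborhood).
    """

    n_addition_replicates: int = 200
    ratchet_iterations: int = 50
    perturb_fraction: float = 0.25
    perturb_weight: int = 2
    seed: int = 0
    max_retained: int = 10_000
    use_spr: bool = True
    spr_sample: Optional[int] = None

    def __post_init__(self):
        if self.n_addition_replicates < 1 or self.ratchet_iterations < 0:
            raise ValueError("replicate/iteration counts must be >= 1")
        if not 0.0 < self.perturb_fraction < 1.0:
            raise ValueError("perturb_fraction must lie in (0, 1)")
        if self.perturb_weight < 1:
            raise ValueError("perturb_weight must be >= 1")


@dataclass
class TreeSet:
    """Equally most-parsimonious trees sharing one score."""

    trees: list[Tree]
    score: int

    def __post_init__(self):
        if not self.trees:
            raise ValueError("empty tree set")
        tipsets = {frozenset(t.leaf_names()) for t in self.trees}
        if len(tipsets) != 1:
            raise ValueError("trees in a TreeSet must share one tip set")

    def __len__(self):
        return len(self.trees)


# --------------------------------------------------- constraint bookkeeping


def _constraint_masks(constraint: Tree, tindex: dict[str, int]) -> list[int]:
    """Non-trivial constraint clades as integer bitsets over taxon indices."""
    out = []
    n = len(tindex)
    for clade in constraint.clades(nontrivial=True):
        m = 0
        for t in clade:
            m |= 1 << tindex[t]
        out.append(m)
    return out


def _tip_bitsets(tree: Tree, tindex: dict[str, int]) -> dict[int, int]:
    bits: dict[int, int] = {}
    for n in tree.postorder():
        if n.is_leaf:
            bits[id(n)] = 1 << tindex[n.label]
        else:
            m = 0
            for c in n.children:
                m |= bits[id(c)]
            bits[id(n)] = m
    return bits


def _compatible_bits(tree: Tree, cons_masks: list[int], tindex: dict[str, int]) -> bool:
    """Does the tree contain every (restricted) constraint clade?"""
    bits = _tip_bitsets(tree, tindex)
    present = set(bits.values())
    full = bits[id(tree.root)]
    for m in cons_masks:
        mr = m & full
        if mr.bit_count() >= 2 and mr != full and mr not in present:
            return False
    return True


# ------------------------------------------------------- stepwise addition


class _AdditionScorer:
    """Cached Fitch state sets; evaluates leaf insertions by path re-scoring."""

    def __init__(self, tree: Tree, enc, tindex, weights):
        self.tree, self.enc, self.tindex, self.weights = tree, enc, tindex, weights
        self.rebuild()

    def rebuild(self):
        self.masks: dict[int, np.ndarray] = {}
        self.costs: dict[int, int] = {}
        self.total = 0
        for n in self.tree.postorder():
            if n.is_leaf:
                self.masks[id(n)] = self.enc[self.tindex[n.label]]
            else:
                c, m = _node_cost_mask([self.masks[id(ch)] for ch in n.children], self.weights)
                self.costs[id(n)] = c
                self.masks[id(n)] = m
                self.total += c

    def insert_score(self, x_mask: np.ndarray, edge_child: Optional[Node]) -> int:
        """Tree length after inserting a leaf, without mutating the tree."""
        if edge_child is None:  # join above the root
            c, _ = _node_cost_mask([self.masks[id(self.tree.root)], x_mask], self.weights)
            return self.total + c
        cost0, cur = _node_cost_mask([self.masks[id(edge_child)], x_mask], self.weights)
        total = self.total + cost0
        child, anc = edge_child, edge_child.parent
        while anc is not None:
            kids = [cur if ch is child else self.masks[id(ch)] for ch in anc.children]
            c, m = _node_cost_mask(kids, self.weights)
            total += c - self.costs[id(anc)]
            if np.array_equal(m, self.masks[id(anc)]):
                break
            cur, child, anc = m, anc, anc.parent
        return total


def random_addition_tree(matrix, constraint: Tree, seed: int) -> Tree:
    """Binary constraint-compatible starting tree by seeded stepwise addition.

    Taxa are shuffled with the seed, then each is inserted at the
    compatible position of minimum parsimony length (ties to the first
    position in postorder).
    """
    taxa = sorted(constraint.leaf_names())
    enc_full, tindex = encode_matrix(matrix, taxa=taxa)
    enc, weights = _compress(enc_full, None)
    cons_masks = _constraint_masks(constraint, tindex)
    rng = np.random.default_rng(seed)
    order = [taxa[i] for i in rng.permutation(len(taxa))]

    tree = Tree(Node(label=order[0]))
    for x in order[1:]:
        x_mask = enc[tindex[x]]
        scorer = _AdditionScorer(tree, enc, tindex, weights)
        best = None
        # candidate edges: every non-root node, plus the root join (None)
        for edge_child in list(tree.edges()) + [None]:
            _insert_leaf(tree, Node(label=x), edge_child)
            ok = _compatible_bits(tree, cons_masks, tindex)
            _undo_insert(tree, edge_child)
            if not ok:
                continue
            s = scorer.insert_score(x_mask, edge_child)
            if best is None or s < best[0]:
                best = (s, edge_child)
        if best is None:
            raise RuntimeError("no compatible insertion position (invalid constraint?)")
        _insert_leaf(tree, Node(label=x), best[1])
    return tree


def _insert_leaf(tree: Tree, leaf: Node, edge_child: Optional[Node]) -> None:
    if edge_child is None:
        tree.root = Node(children=[tree.root, leaf])
    else:
        p = edge_child.parent
        mid = Node()
        idx = p.children.index(edge_child)
        p.children[idx] = mid
        mid.parent = p
        mid.add_child(edge_child)
        mid.add_child(leaf)


def _undo_insert(tree: Tree, edge_child: Optional[Node]) -> None:
    if edge_child is None:
        old = tree.root.children[0]
        old.parent = None
        tree.root = old
    else:
        mid = edge_child.parent
        p = mid.parent
        idx = p.children.index(mid)
        p.children[idx] = edge_child
        edge_child.parent = p


# ------------------------------------------------------------- hill climbing


def _nni_moves(tree: Tree):
    """(parent, vi, v, ci) swaps: child ci of internal node v with v's sibling."""
    for v in tree.internal_nodes(include_root=False):
        p = v.parent
        for si, s in enumerate(p.children):
            if s is v:
                continue
            for ci in range(len(v.children)):
                yield (p, si, v, ci)


def _apply_nni(p: Node, si: int, v: Node, ci: int) -> None:
    s, c = p.children[si], v.children[ci]
    p.children[si], v.children[ci] = c, s
    c.parent, s.parent = p, v


def _hill_climb(tree: Tree, enc, tindex, weights, cons_masks, rng,
                use_spr: bool, spr_sample: Optional[int]) -> tuple[Tree, int]:
    """First-improvement NNI (+ SPR) descent under the constraint filter."""
    score = _score_tree(tree, enc, tindex, weights)
    improved = True
    while improved:
        improved = False
        # --- NNI sweep
        for p, si, v, ci in list(_nni_moves(tree)):
            # earlier accepted moves in this sweep can stale the tuple
            if v.parent is not p or p.children[si] is v:
                continue
            _apply_nni(p, si, v, ci)
            if _compatible_bits(tree, cons_masks, tindex):
                s = _score_tree(tree, enc, tindex, weights)
                if s < score:
                    score = s
                    improved = True
                    continue
            _apply_nni(p, si, v, ci)  # undo (swap is an involution)
        if improved or not use_spr:
            continue
        # --- SPR sweep on a copy-per-move basis
        nodes = tree.edges()
        moves = []
        for i, prune in enumerate(nodes):
            for j, regraft in enumerate(nodes):
                if i != j:
                    moves.append((i, j, False))
            moves.append((i, None, True))  # regraft above the root
        if spr_sample is not None and len(moves) > spr_sample:
            pick = rng.choice(len(moves), size=spr_sample, replace=False)
            moves = [moves[k] for k in sorted(pick)]
        for i, j, at_root in moves:
            cand = tree.copy()
            cnodes = cand.edges()
            prune = cnodes[i]
            target = None if at_root else cnodes[j]
            # skip if regraft target is inside the pruned subtree
            sub = set(map(id, _subtree_nodes(prune)))
            if target is not None and id(target) in sub:
                continue
            cand.detach(prune)
            prune.parent = None
            # suppression during detach may have removed or re-rooted nodes
            remaining = set(map(id, _subtree_nodes(cand.root)))
            if target is not None and id(target) not in remaining:
                continue
            if target is None or target.parent is None:
                cand.attach_at_root(prune)
            else:
                cand.attach_on_edge(prune, target)
            if not _compatible_bits(cand, cons_masks, tindex):
                continue
            s = _score_tree(cand, enc, tindex, weights)
            if s < score:
                tree, score = cand, s
                improved = True
                break
    return tree, score


def _subtree_nodes(root: Node) -> list[Node]:
    out, stack = [], [root]
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(n.children)
    return out


# ------------------------------------------------------------------ ratchet


def ratchet_search(matrix, constraint: Tree, config: SearchConfig) -> TreeSet:
    """Constrained parsimony-ratchet search; returns the pooled best trees."""
    taxa = sorted(constraint.leaf_names())
    enc_full, tindex = encode_matrix(matrix, taxa=taxa)
    enc, base_w = _compress(enc_full, None)
    cons_masks = _constraint_masks(constraint, tindex)
    ncols = enc.shape[1]

    best_score = None
    pool: dict[str, Tree] = {}

    def record(tree: Tree, score: int):
        nonlocal best_score
        if best_score is None or score < best_score:
            best_score = score
            pool.clear()
        if score == best_score:
            key = tree.canonical_form()
            if key not in pool:
                if len(pool) >= config.max_retained:
                    # deterministic eviction: drop the canonically largest
                    worst = max(pool)
                    if key < worst:
                        del pool[worst]
                    else:
                        return
                pool[key] = tree.copy()

    for rep in range(config.n_addition_replicates):
        rep_seed = config.seed + rep
        rng = np.random.default_rng((config.seed, rep))
        tree = random_addition_tree(matrix, constraint, seed=rep_seed)
        tree, score = _hill_climb(tree, enc, tindex, base_w, cons_masks, rng,
                                  config.use_spr, config.spr_sample)
        record(tree, score)
        for _ in range(config.ratchet_iterations):
            k = max(1, int(round(config.perturb_fraction * ncols)))
            idx = rng.choice(ncols, size=k, replace=False)
            pw = base_w.copy()
            pw[idx] *= config.perturb_weight
            t2 = tree.copy()
            t2, _ = _hill_climb(t2, enc, tindex, pw, cons_masks, rng,
                                config.use_spr, config.spr_sample)
            t2, s2 = _hill_climb(t2, enc, tindex, base_w, cons_masks, rng,
                                 config.use_spr, config.spr_sample)
            record(t2, s2)
            if s2 <= score:
                tree, score = t2, s2

    trees = [pool[k] for k in sorted(pool)]
    for t in trees:
        assert is_compatible(t, constraint)
    return TreeSet(trees=trees, score=int(best_score))


def exhaustive_constrained_search(matrix, constraint: Tree) -> TreeSet:
    """Score every binary refinement of the constraint; exact but tiny-n only."""
    taxa = sorted(constraint.leaf_names())
    enc_full, tindex = encode_matrix(matrix, taxa=taxa)
    enc, w = _compress(enc_full, None)
    best, trees = None, []
    for t in enumerate_binary_refinements(constraint):
        s = _score_tree(t, enc, tindex, w)
        if best is None or s < best:
            best, trees = s, [t]
        elif s == best:
            trees.append(t)
    # refinements of distinct polytomy resolutions can coincide as rooted
    # topologies only if the constraint had none; dedupe regardless
    uniq = {t.canonical_form(): t for t in trees}
    return TreeSet(trees=[uniq[k] for k in sorted(uniq)], score=int(best))


# ---------------------------------------------------------------- consensus


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _tree_from_clades(tips: list[str], clades: dict[frozenset, float]) -> Tree:
    """Rooted tree realizing a nested (compatible) clade collection."""
    items: list[tuple[frozenset, Node]] = [(frozenset([t]), Node(label=t)) for t in tips]
    for clade in sorted(clades, key=len):
        members = [(s, n) for s, n in items if s <= clade]
        node = Node(children=[n for _, n in members])
        node.support = clades[clade]
        items = [(s, n) for s, n in items if not s <= clade]
        items.append((clade, node))
    if len(items) == 1 and len(items[0][0]) == len(tips):
        root = items[0][1]
    else:
        root = Node(children=[n for _, n in items])
        root.support = 100.0
    return Tree(root)


def majority_consensus(trees: TreeSet, threshold: float = 0.5,
                       extended: bool = False) -> Tree:
    """Majority-rule consensus with clade-frequency supports.

    Clades occurring in strictly more than ``threshold`` of the input trees
    are retained; node support is the rounded percentage frequency. With
    ``extended`` the remaining clades are added greedily in descending
    frequency when compatible (majority-rule-extended).
    """
    n = len(trees.trees)
    tips = sorted(trees.trees[0].leaf_names())
    counts: dict[frozenset, int] = {}
    for t in trees.trees:
        for c in t.clades(nontrivial=True):
            counts[c] = counts.get(c, 0) + 1
    kept: dict[frozenset, float] = {}
    for c, k in counts.items():
        if k / n > threshold:
            kept[c] = float(_round_half_up(100.0 * k / n))
    if extended:
        rest = sorted((c for c in counts if c not in kept),
                      key=lambda c: (-counts[c], -len(c), tuple(sorted(c))))
        for c in rest:
            if all(c <= o or o <= c or not (c & o) for o in kept):
                kept[c] = float(_round_half_up(100.0 * counts[c] / n))
    return _tree_from_clades(tips, kept)
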