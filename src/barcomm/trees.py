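"""Rooted trees with polytomies: the shared container for constraints, search and metrics.

Newick reading goes through dendropy; this module only adds the light
mutable structure (parent pointers, clade bitsets, rearrangement surgery)
that the parsimony search needs and that a general-purpose phylogenetics
library does not expose cheaply.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Iterator, Optional

import dendropy

__all__ = ["Node", "Tree", "enumerate_binary_refinements"]


class Node:
    __slots__ = ("label", "children", "parent", "length", "support")

    def __init__(
        self,
        label: Optional[str] = None,
        children: Optional[list["Node"]] = None,
        length: Optional[float] = None,
        support: Optional[float] = None,
    ):
        self.label = label
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.length = length
        self.support = support
        if children:
            for c in children:
                self.add_child(c)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.label or '*'} deg={len(self.children)}>"


class Tree:
    """A rooted tree over uniquely labelled tips."""

    def __init__(self, root: Node):
        self.root = root

    # ------------------------------------------------------------------ io
    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dt = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        return cls.from_dendropy(dt)

    @classmethod
    def read(cls, path) -> "Tree":
        dt = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
        return cls.from_dendropy(dt)

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Tree":
        def conv(dnode) -> Node:
            label = None
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            n = Node(label=label, length=dnode.edge.length)
            for dc in dnode.child_nodes():
                n.add_child(conv(dc))
            if n.children and n.label is not None:
                # numeric internal labels are node supports by convention
                try:
                    n.support = float(n.label)
                except ValueError:
                    pass
                else:
                    n.label = None
            return n

        return cls(conv(dtree.seed_node))

    def to_newick(self, supports: bool = False, lengths: bool = False) -> str:
        def fmt(n: Node) -> str:
            if n.is_leaf:
                s = n.label or ""
            else:
                inner = ",".join(fmt(c) for c in n.children)
                lab = ""
                if supports and n.support is not None:
                    lab = format(n.support, "g")
                elif n.label:
                    lab = n.label
                s = f"({inner}){lab}"
            if lengths and n.length is not None:
                s += f":{n.length:g}"
            return s

        return fmt(self.root) + ";"

    def to_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.to_newick(lengths=True),
            schema="newick",
            taxon_namespace=taxon_namespace,
            preserve_underscores=True,
        )

    def write(self, path, **kw) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(**kw) + "\n")

    # ------------------------------------------------------------ traversal
    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return reversed(out)

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def internal_nodes(self, include_root: bool = True) -> list[Node]:
        out = [n for n in self.postorder() if not n.is_leaf]
        if not include_root:
            out = [n for n in out if n is not self.root]
        return out

    def edges(self) -> list[Node]:
        """Edges identified by their child node (every non-root node)."""
        return [n for n in self.postorder() if n is not self.root]

    # --------------------------------------------------------------- clades
    def clades(self, nontrivial: bool = True) -> set[frozenset]:
        """Tip-name sets subtended by internal nodes.

        With ``nontrivial`` only clades of size >= 2 that are proper
        subsets of the full tip set are returned.
        """
        all_tips = frozenset(self.leaf_names())
        sets: dict[int, frozenset] = {}
        out: set[frozenset] = set()
        for n in self.postorder():
            if n.is_leaf:
                sets[id(n)] = frozenset([n.label])
            else:
                s = frozenset().union(*(sets[id(c)] for c in n.children))
                sets[id(n)] = s
                if not nontrivial or (len(s) >= 2 and s != all_tips):
                    out.add(s)
        return out

    def node_clade_map(self) -> dict[int, frozenset]:
        sets: dict[int, frozenset] = {}
        for n in self.postorder():
            if n.is_leaf:
                sets[id(n)] = frozenset([n.label])
            else:
                sets[id(n)] = frozenset().union(*(sets[id(c)] for c in n.children))
        return sets

    def mrca(self, names: Iterable[str]) -> Node:
        want = frozenset(names)
        sets = self.node_clade_map()
        best, best_size = None, None
        for n in self.postorder():
            s = sets[id(n)]
            if want <= s and (best_size is None or len(s) < best_size):
                best, best_size = n, len(s)
        if best is None:
            raise ValueError(f"tips not in tree: {sorted(want)}")
        return best

    # -------------------------------------------------------------- surgery
    def copy(self) -> "Tree":
        def dup(n: Node) -> Node:
            m = Node(label=n.label, length=n.length, support=n.support)
            for c in n.children:
                m.add_child(dup(c))
            return m

        return Tree(dup(self.root))

    def suppress_unifurcations(self) -> None:
        # merge chains of out-degree-1 nodes, preserving summed branch lengths
        changed = True
        while changed:
            changed = False
            for n in list(self.preorder()):
                if not n.is_leaf and len(n.children) == 1:
                    child = n.children[0]
                    if child.length is not None and n.length is not None:
                        child.length += n.length
                    if n.parent is None:
                        child.parent = None
                        self.root = child
                    else:
                        p = n.parent
                        idx = p.children.index(n)
                        p.children[idx] = child
                        child.parent = p
                    changed = True
                    break

    def prune_to(self, keep: Iterable[str]) -> "Tree":
        """Induced rooted tree on the tip subset ``keep`` (copy)."""
        keep = set(keep)
        t = self.copy()
        for leaf in t.leaves():
            if leaf.label not in keep:
                p = leaf.parent
                if p is None:
                    raise ValueError("cannot prune every tip")
                p.remove_child(leaf)
        # drop now-empty internal nodes bottom-up
        changed = True
        while changed:
            changed = False
            for n in list(t.postorder()):
                if not n.children and n.label not in keep and n.parent is not None:
                    n.parent.remove_child(n)
                    changed = True
        t.suppress_unifurcations()
        return t

    def detach(self, node: Node) -> None:
        """Remove the subtree at ``node``; suppress the vacated unifurcation."""
        p = node.parent
        if p is None:
            raise ValueError("cannot detach the root")
        p.remove_child(node)
        if len(p.children) == 1:
            self.suppress_unifurcations()

    def attach_on_edge(self, subtree: Node, edge_child: Node) -> None:
        """Insert ``subtree`` by bisecting the edge above ``edge_child``."""
        p = edge_child.parent
        if p is None:
            raise ValueError("edge above the root does not exist")
        mid = Node()
        idx = p.children.index(edge_child)
        p.children[idx] = mid
        mid.parent = p
        mid.add_child(edge_child)
        mid.add_child(subtree)

    def attach_at_root(self, subtree: Node) -> None:
        new_root = Node(children=[self.root, subtree])
        self.root = new_root

    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes())

    def canonical_form(self) -> str:
        """Rotation-invariant serialization; equal iff same rooted topology."""

        def key(n: Node) -> str:
            if n.is_leaf:
                return n.label
            return "(" + ",".join(sorted(key(c) for c in n.children)) + ")"

        return key(self.root)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Tree):
            return NotImplemented
        return self.canonical_form() == other.canonical_form()

    def __hash__(self):
        return hash(self.canonical_form())

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tree({self.to_newick()})"


def _copy_subtree(n: Node) -> Node:
    m = Node(label=n.label, length=n.length, support=n.support)
    for c in n.children:
        m.add_child(_copy_subtree(c))
    return m


def _all_nodes(root: Node) -> list[Node]:
    out, stack = [], [root]
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(n.children)
    return out


def _resolutions(subtrees: list[Node]) -> Iterator[Node]:
    """All rooted binary trees whose leaves are the given subtrees (as units).

    Standard edge-insertion enumeration: (2k-3)!! rooted shapes for k units.
    """
    if len(subtrees) == 1:
        yield _copy_subtree(subtrees[0])
        return
    for partial in _resolutions(subtrees[:-1]):
        # insertion positions: bisect any non-root edge, or join above root
        n_edges = len(_all_nodes(partial)) - 1
        for pos in range(n_edges + 1):
            root = _copy_subtree(partial)
            newleaf = _copy_subtree(subtrees[-1])
            if pos == n_edges:
                yield Node(children=[root, newleaf])
            else:
                target = [n for n in _all_nodes(root) if n.parent is not None][pos]
                p = target.parent
                mid = Node()
                idx = p.children.index(target)
                p.children[idx] = mid
                mid.parent = p
                mid.add_child(target)
                mid.add_child(newleaf)
                yield root


def enumerate_binary_refinements(tree: Tree) -> Iterator[Tree]:
    """Every rooted binary tree refining ``tree`` (its polytomies resolved).

    Each multifurcation is resolved independently; the product over
    polytomies of (2k-3)!! shapes is generated. Intended for small
    constraint trees where exhaustive search is the oracle.
    """

    def expand(n: Node) -> Iterator[Node]:
        if n.is_leaf:
            yield Node(label=n.label)
            return
        child_variants = [list(expand(c)) for c in n.children]
        for combo in itertools.product(*child_variants):
            if len(combo) == 1:
                yield _copy_subtree(combo[0])
            elif len(combo) == 2:
                yield Node(children=[_copy_subtree(c) for c in combo])
            else:
                yield from _resolutions(list(combo))

    for r in expand(tree.root):
        yield Tree(r)
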