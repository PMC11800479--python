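"""Lightweight phylogenetic tree container used across the pipeline.

Nodes carry branch lengths and an optional *dual* support pair
``(aLRT-like %, bootstrap %)`` serialized in Newick as an internal label of
the form ``"80/95"`` (a bare ``"87"`` is read as a single bootstrap-style
support with the first slot absent). Parsing is delegated to dendropy;
writing is a small local serializer that emits the dual-label dialect.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator

import dendropy

__all__ = ["Node", "Tree", "read_newick", "write_newick", "NewickError"]


class NewickError(ValueError):
    pass


@dataclass
class Node:
    name: str | None = None
    length: float = 0.0
    support: tuple[float | None, float | None] | None = None
    children: list["Node"] = field(default_factory=list)
    parent: "Node | None" = field(default=None, repr=False)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child


class Tree:
    """Rooted or unrooted tree (unrooted = root is a basal multifurcation)."""

    def __init__(self, root: Node, rooted: bool = True,
                 taxon_map: dict[str, tuple[int, str]] | None = None):
        self.root = root
        self.rooted = rooted
        #: leaf name -> (taxid, species label); optional
        self.taxon_map = taxon_map or {}

    # ------------------------------------------------------------------ basics
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
        return [n.name for n in self.leaves()]

    def find_leaf(self, name: str) -> Node:
        for n in self.leaves():
            if n.name == name:
                return n
        raise KeyError(f"leaf {name!r} not in tree")

    def copy(self) -> "Tree":
        def clone(n: Node) -> Node:
            c = Node(n.name, n.length, n.support)
            for ch in n.children:
                c.add(clone(ch))
            return c

        return Tree(clone(self.root), self.rooted, dict(self.taxon_map))

    # ----------------------------------------------------------- bipartitions
    def bipartitions(self, include_trivial: bool = False) -> set[frozenset[str]]:
        """Unrooted bipartitions, each encoded as the side *not* containing
        the lexicographically smallest leaf (canonical form)."""
        names = set(self.leaf_names())
        anchor = min(names)
        out: set[frozenset[str]] = set()
        below: dict[int, set[str]] = {}
        for n in self.postorder():
            if n.is_leaf:
                below[id(n)] = {n.name}
            else:
                s: set[str] = set()
                for c in n.children:
                    s |= below[id(c)]
                below[id(n)] = s
            side = below[id(n)]
            if n is self.root:
                continue
            if not include_trivial and (len(side) < 2 or len(side) > len(names) - 2):
                continue
            canon = frozenset(side if anchor not in side else names - side)
            out.add(canon)
        return out

    def clade_leaf_sets(self) -> dict[int, set[str]]:
        """id(node) -> set of descendant leaf names (leaves map to themselves)."""
        below: dict[int, set[str]] = {}
        for n in self.postorder():
            if n.is_leaf:
                below[id(n)] = {n.name}
            else:
                s: set[str] = set()
                for c in n.children:
                    s |= below[id(c)]
                below[id(n)] = s
        return below

    def is_monophyletic(self, leaf_set: set[str]) -> bool:
        """Rooted trees: some node's descendant leaves equal ``leaf_set``.
        Unrooted trees: the bipartition ``leaf_set | complement`` exists.
        Singleton sets are monophyletic by convention."""
        names = set(self.leaf_names())
        missing = set(leaf_set) - names
        if missing:
            raise KeyError(f"leaves not in tree: {sorted(missing)}")
        if len(leaf_set) <= 1 or leaf_set == names:
            return True
        target = frozenset(leaf_set)
        if self.rooted:
            return any(s == target for s in self.clade_leaf_sets().values())
        comp = frozenset(names - leaf_set)
        sets = set(map(frozenset, self.clade_leaf_sets().values()))
        return target in sets or comp in sets

    def mrca(self, leaf_names: set[str]) -> Node:
        """Smallest clade containing all named leaves (rooted trees)."""
        below = self.clade_leaf_sets()
        best: Node | None = None
        best_size = None
        for n in self.postorder():
            if set(leaf_names) <= below[id(n)]:
                if best is None or len(below[id(n)]) < best_size:
                    best, best_size = n, len(below[id(n)])
        if best is None:
            raise KeyError("leaves not all present")
        return best

    # -------------------------------------------------------------- distances
    def leaf_distances(self) -> tuple[list[str], dict[tuple[str, str], float]]:
        """All pairwise leaf-to-leaf path lengths."""
        names = self.leaf_names()
        dist: dict[tuple[str, str], float] = {}
        # distances from each node down to its descendant leaves
        down: dict[int, dict[str, float]] = {}
        for n in self.postorder():
            if n.is_leaf:
                down[id(n)] = {n.name: 0.0}
            else:
                d: dict[str, float] = {}
                for c in n.children:
                    for leaf, x in down[id(c)].items():
                        d[leaf] = x + c.length
                down[id(n)] = d
                kids = n.children
                for i in range(len(kids)):
                    for j in range(i + 1, len(kids)):
                        for la, xa in down[id(kids[i])].items():
                            for lb, xb in down[id(kids[j])].items():
                                key = (min(la, lb), max(la, lb))
                                dist[key] = xa + kids[i].length + xb + kids[j].length
        return names, dist

    # ---------------------------------------------------------------- rooting
    def midpoint_root(self) -> "Tree":
        """Root at the midpoint of the longest leaf-to-leaf path.

        Ties are broken by the lexicographically smaller endpoint pair. If
        every branch length is zero, the root is placed on the first
        internal edge.
        """
        t = self.copy()
        names, dist = t.leaf_distances()
        if len(names) < 2:
            t.rooted = True
            return t
        pairs = sorted(dist.items(), key=lambda kv: (-kv[1], kv[0]))
        (a, b), total = pairs[0]
        if total == 0.0:
            edges = [n for n in t.postorder() if n is not t.root]
            target, offset = edges[0], 0.0
        else:
            # walk from leaf a toward b, find edge containing the midpoint;
            # edges before the LCA are traversed child->parent, edges after
            # parent->child, so the offset from the child end differs
            path = t._path(a, b)
            half = total / 2.0
            acc = 0.0
            target, offset = None, 0.0
            for node, upward in path:
                if acc + node.length >= half - 1e-12:
                    along = half - acc  # distance from the near end
                    offset = along if upward else node.length - along
                    target = node
                    break
                acc += node.length
            if target is None:  # numerical edge: root at far end
                target, offset = path[-1][0], 0.0
        return t._reroot_on_edge(target, offset)

    def _path(self, leaf_a: str, leaf_b: str) -> list[tuple[Node, bool]]:
        """Edges (child-node, walking-upward flag) from leaf_a to leaf_b."""
        na, nb = self.find_leaf(leaf_a), self.find_leaf(leaf_b)
        anc_a = []
        x = na
        while x is not None:
            anc_a.append(x)
            x = x.parent
        anc_set = {id(n) for n in anc_a}
        up_b = []
        x = nb
        while id(x) not in anc_set:
            up_b.append(x)
            x = x.parent
        lca = x
        up_a = []
        x = na
        while x is not lca:
            up_a.append(x)
            x = x.parent
        return [(n, True) for n in up_a] + [(n, False) for n in reversed(up_b)]

    def _reroot_on_edge(self, child: Node, dist_from_child_top: float) -> "Tree":
        """Place a new root on the edge above ``child``; the new root sits
        ``dist_from_child_top`` below ``child``'s parent-side endpoint...
        offset is measured from the child end of the edge (walking upward)."""
        parent = child.parent
        if parent is None:
            t = Tree(self.root, True, dict(self.taxon_map))
            return t
        d_child = max(dist_from_child_top, 0.0)
        d_parent = max(child.length - d_child, 0.0)
        new_root = Node(None, 0.0)
        # detach child
        parent.children.remove(child)
        child.parent = None
        child.length = d_child
        new_root.add(child)
        # invert the path from parent up to the old root
        prev = new_root
        prev_len = d_parent
        node: Node | None = parent
        while node is not None:
            up = node.parent
            up_len = node.length
            sup = node.support
            if up is not None:
                up.children.remove(node)
            node.parent = None
            node.length = prev_len
            node.support = sup
            prev.add(node)
            prev, prev_len = node, up_len
            node = up
        # collapse degree-2 remnants of the old root
        _suppress_unifurcations(new_root)
        t = Tree(new_root, True, dict(self.taxon_map))
        return t

    # ------------------------------------------------------------------ text
    def __str__(self) -> str:
        return write_newick(self)


def _suppress_unifurcations(root: Node) -> None:
    stack = [root]
    while stack:
        n = stack.pop()
        changed = True
        while changed:
            changed = False
            for c in list(n.children):
                if not c.is_leaf and len(c.children) == 1:
                    gc = c.children[0]
                    gc.length += c.length
                    gc.parent = n
                    n.children[n.children.index(c)] = gc
                    changed = True
        stack.extend(n.children)


# ---------------------------------------------------------------------- I/O
def _parse_support(label: str | None) -> tuple[float | None, float | None] | None:
    if label is None or label == "":
        return None
    if "/" in label:
        a, b = label.split("/", 1)
        try:
            return (float(a) if a else None, float(b) if b else None)
        except ValueError:
            return None
    try:
        return (float(label), None)
    except ValueError:
        return None


def read_newick(text: str) -> Tree:
    """Parse a Newick string, interpreting internal labels as dual supports."""
    try:
        dt = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise NewickError(f"newick parse error: {exc}") from exc

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            name = dnode.taxon.label if dnode.taxon else dnode.label
            n = Node(name, dnode.edge.length or 0.0)
        else:
            n = Node(None, dnode.edge.length or 0.0, _parse_support(dnode.label))
        for ch in dnode.child_nodes():
            n.add(convert(ch))
        return n

    root = convert(dt.seed_node)
    return Tree(root, rooted=len(root.children) == 2)


def _fmt_support(sup: tuple[float | None, float | None] | None) -> str:
    if sup is None:
        return ""
    a, b = sup
    if b is None:
        return "" if a is None else f"{a:g}"
    return f"{'' if a is None else format(a, 'g')}/{b:g}"


def write_newick(tree: Tree, support: bool = True) -> str:
    """Serialize with branch lengths and ``aLRT/UFboot``-style dual labels."""
    buf = io.StringIO()

    def emit(n: Node, top: bool) -> None:
        if n.is_leaf:
            buf.write(n.name or "")
        else:
            buf.write("(")
            for i, c in enumerate(n.children):
                if i:
                    buf.write(",")
                emit(c, False)
            buf.write(")")
            if support and not top:
                buf.write(_fmt_support(n.support))
        if not top:
            buf.write(f":{n.length:g}")

    emit(tree.root, True)
    buf.write(";")
    return buf.getvalue()
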