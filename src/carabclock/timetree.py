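"""Rooted, dated phylogenetic trees.

A :class:`TimeTree` stores node ages in mega-annums (Ma) with the present at
age 0 and ages increasing into the past.  Branch lengths of a time-tree
written to Newick are durations in Ma (parent age minus child age); undated
trees in substitutions/site are a different dialect and are never guessed —
callers declare which they are reading.

Only strictly binary rooted trees are supported: polytomies are rejected at
parse time, and strict age ordering (parent strictly older than child) is
enforced, jittering exactly-tied ages upward by ``AGE_JITTER`` Ma.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import dendropy

logger = logging.getLogger(__name__)

AGE_JITTER = 1e-6
AGE_TOL = 1e-9


class TreeError(ValueError):
    """Malformed tree, label, or constraint."""


class Node:
    """A node of a :class:`TimeTree` (tip or internal)."""

    __slots__ = ("name", "parent", "children", "age", "index")

    def __init__(self, name: Optional[str] = None, age: float = 0.0):
        self.name = name
        self.parent: Optional["Node"] = None
        self.children: list["Node"] = []
        self.age = float(age)
        self.index: int = -1

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else "node"
        return f"<{kind} {self.name or self.index} age={self.age:.4g}>"


class TimeTree:
    """Rooted binary dated tree.

    Node indices are assigned deterministically: tips ``0..n-1`` in the order
    they appear in the underlying topology, internal nodes ``n..2n-2`` in
    postorder, so the root always has index ``2n-2``.
    """

    def __init__(self, root: Node, jitter: bool = True):
        self.root = root
        self._index()
        if jitter:
            self._jitter_ties()
        self._validate()

    # ------------------------------------------------------------------
    # construction helpers
    def _index(self) -> None:
        tips: list[Node] = []
        internals: list[Node] = []
        for node in self.postorder():
            if node.is_tip:
                tips.append(node)
            else:
                internals.append(node)
        names = [t.name for t in tips]
        if any(n is None for n in names):
            raise TreeError("every tip must be labelled")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")
        self.tips: list[Node] = tips
        self.internal_nodes: list[Node] = internals
        for i, node in enumerate(tips):
            node.index = i
        for i, node in enumerate(internals):
            node.index = len(tips) + i
        self._by_name = {t.name: t for t in tips}

    def _jitter_ties(self) -> None:
        for node in self.postorder():
            if node.is_tip:
                continue
            oldest_child = max(c.age for c in node.children)
            if node.age <= oldest_child + AGE_TOL:
                new_age = oldest_child + AGE_JITTER
                logger.info(
                    "jittering node age %.9g -> %.9g to enforce strict ordering",
                    node.age,
                    new_age,
                )
                node.age = new_age

    def _validate(self) -> None:
        if len(self.tips) < 2:
            raise TreeError("a tree needs at least 2 tips")
        for node in self.postorder():
            if node is not self.root and node.parent is None:
                raise TreeError("non-root node without parent")
            if not node.is_tip:
                if len(node.children) != 2:
                    raise TreeError(
                        f"polytomy or unary node at {node!r}: "
                        f"{len(node.children)} children (binary trees only)"
                    )
                for child in node.children:
                    if node.age - child.age <= AGE_TOL:
                        raise TreeError(
                            f"age ordering violated: parent {node.age} <= "
                            f"child {child.age}"
                        )
        if self.root.parent is not None:
            raise TreeError("root must not have a parent")

    # ------------------------------------------------------------------
    # basic queries
    @property
    def taxa(self) -> list[str]:
        return [t.name for t in self.tips]

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def postorder(self) -> Iterable[Node]:
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_tip:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterable[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def nodes(self) -> list[Node]:
        """All nodes ordered by index (tips first, then internal postorder)."""
        out: list[Node] = [None] * (2 * self.n_tips - 1)  # type: ignore[list-item]
        for node in self.postorder():
            out[node.index] = node
        return out

    def tip(self, name: str) -> Node:
        try:
            return self._by_name[name]
        except KeyError:
            raise TreeError(f"unknown taxon {name!r}") from None

    def branch_duration(self, node: Node) -> float:
        if node.parent is None:
            raise TreeError("root has no branch")
        return node.parent.age - node.age

    def total_branch_length(self) -> float:
        return sum(
            n.parent.age - n.age for n in self.postorder() if n.parent is not None
        )

    def root_age(self) -> float:
        return self.root.age

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        ages = [t.age for t in self.tips]
        return max(ages) - min(ages) <= tol

    def leaf_set(self, node: Node) -> frozenset[str]:
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_tip:
                out.append(n.name)
            else:
                stack.extend(n.children)
        return frozenset(out)

    # ------------------------------------------------------------------
    # MRCA machinery
    def mrca(self, taxon_set: Iterable[str]) -> Node:
        """Most recent common ancestor (crown node) of a set of tips."""
        names = list(taxon_set)
        if not names:
            raise TreeError("empty taxon set")
        nodes = [self.tip(n) for n in names]
        if len(nodes) == 1:
            return nodes[0]
        # Walk the first tip's root path, marking depth, then ascend others.
        depth: dict[int, int] = {}
        cur: Optional[Node] = nodes[0]
        d = 0
        path: list[Node] = []
        while cur is not None:
            depth[id(cur)] = d
            path.append(cur)
            cur = cur.parent
            d += 1
        best = 0
        for node in nodes[1:]:
            cur = node
            while id(cur) not in depth:
                cur = cur.parent  # type: ignore[assignment]
            best = max(best, depth[id(cur)])
        return path[best]

    def tmrca_age(self, taxon_set: Iterable[str]) -> float:
        """Age (Ma) of the crown MRCA node of ``taxon_set``.

        A singleton has no crown node and is an error.
        """
        names = list(taxon_set)
        if len(names) < 2:
            raise TreeError("TMRCA needs at least two taxa (no crown for a singleton)")
        return self.mrca(names).age

    def subtree(self, taxon_set: Iterable[str]) -> "TimeTree":
        """The crown subtree of ``taxon_set``'s MRCA as a standalone tree.

        The taxon set must be monophyletic (the subtree contains exactly it).
        """
        names = frozenset(taxon_set)
        crown = self.mrca(names)
        if self.leaf_set(crown) != names:
            raise TreeError("taxon set is not monophyletic; cannot extract subtree")
        mapping: dict[int, Node] = {}
        stack = [crown]
        order: list[Node] = []
        while stack:
            n = stack.pop()
            order.append(n)
            stack.extend(n.children)
        for node in reversed(order):
            clone = Node(node.name, node.age)
            mapping[id(node)] = clone
            for child in node.children:
                cc = mapping[id(child)]
                cc.parent = clone
                clone.children.append(cc)
        return TimeTree(mapping[id(crown)], jitter=False)

    def copy(self) -> "TimeTree":
        mapping: dict[int, Node] = {}
        for node in self.postorder():
            clone = Node(node.name, node.age)
            mapping[id(node)] = clone
            for child in node.children:
                cc = mapping[id(child)]
                cc.parent = clone
                clone.children.append(cc)
        return TimeTree(mapping[id(self.root)], jitter=False)


# ----------------------------------------------------------------------
# clade constraints


@dataclass(frozen=True)
class CladeConstraint:
    """A named constraint on a clade: monophyly and crown/stem placement.

    ``basal_taxon`` optionally names a tip that must attach as a direct child
    of the clade's crown node (the "most basal split" style of constraint).
    """

    name: str
    taxon_set: frozenset[str]
    placement: str = "crown"  # crown | stem
    monophyletic: bool = True
    basal_taxon: Optional[str] = None

    def __post_init__(self):
        if self.placement not in ("crown", "stem"):
            raise TreeError(f"placement must be crown or stem, got {self.placement!r}")
        need = 2 if self.placement == "crown" else 1
        if len(self.taxon_set) < need:
            raise TreeError(
                f"constraint {self.name!r}: need >= {need} taxa for "
                f"{self.placement} placement"
            )


def mrca_node(tree: TimeTree, taxon_set: Iterable[str], placement: str = "crown") -> Node:
    """Resolve a taxon set to its crown MRCA, or the stem (its parent)."""
    names = list(taxon_set)
    unknown = [n for n in names if n not in tree._by_name]
    if unknown:
        raise TreeError(f"unknown taxa: {unknown}")
    crown = tree.mrca(names)
    if placement == "crown":
        if len(names) < 2:
            raise TreeError("crown placement needs >= 2 taxa")
        return crown
    if placement == "stem":
        if crown.parent is None:
            raise TreeError("stem of the root is undefined")
        return crown.parent
    raise TreeError(f"unknown placement {placement!r}")


def constraint_node(tree: TimeTree, constraint: CladeConstraint) -> Node:
    return mrca_node(tree, constraint.taxon_set, constraint.placement)


def check_constraints(
    tree: TimeTree, constraints: Sequence[CladeConstraint]
) -> dict[str, bool]:
    """Evaluate monophyly / basal-attachment constraints; never raises on failure."""
    report: dict[str, bool] = {}
    for c in constraints:
        try:
            crown = tree.mrca(c.taxon_set)
        except TreeError:
            report[c.name] = False
            continue
        ok = True
        if c.monophyletic:
            ok = tree.leaf_set(crown) == frozenset(c.taxon_set)
        if ok and c.basal_taxon is not None:
            ok = any(
                child.is_tip and child.name == c.basal_taxon
                for child in crown.children
            )
        report[c.name] = ok
    return report


# ----------------------------------------------------------------------
# Newick / NEXUS I/O


def parse_newick(
    text: str,
    allow_non_ultrametric: bool = False,
    ultrametric_tol: float = 1e-6,
) -> TimeTree:
    """Parse a Newick string with branch lengths into a :class:`TimeTree`.

    Tips are placed at age 0 and ages accumulate rootward.  Input whose tips
    are not equidistant from the root is rejected unless
    ``allow_non_ultrametric`` is set, in which case tip ages are kept as
    computed (root age minus root-to-tip depth).
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises various error types
        raise TreeError(f"Newick parse error: {exc}") from exc
    return _from_dendropy(dtree, allow_non_ultrametric, ultrametric_tol)


def read_nexus_trees(path: str) -> list[TimeTree]:
    """Read the trees block of a NEXUS file (translate tables honoured)."""
    trees = dendropy.TreeList.get(path=path, schema="nexus", preserve_underscores=True)
    return [_from_dendropy(t, allow_non_ultrametric=True) for t in trees]


def _from_dendropy(
    dtree: "dendropy.Tree",
    allow_non_ultrametric: bool = False,
    ultrametric_tol: float = 1e-6,
) -> TimeTree:
    # depth-first conversion with depth bookkeeping
    droot = dtree.seed_node
    mapping: dict[int, Node] = {}
    depths: dict[int, float] = {id(droot): 0.0}
    max_depth = 0.0
    for dnode in dtree.preorder_node_iter():
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label and dnode.is_leaf():
            label = dnode.label
        node = Node(label)
        mapping[id(dnode)] = node
        if dnode is not droot:
            length = dnode.edge.length
            if length is None:
                raise TreeError(f"missing branch length above {label or 'a node'}")
            if length < 0:
                raise TreeError(f"negative branch length {length}")
            depths[id(dnode)] = depths[id(dnode.parent_node)] + length
            parent = mapping[id(dnode.parent_node)]
            node.parent = parent
            parent.children.append(node)
        if dnode.is_leaf():
            if label is None:
                raise TreeError("unlabelled tip in Newick input")
            max_depth = max(max_depth, depths[id(dnode)])
    tip_depths = [
        depths[id(d)] for d in dtree.leaf_node_iter()
    ]
    if max(tip_depths) - min(tip_depths) > ultrametric_tol and not allow_non_ultrametric:
        raise TreeError(
            "input tree is not ultrametric (tip depth spread "
            f"{max(tip_depths) - min(tip_depths):.3g}); pass "
            "allow_non_ultrametric=True to keep computed tip ages"
        )
    for dnode in dtree.preorder_node_iter():
        mapping[id(dnode)].age = max_depth - depths[id(dnode)]
        if abs(mapping[id(dnode)].age) < AGE_TOL:
            mapping[id(dnode)].age = 0.0
    return TimeTree(mapping[id(droot)])


def _fmt(x: float, precision: int = 10) -> str:
    s = f"{x:.{precision}g}"
    return s


def write_newick(
    tree: TimeTree,
    annotations: Optional[Mapping[str, Mapping[str, object]]] = None,
    precision: int = 10,
) -> str:
    """Serialize to Newick with durations (Ma) as branch lengths.

    ``annotations`` maps a node key (tip label, or a clade name resolved by
    callers to an internal node via its node ``index`` as ``"@<index>"``) to
    key-value pairs emitted as ``[&k=v,...]`` comment blocks, the dialect
    common tree annotators display.
    """
    annotations = annotations or {}

    def node_key(node: Node) -> Optional[str]:
        if node.is_tip and node.name in annotations:
            return node.name
        key = f"@{node.index}"
        if key in annotations:
            return key
        if node is tree.root and "root" in annotations:
            return "root"
        return None

    def annot(node: Node) -> str:
        key = node_key(node)
        if key is None:
            return ""
        items = ",".join(f"{k}={v}" for k, v in annotations[key].items())
        return f"[&{items}]"

    def render(node: Node) -> str:
        if node.is_tip:
            base = node.name
        else:
            base = "(" + ",".join(render(c) for c in node.children) + ")"
        base += annot(node)
        if node.parent is not None:
            base += ":" + _fmt(node.parent.age - node.age, precision)
        return base

    return render(tree.root) + ";"
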