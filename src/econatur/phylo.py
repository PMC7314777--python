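"""Phylogeny container, newick I/O, grafting, pruning and Faith's PD.

Trees are rooted, with branch lengths in millions of years (myr) and
tip labels equal to ``taxon_id``.  Taxa absent from a published tree
are grafted onto the crown node of their genus (or, failing that, of
their family) with a pendant branch reaching the present, so an
ultrametric tree stays ultrametric.

Faith's phylogenetic diversity uses the rooted convention: the minimal
spanning subtree always includes the root, so the PD of a single tip is
its root-to-tip depth and the PD of all tips is the total branch
length.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .core import TaxonTable, ValidationError

__all__ = [
    "PhyloNode",
    "Phylogeny",
    "read_newick",
    "graft_missing_taxa",
    "prune",
    "faith_pd",
    "PDIndex",
]


class PhyloNode:
    """A node of a rooted tree; ``length`` is the edge to the parent."""

    __slots__ = ("children", "parent", "length", "label")

    def __init__(self, label=None, length=0.0):
        self.children: list[PhyloNode] = []
        self.parent: PhyloNode | None = None
        self.length: float = length
        self.label: str | None = label

    def add_child(self, child: "PhyloNode") -> "PhyloNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children


@dataclass
class Phylogeny:
    """Rooted tree with branch lengths in myr; tips labelled by taxon id."""

    root: PhyloNode
    ultrametric: bool = True
    #: optional tip -> (genus, family) map attached by the generator
    tip_lineage: dict | None = None

    # -- traversal -----------------------------------------------------------

    def postorder(self):
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for c in reversed(node.children):
                stack.append(c)

    def tips(self) -> list[PhyloNode]:
        return [n for n in self.postorder() if n.is_tip]

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    def n_tips(self) -> int:
        return sum(1 for n in self.postorder() if n.is_tip)

    # -- metrics -------------------------------------------------------------

    def depths_from_root(self) -> dict[PhyloNode, float]:
        d = {self.root: 0.0}
        for node in self.preorder():
            if node is not self.root:
                d[node] = d[node.parent] + node.length
        return d

    def tip_depths(self) -> dict[str, float]:
        d = self.depths_from_root()
        return {n.label: d[n] for n in self.tips()}

    def heights(self) -> dict[PhyloNode, float]:
        """Distance from each node down to its deepest descendant tip."""
        h: dict[PhyloNode, float] = {}
        for node in self.postorder():
            if node.is_tip:
                h[node] = 0.0
            else:
                h[node] = max(h[c] + c.length for c in node.children)
        return h

    def total_branch_length(self) -> float:
        return sum(n.length for n in self.postorder() if n is not self.root)

    def is_ultrametric(self, rel_tol: float = 1e-9) -> bool:
        depths = list(self.tip_depths().values())
        span = max(depths)
        if span == 0:
            return True
        return (max(depths) - min(depths)) <= rel_tol * span

    def mrca(self, labels) -> PhyloNode:
        labels = set(labels)
        tip_map = {n.label: n for n in self.tips()}
        missing = labels - tip_map.keys()
        if missing:
            raise ValidationError(f"unknown tip ids: {sorted(missing)}")
        paths = []
        for lab in labels:
            path = []
            node = tip_map[lab]
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(list(reversed(path)))
        mrca = self.root
        for nodes in zip(*paths):
            first = nodes[0]
            if all(n is first for n in nodes):
                mrca = first
            else:
                break
        return mrca

    def tip_distance_matrix(self) -> tuple[list[str], np.ndarray]:
        """Pairwise patristic distances between tips (test-size trees)."""
        tips = self.tips()
        labels = [t.label for t in tips]
        depth = self.depths_from_root()
        # ancestor chains with depths
        anc = {}
        for t in tips:
            chain = {}
            node = t
            while node is not None:
                chain[id(node)] = depth[node]
                node = node.parent
            anc[t.label] = chain
        n = len(tips)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                ci = anc[labels[i]]
                node = tips[j]
                while id(node) not in ci:
                    node = node.parent
                dm = depth[node]
                D[i, j] = D[j, i] = (
                    depth[tips[i]] + depth[tips[j]] - 2.0 * dm
                )
        return labels, D

    # -- copying -------------------------------------------------------------

    def copy(self) -> "Phylogeny":
        def clone(node: PhyloNode) -> PhyloNode:
            c = PhyloNode(label=node.label, length=node.length)
            for ch in node.children:
                c.add_child(clone(ch))
            return c

        return Phylogeny(root=clone(self.root), ultrametric=self.ultrametric)

    # -- newick --------------------------------------------------------------

    def _canonical_sort(self) -> None:
        """Order children by their smallest descendant tip label."""
        key: dict[int, str] = {}
        for node in self.postorder():
            if node.is_tip:
                key[id(node)] = node.label or ""
            else:
                node.children.sort(key=lambda c: key[id(c)])
                key[id(node)] = key[id(node.children[0])]

    def to_newick(self) -> str:
        """Canonical newick string (sorted children, 10 sig digits)."""
        tree = self.copy()
        tree._canonical_sort()

        out: list[str] = []

        def emit(node: PhyloNode, with_length: bool) -> None:
            if node.children:
                out.append("(")
                for i, c in enumerate(node.children):
                    if i:
                        out.append(",")
                    emit(c, True)
                out.append(")")
            if node.label:
                out.append(node.label)
            if with_length:
                out.append(f":{node.length:.10g}")

        emit(tree.root, False)
        out.append(";")
        return "".join(out)

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree, ultrametric: bool = True) -> "Phylogeny":
        def convert(dnode) -> PhyloNode:
            label = None
            if dnode.is_leaf():
                label = dnode.taxon.label if dnode.taxon else dnode.label
            node = PhyloNode(
                label=label,
                length=float(dnode.edge.length or 0.0),
            )
            for ch in dnode.child_nodes():
                node.add_child(convert(ch))
            return node

        root = convert(dtree.seed_node)
        root.length = 0.0
        return cls(root=root, ultrametric=ultrametric)


def read_newick(source, ultrametric: bool = True) -> Phylogeny:
    """Read a newick tree from a path or string; polytomies allowed."""
    if isinstance(source, str) and source.lstrip().startswith("("):
        dtree = dendropy.Tree.get(
            data=source, schema="newick", preserve_underscores=True
        )
    else:
        dtree = dendropy.Tree.get(
            path=str(source), schema="newick", preserve_underscores=True
        )
    return Phylogeny.from_dendropy(dtree, ultrametric=ultrametric)


# ---------------------------------------------------------------------------
# grafting
# ---------------------------------------------------------------------------


def _attachment_node(tree: Phylogeny, tip_nodes: list[PhyloNode]) -> PhyloNode:
    """Crown node for a set of tips; splits a lone tip's pendant edge."""
    if len(tip_nodes) >= 2:
        return tree.mrca([t.label for t in tip_nodes])
    tip = tip_nodes[0]
    if tip.parent is None:
        raise ValidationError("cannot graft onto a single-node tree")
    half = tip.length / 2.0
    mid = PhyloNode(length=half)
    parent = tip.parent
    parent.children[parent.children.index(tip)] = mid
    mid.parent = parent
    tip.length = half
    mid.add_child(tip)
    return mid


def graft_missing_taxa(
    tree: Phylogeny, table: TaxonTable
) -> tuple[Phylogeny, list[str]]:
    """Attach table taxa missing from ``tree`` at genus/family crown nodes.

    A missing taxon with at least one congeneric tip is attached at the
    crown node (MRCA) of its genus with a pendant branch equal to that
    node's height, which preserves ultrametricity.  If the genus is
    absent, the family crown node is used instead.  Taxa whose family
    is also absent are returned in the unplaced report.  Attachment
    points are determined from the original tips only, so the result
    does not depend on the order of the table rows.

    Returns the grafted tree (a copy) and the list of unplaced ids.
    """
    if tree.n_tips() == 0:
        raise ValidationError("empty tree")
    if tree.ultrametric and not tree.is_ultrametric(rel_tol=1e-6):
        raise ValidationError("tree flagged ultrametric but tip depths differ")

    out = tree.copy()
    present = set(out.tip_labels())
    info = table.by_id()

    genus_tips: dict[str, list[PhyloNode]] = {}
    family_tips: dict[str, list[PhyloNode]] = {}
    for node in out.tips():
        t = info.get(node.label)
        if t is None:
            continue
        genus_tips.setdefault(t.genus, []).append(node)
        family_tips.setdefault(t.family, []).append(node)

    # resolve attachment nodes once per lineage needing one
    missing = [t for t in table if t.taxon_id not in present]
    unplaced: list[str] = []
    attach_cache: dict[tuple[str, str], PhyloNode | None] = {}

    def attach_for(taxon) -> PhyloNode | None:
        if taxon.genus in genus_tips:
            key = ("genus", taxon.genus)
            if key not in attach_cache:
                attach_cache[key] = _attachment_node(out, genus_tips[taxon.genus])
            return attach_cache[key]
        if taxon.family in family_tips:
            key = ("family", taxon.family)
            if key not in attach_cache:
                attach_cache[key] = _attachment_node(out, family_tips[taxon.family])
            return attach_cache[key]
        return None

    heights: dict[int, float] | None = None
    for taxon in sorted(missing, key=lambda t: t.taxon_id):
        node = attach_for(taxon)
        if node is None:
            unplaced.append(taxon.taxon_id)
            continue
        if heights is None or id(node) not in heights:
            h = out.heights()
            heights = {id(n): v for n, v in h.items()}
        node.add_child(PhyloNode(label=taxon.taxon_id, length=heights[id(node)]))
    return out, unplaced


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------


def prune(tree: Phylogeny, keep) -> Phylogeny:
    """Restrict the tree to ``keep`` tips, suppressing unifurcations.

    Collapsed branch lengths are summed, so root-to-tip depths of the
    retained tips are preserved.
    """
    keep = set(keep)
    if not keep:
        raise ValidationError("keep set is empty")
    tips = set(tree.tip_labels())
    missing = keep - tips
    if missing:
        raise ValidationError(f"ids not in tree: {sorted(missing)}")

    def build(node: PhyloNode) -> PhyloNode | None:
        if node.is_tip:
            if node.label in keep:
                return PhyloNode(label=node.label, length=node.length)
            return None
        kept = [c for c in (build(ch) for ch in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            child = kept[0]
            child.length += node.length
            return child
        new = PhyloNode(length=node.length)
        for c in kept:
            new.add_child(c)
        return new

    new_root = build(tree.root)
    # the root keeps no pendant length above it
    new_root.length = 0.0
    return Phylogeny(root=new_root, ultrametric=tree.ultrametric)


# ---------------------------------------------------------------------------
# Faith's PD
# ---------------------------------------------------------------------------


def faith_pd(tree: Phylogeny, tips) -> float:
    """Faith's PD of a tip set (rooted convention), in myr."""
    tips = set(tips)
    if not tips:
        raise ValidationError("tip set is empty")
    labels = set(tree.tip_labels())
    unknown = tips - labels
    if unknown:
        raise ValidationError(f"unknown tip ids: {sorted(unknown)}")
    selected: dict[int, bool] = {}
    pd = 0.0
    for node in tree.postorder():
        if node.is_tip:
            sel = node.label in tips
        else:
            sel = any(selected[id(c)] for c in node.children)
        selected[id(node)] = sel
        if sel and node is not tree.root:
            pd += node.length
    return pd


class PDIndex:
    """Array form of a tree for evaluating PD over many tip subsets.

    Nodes are numbered in postorder; for a boolean tip-selection matrix
    the PD of every row is obtained by propagating "has a selected
    descendant" up the tree and summing edge lengths.
    """

    def __init__(self, tree: Phylogeny):
        nodes = list(tree.postorder())
        self._index = {id(n): i for i, n in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.lengths = np.array(
            [n.length if n.parent is not None else 0.0 for n in nodes]
        )
        self.tip_ids = [n.label for n in nodes if n.is_tip]
        self.tip_pos = np.array(
            [self._index[id(n)] for n in nodes if n.is_tip], dtype=np.int64
        )
        self.children: list[np.ndarray] = []
        self.internal: list[int] = []
        for i, n in enumerate(nodes):
            if n.children:
                self.internal.append(i)
                self.children.append(
                    np.array([self._index[id(c)] for c in n.children], dtype=np.int64)
                )
        self.tip_index = {lab: k for k, lab in enumerate(self.tip_ids)}
        self.n_tips = len(self.tip_ids)

    def pd_batch(self, selection: np.ndarray) -> np.ndarray:
        """PD for each row of a (n_sets, n_tips) boolean matrix."""
        selection = np.asarray(selection, dtype=bool)
        n_sets = selection.shape[0]
        desc = np.zeros((self.n_nodes, n_sets), dtype=bool)
        desc[self.tip_pos] = selection.T
        for i, ch in zip(self.internal, self.children):
            if len(ch) == 2:
                desc[i] = desc[ch[0]] | desc[ch[1]]
            else:
                desc[i] = desc[ch].any(axis=0)
        return self.lengths @ desc

    def pd_of(self, tips) -> float:
        sel = np.zeros((1, self.n_tips), dtype=bool)
        for lab in tips:
            sel[0, self.tip_index[lab]] = True
        return float(self.pd_batch(sel)[0])
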