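"""Rooted phylogenies: Newick I/O, pruning, patristic distances, MPL dating.

The tree is the substrate of every diversity metric downstream: Faith's PD
sums its branch lengths, MPD/MNTD/Dpw/Dnn consume its patristic distances,
and UniFrac classifies its edges.  A :class:`PhyloTree` wraps a
:class:`dendropy.Tree` (which handles Newick parsing and serialisation) and
adds the validation and operations the analysis needs: leaf labels must be
unique, branch lengths non-negative, and ultrametricity is a *checkable*
predicate rather than an assumed property.

Dating is provided by a deliberately simple mean-path-length procedure
("MPL-lite"): node ages are the mean root-ward accumulation of child ages
plus child branch lengths, linearly rescaled so calibrated nodes sit at
exactly their assigned ages, with age clamping to resolve any reversals.
Rate-smoothing refinements found in full dating programs are intentionally
out of scope -- the purpose here is only to obtain a usable ultrametric
chronogram from additive branch lengths.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np
from skbio import DistanceMatrix

__all__ = [
    "PhyloTree",
    "Calibration",
    "TreeError",
    "parse_newick",
    "write_newick",
    "prune_to_taxa",
    "patristic_distances",
    "total_branch_length",
    "is_ultrametric",
    "mpl_ultrametricize",
]


class TreeError(ValueError):
    """Raised for malformed Newick input or invalid tree state."""


@dataclass(frozen=True)
class Calibration:
    """Fixed age (time units before present) for the MRCA of two leaves.

    A leaf label may be repeated (``("A", "A")``) to address a terminal
    node, though calibrating a leaf to a nonzero age is rejected.
    """

    mrca_of: tuple[str, str]
    age: float

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError(f"calibration age must be positive, got {self.age}")


class PhyloTree:
    """A rooted tree with branch lengths and uniquely labelled leaves.

    Thin wrapper over ``dendropy.Tree``.  Invariants enforced at
    construction: single root, unique non-empty leaf labels, all branch
    lengths present (or zero-filled under ``permissive``) and >= 0.  A
    length on the root edge, if present in the source, is dropped --
    rooting conventions for PD are handled by the alpha-diversity module.
    """

    def __init__(self, dtree: dendropy.Tree, permissive: bool = False) -> None:
        self._t = dtree
        self._t.seed_node.edge.length = None  # root edge dropped by convention
        self._validate(permissive)
        self._index()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, permissive: bool = False) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeError(f"malformed Newick: {exc}") from exc
        return cls(dtree, permissive=permissive)

    @classmethod
    def from_file(cls, path, permissive: bool = False) -> "PhyloTree":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_newick(fh.read(), permissive=permissive)

    def _validate(self, permissive: bool) -> None:
        labels = []
        for leaf in self._t.leaf_node_iter():
            label = leaf.taxon.label if leaf.taxon is not None else None
            if not label:
                raise TreeError("leaf without a label")
            labels.append(label)
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate leaf labels: {dupes}")
        for node in self._t.preorder_node_iter():
            if node is self._t.seed_node:
                continue
            if node.edge.length is None:
                if permissive:
                    node.edge.length = 0.0
                else:
                    raise TreeError(
                        "missing branch length (pass permissive=True to zero-fill)"
                    )
            if node.edge.length < 0:
                raise TreeError(f"negative branch length {node.edge.length}")

    def _index(self) -> None:
        """Cache leaf order, per-node depths and post-order leaf index sets."""
        self._leaves = sorted(
            self._t.leaf_node_iter(), key=lambda n: n.taxon.label
        )
        self._leaf_labels = [n.taxon.label for n in self._leaves]
        self._leaf_pos = {lab: i for i, lab in enumerate(self._leaf_labels)}
        self._depth = {}
        for node in self._t.preorder_node_iter():
            parent = node.parent_node
            if parent is None:
                self._depth[node] = 0.0
            else:
                self._depth[node] = self._depth[parent] + node.edge.length

    # -- basic accessors ---------------------------------------------------

    @property
    def leaf_labels(self) -> list[str]:
        """Leaf labels in sorted order (the canonical ID order)."""
        return list(self._leaf_labels)

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_labels)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._t

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-leaf path length per leaf."""
        return {n.taxon.label: self._depth[n] for n in self._leaves}

    def height(self) -> float:
        return max(self._depth[n] for n in self._leaves)

    def total_branch_length(self) -> float:
        return float(
            sum(
                n.edge.length
                for n in self._t.preorder_node_iter()
                if n.parent_node is not None
            )
        )

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        depths = [self._depth[n] for n in self._leaves]
        span = max(depths) - min(depths)
        scale = max(max(depths), 1e-300)
        return span / scale <= rel_tol

    # -- edge / clade machinery (shared by PD and UniFrac) -----------------

    def edge_table(self) -> tuple[np.ndarray, np.ndarray]:
        """All non-root edges as ``(lengths, clade_membership)``.

        ``clade_membership`` is a boolean (n_edges, n_leaves) matrix in
        canonical leaf order: entry (e, i) is True when leaf i descends
        from edge e.  PD of a leaf subset S (rooted convention) is then
        ``lengths @ (membership[:, S].any(axis=1))``.
        """
        n = self.n_leaves
        lengths = []
        rows = []
        masks: dict[dendropy.Node, np.ndarray] = {}
        for node in self._t.postorder_node_iter():
            if node.is_leaf():
                m = np.zeros(n, dtype=bool)
                m[self._leaf_pos[node.taxon.label]] = True
            else:
                m = np.zeros(n, dtype=bool)
                for child in node.child_nodes():
                    m |= masks[child]
            masks[node] = m
            if node.parent_node is not None:
                lengths.append(node.edge.length)
                rows.append(m)
        return np.asarray(lengths, dtype=float), np.asarray(rows, dtype=bool)

    # -- operations --------------------------------------------------------

    def patristic_distances(self) -> DistanceMatrix:
        """Pairwise path-length distances between all leaves.

        Computed as d(i, j) = depth(i) + depth(j) - 2 * depth(mrca(i, j)),
        accumulating MRCA depths in one post-order sweep.
        """
        n = self.n_leaves
        depths = np.array([self._depth[leaf] for leaf in self._leaves])
        mrca_depth = np.zeros((n, n))
        below: dict[dendropy.Node, list[int]] = {}
        for node in self._t.postorder_node_iter():
            if node.is_leaf():
                below[node] = [self._leaf_pos[node.taxon.label]]
                continue
            children = [below[c] for c in node.child_nodes()]
            d = self._depth[node]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    ia = np.asarray(children[a])
                    ib = np.asarray(children[b])
                    mrca_depth[np.ix_(ia, ib)] = d
                    mrca_depth[np.ix_(ib, ia)] = d
            below[node] = [i for ch in children for i in ch]
        dist = depths[:, None] + depths[None, :] - 2.0 * mrca_depth
        np.fill_diagonal(dist, 0.0)
        return DistanceMatrix(dist, ids=self._leaf_labels)

    def prune_to_taxa(self, taxa: Iterable[str]) -> "PhyloTree":
        """Restrict to a leaf subset, preserving root-to-leaf depths.

        Unifurcating internal nodes are suppressed with branch lengths
        summed; the root itself is retained even if left with one child,
        so retained leaves keep their original depths (and an ultrametric
        input stays ultrametric at the same height).
        """
        keep = set(taxa)
        if not keep:
            raise TreeError("cannot prune to an empty taxon set")
        missing = sorted(keep - set(self._leaf_labels))
        if missing:
            raise TreeError(f"unknown taxa: {missing}")

        clone = self._t.clone(depth=1)
        # drop leaves not kept, bottom-up
        changed = True
        while changed:
            changed = False
            for leaf in list(clone.leaf_node_iter()):
                label = leaf.taxon.label if leaf.taxon is not None else None
                if label not in keep:
                    parent = leaf.parent_node
                    if parent is None:
                        raise TreeError("pruning removed the entire tree")
                    parent.remove_child(leaf)
                    changed = True
        # suppress unifurcations (root excepted), summing lengths
        for node in list(clone.postorder_node_iter()):
            children = node.child_nodes()
            if len(children) == 1 and node.parent_node is not None:
                (child,) = children
                child.edge.length = (child.edge.length or 0.0) + (
                    node.edge.length or 0.0
                )
                parent = node.parent_node
                parent.remove_child(node)
                parent.add_child(child)
        return PhyloTree(clone)

    def mrca(self, labels: Sequence[str]) -> dendropy.Node:
        nodes = []
        for lab in labels:
            if lab not in self._leaf_pos:
                raise TreeError(f"unknown leaf label: {lab}")
            nodes.append(self._leaves[self._leaf_pos[lab]])
        # walk up from the first, then check coverage
        want = set(nodes)
        node = nodes[0]
        while node is not None:
            clade = set(node.leaf_iter())
            if want <= clade:
                return node
            node = node.parent_node
        raise TreeError("no common ancestor found (disconnected tree?)")

    def to_newick(self) -> str:
        out = self._t.as_string(
            schema="newick",
            suppress_rooting=True,
            preserve_spaces=True,  # spaced labels stay quoted, not underscored
            real_value_format_specifier=".12g",
        )
        return out.strip() + "\n"

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_newick())

    def __repr__(self) -> str:
        return f"PhyloTree(n_leaves={self.n_leaves}, height={self.height():.4g})"


# ---------------------------------------------------------------------------
# functional façade

def parse_newick(text: str, permissive: bool = False) -> PhyloTree:
    """Parse a Newick string into a validated :class:`PhyloTree`."""
    return PhyloTree.from_newick(text, permissive=permissive)


def write_newick(tree: PhyloTree) -> str:
    return tree.to_newick()


def prune_to_taxa(tree: PhyloTree, taxa: Iterable[str]) -> PhyloTree:
    return tree.prune_to_taxa(taxa)


def patristic_distances(tree: PhyloTree) -> DistanceMatrix:
    return tree.patristic_distances()


def total_branch_length(tree: PhyloTree) -> float:
    return tree.total_branch_length()


def is_ultrametric(tree: PhyloTree, rel_tol: float = 1e-6) -> bool:
    return tree.is_ultrametric(rel_tol=rel_tol)


def mpl_ultrametricize(
    tree: PhyloTree,
    calibrations: Sequence[Calibration] = (),
    root_age: float | None = None,
) -> PhyloTree:
    """Date a tree by mean path lengths, honouring fixed node ages.

    Raw ages are computed bottom-up: age(leaf) = 0 and
    age(v) = mean over children c of (age(c) + branch(c)).  Each
    uncalibrated node is then rescaled by the factor that maps its nearest
    calibrated ancestor's raw age onto that ancestor's assigned age; ages
    are clamped (child age := min(child age, parent age)) so they weakly
    decrease root-ward, and branch lengths are rebuilt as age differences.
    The result is ultrametric with all leaves at age 0.

    The root must receive an age, either through ``root_age`` or through a
    calibration whose MRCA is the root.
    """
    clone = PhyloTree(tree.dendropy_tree.clone(depth=1))
    t = clone.dendropy_tree

    # raw mean-path-length ages
    raw: dict[dendropy.Node, float] = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            raw[node] = 0.0
        else:
            raw[node] = float(
                np.mean([raw[c] + (c.edge.length or 0.0) for c in node.child_nodes()])
            )

    # resolve calibrations to nodes of the clone
    fixed: dict[dendropy.Node, float] = {}
    for cal in calibrations:
        a, b = cal.mrca_of
        node = clone.mrca([a, b])
        if node.is_leaf():
            raise TreeError(f"cannot calibrate leaf {a!r} to a nonzero age")
        if node in fixed and fixed[node] != cal.age:
            raise TreeError(
                f"conflicting calibrations for mrca({a},{b}): "
                f"{fixed[node]} vs {cal.age}"
            )
        fixed[node] = cal.age
    root = t.seed_node
    if root not in fixed:
        if root_age is None:
            raise TreeError("root age required (root_age= or a root calibration)")
        fixed[root] = float(root_age)

    # conflicting nesting: a calibrated descendant older than its ancestor
    for node, age in fixed.items():
        anc = node.parent_node
        while anc is not None:
            if anc in fixed and fixed[anc] < age:
                raise TreeError(
                    f"calibration conflict: descendant age {age} exceeds "
                    f"ancestor age {fixed[anc]}"
                )
            anc = anc.parent_node

    # top-down: assign ages, rescaling raw ages within calibrated segments
    age: dict[dendropy.Node, float] = {}
    scale: dict[dendropy.Node, float] = {}
    for node in t.preorder_node_iter():
        if node.is_leaf():
            age[node] = 0.0
            continue
        if node in fixed:
            age[node] = fixed[node]
            scale[node] = fixed[node] / raw[node] if raw[node] > 0 else 1.0
        else:
            s = scale[node.parent_node]
            age[node] = raw[node] * s
            scale[node] = s
        parent = node.parent_node
        if parent is not None and age[node] > age[parent]:
            if node in fixed:
                raise TreeError(
                    f"calibrated age {age[node]} exceeds parent age {age[parent]}"
                )
            age[node] = age[parent]  # clamp reversals

    for node in t.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = age[node.parent_node] - age[node]
    return PhyloTree(t)
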