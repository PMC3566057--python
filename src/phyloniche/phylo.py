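"""Rooted ultrametric phylogenies and clade membership.

The tree is a time-calibrated chronogram: branch lengths in Myr, node heights
measured downward from the root (root height 0, all tips at the tree height).
Newick parsing/writing goes through dendropy; the array representation here
is what the comparative methods (pruning passes, disparity curves, Brownian
simulation) operate on.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

__all__ = ["Phylogeny", "CladeMap", "read_newick", "write_newick", "UltrametricError"]

ULTRAMETRIC_RTOL = 1e-6  # tolerance as a fraction of tree height


class UltrametricError(ValueError):
    """Tree is not ultrametric within tolerance."""


@dataclass(frozen=True, eq=False)
class Phylogeny:
    """Rooted binary ultrametric tree in array form.

    Nodes are indexed 0..2n-2 with tips first (0..n-1, in ``tip_labels``
    order) and internal nodes in postorder after them; the root is the last
    index. ``parent[root] == -1``; ``branch_lengths[root] == 0``.
    """

    tip_labels: tuple[str, ...]
    parent: np.ndarray  # int, per node
    children: tuple[tuple[int, ...], ...]  # per node, () for tips
    branch_lengths: np.ndarray  # float, per node (length of edge above node)
    heights: np.ndarray  # float, per node, root = 0

    # -- construction -------------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        tip_labels: Sequence[str],
        parent: Sequence[int],
        branch_lengths: Sequence[float],
        validate: bool = True,
    ) -> "Phylogeny":
        tip_labels = tuple(str(t) for t in tip_labels)
        parent = np.asarray(parent, dtype=int)
        branch_lengths = np.asarray(branch_lengths, dtype=float)
        n_nodes = parent.size
        children: list[list[int]] = [[] for _ in range(n_nodes)]
        root = -1
        for i, p in enumerate(parent):
            if p < 0:
                root = i
            else:
                children[p].append(i)
        heights = np.zeros(n_nodes)
        for i in _preorder(parent, children, root):
            if i != root:
                heights[i] = heights[parent[i]] + branch_lengths[i]
        tree = cls(
            tip_labels=tip_labels,
            parent=parent,
            children=tuple(tuple(c) for c in children),
            branch_lengths=branch_lengths,
            heights=heights,
        )
        if validate:
            tree._validate()
        return tree

    def _validate(self) -> None:
        n = self.n_tips
        if len(set(self.tip_labels)) != n:
            raise ValueError("tip labels must be unique")
        for i, ch in enumerate(self.children):
            if i < n:
                if ch:
                    raise ValueError("tips must be indexed before internal nodes")
            elif len(ch) != 2:
                raise ValueError(f"internal node {i} is not binary ({len(ch)} children)")
        if (self.branch_lengths[: self.root] < 0).any():
            raise ValueError("negative branch length")
        height = self.height
        tol = ULTRAMETRIC_RTOL * max(height, np.finfo(float).tiny)
        dev = np.abs(self.heights[:n] - height)
        worst = int(np.argmax(dev))
        if dev[worst] > tol:
            raise UltrametricError(
                f"tree is not ultrametric: tip {self.tip_labels[worst]!r} at height "
                f"{self.heights[worst]:.9g} vs tree height {height:.9g}"
            )

    # -- basic properties ---------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def height(self) -> float:
        """Tree height in Myr (mean tip height; tips agree within tolerance)."""
        return float(self.heights[: self.n_tips].mean())

    def tip_index(self, label: str) -> int:
        try:
            return self.tip_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown tip label {label!r}") from None

    def postorder(self) -> list[int]:
        return _postorder(self.parent, self.children, self.root)

    def preorder(self) -> list[int]:
        return _preorder(self.parent, self.children, self.root)

    def internal_nodes(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.children[i]]

    def tips_below(self, node: int) -> np.ndarray:
        """Sorted tip indices descending from ``node`` (itself if a tip)."""
        stack, tips = [node], []
        while stack:
            i = stack.pop()
            if not self.children[i]:
                tips.append(i)
            else:
                stack.extend(self.children[i])
        return np.array(sorted(tips), dtype=int)

    def mrca(self, labels: Sequence[str]) -> int:
        idx = {self.tip_index(l) for l in labels}
        if not idx:
            raise ValueError("mrca of empty set")
        node_sets = {}
        for i in self.postorder():
            if not self.children[i]:
                node_sets[i] = {i}
            else:
                node_sets[i] = set().union(*(node_sets[c] for c in self.children[i]))
            if idx <= node_sets[i]:
                return i
        raise AssertionError("unreachable: root contains all tips")

    def rescale(self, height: float) -> "Phylogeny":
        """Return a copy scaled to the given total height."""
        k = height / self.height
        return Phylogeny.from_arrays(
            self.tip_labels, self.parent, self.branch_lengths * k, validate=False
        )

    # -- subtree extraction -------------------------------------------------
    def extract(self, labels: Sequence[str]) -> "Phylogeny":
        """Subtree spanned by ``labels``, re-rooted at their MRCA.

        Branch lengths below the MRCA are preserved; degree-2 internal nodes
        created by dropping tips are suppressed (their branch lengths merged).
        Requires at least 2 labels.
        """
        labels = list(labels)
        if len(labels) < 2:
            raise ValueError("subtree extraction needs at least 2 tips")
        keep = {self.tip_index(l) for l in labels}
        mrca = self.mrca(labels)
        # bottom-up: map old node -> (representative subtree info)
        new_parent: list[int] = []
        new_blen: list[float] = []
        new_labels: list[str] = []

        def build(node: int) -> tuple[int, float] | None:
            """Return (new node id, pending branch length) or None if pruned."""
            if not self.children[node]:
                if node not in keep:
                    return None
                new_labels.append(self.tip_labels[node])
                new_parent.append(-2)  # placeholder
                new_blen.append(0.0)
                return len(new_parent) - 1, float(self.branch_lengths[node])
            kept = []
            for c in self.children[node]:
                r = build(c)
                if r is not None:
                    kept.append(r)
            if not kept:
                return None
            if len(kept) == 1:
                nid, bl = kept[0]
                return nid, bl + float(self.branch_lengths[node])
            new_parent.append(-2)
            new_blen.append(0.0)
            me = len(new_parent) - 1
            for nid, bl in kept:
                new_parent[nid] = me
                new_blen[nid] = bl
            return me, float(self.branch_lengths[node])

        res = build(mrca)
        assert res is not None
        root_id = res[0]
        new_parent[root_id] = -1
        n_new = len(new_parent)
        # renumber so tips come first, internals after, root last
        has_child = [False] * n_new
        for i, p in enumerate(new_parent):
            if p >= 0:
                has_child[p] = True
        tips_old = [i for i in range(n_new) if not has_child[i]]
        internals_old = [i for i in range(n_new) if has_child[i] and i != root_id]
        order = tips_old + internals_old + [root_id]
        remap = {old: new for new, old in enumerate(order)}
        parent2 = [0] * n_new
        blen2 = [0.0] * n_new
        for old, new in remap.items():
            p = new_parent[old]
            parent2[new] = remap[p] if p >= 0 else -1
            blen2[new] = new_blen[old]
        # new_labels[k] is the label of the k-th created tip placeholder, and
        # tip placeholders are exactly the childless new-ids in creation order
        tip_label_by_old = dict(zip(tips_old, new_labels))
        labels2 = [tip_label_by_old[order[i]] for i in range(len(tips_old))]
        return Phylogeny.from_arrays(labels2, parent2, blen2, validate=False)

    # -- newick -------------------------------------------------------------
    def to_newick(self) -> str:
        def rec(node: int) -> str:
            if not self.children[node]:
                return f"{self.tip_labels[node]}:{float(self.branch_lengths[node])!r}"
            inner = ",".join(rec(c) for c in self.children[node])
            if node == self.root:
                return f"({inner})"
            return f"({inner}):{float(self.branch_lengths[node])!r}"

        return rec(self.root) + ";"


def _preorder(parent, children, root) -> list[int]:
    order, stack = [], [root]
    while stack:
        i = stack.pop()
        order.append(i)
        stack.extend(children[i])
    return order


def _postorder(parent, children, root) -> list[int]:
    return _preorder(parent, children, root)[::-1]


# -- dendropy bridge --------------------------------------------------------

def _from_dendropy(dtree: dendropy.Tree, source: str = "<tree>") -> Phylogeny:
    dtree.is_rooted = True
    nodes = list(dtree.postorder_node_iter())
    tips = [nd for nd in nodes if nd.is_leaf()]
    labels = []
    for nd in tips:
        if nd.taxon is None or not nd.taxon.label:
            raise ValueError(f"{source}: unlabeled tip")
        labels.append(nd.taxon.label)
    order = {}
    for i, nd in enumerate(tips):
        order[id(nd)] = i
    internals = [nd for nd in nodes if not nd.is_leaf()]
    root = dtree.seed_node
    internals = [nd for nd in internals if nd is not root] + [root]
    for i, nd in enumerate(internals):
        order[id(nd)] = len(tips) + i
    parent = np.full(len(nodes), -1, dtype=int)
    blen = np.zeros(len(nodes))
    for nd in nodes:
        i = order[id(nd)]
        if nd.parent_node is not None:
            parent[i] = order[id(nd.parent_node)]
            if nd.edge.length is None:
                who = labels[i] if i < len(tips) else f"internal node {i}"
                raise ValueError(f"{source}: missing branch length above {who}")
            blen[i] = float(nd.edge.length)
    return Phylogeny.from_arrays(labels, parent, blen)


def read_newick(path: str | Path) -> Phylogeny:
    """Read a single rooted newick tree with branch lengths.

    Ultrametricity is validated on load (tolerance 1e-6 x tree height); the
    error names the worst-offending tip.
    """
    path = Path(path)
    dtree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    return _from_dendropy(dtree, source=str(path))


def parse_newick(newick: str) -> Phylogeny:
    """Parse a newick string (same contract as :func:`read_newick`)."""
    dtree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    return _from_dendropy(dtree)


def write_newick(tree: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# -- clade membership -------------------------------------------------------

class CladeMap:
    """Taxon -> clade label map, validated for monophyly against a tree."""

    def __init__(self, assignments: Mapping[str, str]):
        if not assignments:
            raise ValueError("empty clade map")
        self.assignments = dict(assignments)

    @classmethod
    def read_csv(cls, path: str | Path) -> "CladeMap":
        import pandas as pd

        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        if "taxon" not in cols or "clade" not in cols:
            raise ValueError(f"{path}: clade CSV needs columns 'taxon' and 'clade'")
        dup = df[cols["taxon"]].duplicated()
        if dup.any():
            raise ValueError(f"{path}: duplicate taxa: {df[cols['taxon']][dup].tolist()}")
        return cls(dict(zip(df[cols["taxon"]].astype(str), df[cols["clade"]].astype(str))))

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("taxon,clade\n")
            for taxon, clade in self.assignments.items():
                fh.write(f"{taxon},{clade}\n")

    @property
    def clades(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.assignments.values():
            seen.setdefault(c, None)
        return list(seen)

    def members(self, clade: str) -> list[str]:
        out = [t for t, c in self.assignments.items() if c == clade]
        if not out:
            raise KeyError(f"unknown clade {clade!r}")
        return out

    def validate(self, tree: Phylogeny) -> None:
        """Every tip assigned exactly once and every clade monophyletic."""
        tips = set(tree.tip_labels)
        assigned = set(self.assignments)
        if tips != assigned:
            missing = sorted(tips - assigned)
            extra = sorted(assigned - tips)
            raise ValueError(
                f"clade map does not match tree tips (missing={missing}, extra={extra})"
            )
        for clade in self.clades:
            members = self.members(clade)
            if len(members) == 1:
                continue
            node = tree.mrca(members)
            below = {tree.tip_labels[i] for i in tree.tips_below(node)}
            if below != set(members):
                raise ValueError(
                    f"clade {clade!r} is not monophyletic: MRCA also contains "
                    f"{sorted(below - set(members))}"
                )
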