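"""Neighbor-joining trees and species-monophyly assessment.

Implements Saitou-Nei neighbor joining on a K2P distance matrix with
deterministic tie-breaking (lowest index pair), negative branch-length
clamping, newick round-tripping, and an outgroup-rooted check of whether
each species' sequences form an exclusive clade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np

from barcodeid.distances import DistanceMatrix


@dataclass
class TreeNode:
    """Tree node; ``length`` is the branch to the parent (None at root)."""

    name: str | None = None
    length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(leaf.name for leaf in self.leaves())


@dataclass
class PhyloTree:
    """Unrooted (root trifurcation) or rooted tree over sequence IDs.

    ``clamped`` flags that one or more negative NJ branch-length estimates
    were clamped to zero.
    """

    root: TreeNode
    rooted: bool = False
    clamped: bool = False

    def leaf_names(self) -> frozenset[str]:
        return self.root.leaf_names()

    def clades(self) -> set[frozenset[str]]:
        """Leaf-name sets of every node (meaningful on a rooted tree)."""
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                s = frozenset([node.name])
            else:
                s = frozenset().union(*(walk(ch) for ch in node.children))
            out.add(s)
            return s

        walk(self.root)
        return out

    def bipartitions(self) -> set[frozenset[frozenset[str]]]:
        """Non-trivial splits induced by internal edges (topology
        comparison helper, rooting-insensitive)."""
        all_leaves = self.leaf_names()
        splits: set[frozenset[frozenset[str]]] = set()
        for clade in self.clades():
            other = all_leaves - clade
            if len(clade) >= 2 and len(other) >= 2:
                splits.add(frozenset((clade, other)))
        return splits

    def to_newick(self) -> str:
        def render(node: TreeNode) -> str:
            if node.is_leaf:
                body = node.name
            else:
                body = "(" + ",".join(render(c) for c in node.children) + ")"
            if node.length is not None:
                body += f":{node.length:.10g}"
            return body

        return render(self.root) + ";"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def read_newick(source: str | Path) -> PhyloTree:
    """Read a newick tree (string or file path) into a :class:`PhyloTree`."""
    text = str(source)
    if not text.strip().endswith(";") and Path(text).exists():
        text = Path(text).read_text()
    dtree = dendropy.Tree.get(data=text, schema="newick",
                              preserve_underscores=True)

    def convert(dnode) -> TreeNode:
        node = TreeNode(
            name=(dnode.taxon.label if dnode.taxon is not None
                  else dnode.label),
            length=(float(dnode.edge.length)
                    if dnode.edge.length is not None else None),
        )
        node.children = [convert(ch) for ch in dnode.child_nodes()]
        return node

    root = convert(dtree.seed_node)
    return PhyloTree(root, rooted=len(root.children) == 2)


def neighbor_joining(matrix: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Joins are chosen by the minimal Q-criterion with ties broken towards
    the lexicographically lowest index pair; an additive input matrix is
    reconstructed exactly. Undefined (NaN) distances raise.
    """
    n = len(matrix.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 sequences")
    if np.isnan(matrix.d).any():
        bad = [(matrix.ids[i], matrix.ids[j])
               for i, j in zip(*np.where(np.isnan(matrix.d))) if i < j]
        raise ValueError(f"undefined distances in matrix: {bad[:5]}")

    D = matrix.d.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in matrix.ids]
    active = list(range(n))
    clamped = False

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0.0:
            clamped = True
        return x if x > 0.0 else 0.0  # also normalizes -0.0

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        best_pair = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best:
                    best, best_pair = q, (i, j)
        i, j = best_pair
        li = clamp(0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2)))
        lj = clamp(D[i, j] - (0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))))
        nodes[i].length, nodes[j].length = li, lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        # grow D in place: new node takes a fresh row/column
        u = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            D[u, k] = D[k, u] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    la = clamp(0.5 * (D[a, b] + D[a, c] - D[b, c]))
    lb = clamp(0.5 * (D[a, b] + D[b, c] - D[a, c]))
    lc = clamp(0.5 * (D[a, c] + D[b, c] - D[a, b]))
    for idx, ln in zip((a, b, c), (la, lb, lc)):
        nodes[idx].length = ln
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return PhyloTree(root, rooted=False, clamped=clamped)


def root_at_outgroup(tree: PhyloTree, outgroup_id: str) -> PhyloTree:
    """Root an unrooted tree on the branch leading to the outgroup leaf,
    making the outgroup sister to all remaining taxa."""
    # adjacency over the undirected tree
    adj: dict[int, list[tuple[int, float]]] = {}
    names: dict[int, str | None] = {}
    counter = [0]

    def build(node: TreeNode, parent: int | None) -> int:
        nid = counter[0]
        counter[0] += 1
        names[nid] = node.name
        adj.setdefault(nid, [])
        if parent is not None:
            length = node.length if node.length is not None else 0.0
            adj[nid].append((parent, length))
            adj[parent].append((nid, length))
        for ch in node.children:
            build(ch, nid)
        return nid

    build(tree.root, None)
    out_id = next((nid for nid, nm in names.items() if nm == outgroup_id),
                  None)
    if out_id is None:
        raise ValueError(f"outgroup {outgroup_id!r} not found among leaves")

    def orient(nid: int, avoid: int, length: float) -> TreeNode:
        node = TreeNode(name=names[nid], length=length)
        kids = [(k, ln) for k, ln in adj[nid] if k != avoid]
        node.children = [orient(k, nid, ln) for k, ln in kids]
        # suppress degree-2 nodes created by re-orientation
        if len(node.children) == 1 and node.name is None:
            child = node.children[0]
            child.length = (child.length or 0.0) + (length or 0.0)
            return child
        return node

    (neigh, ln) = adj[out_id][0]
    half = 0.5 * ln
    root = TreeNode(children=[
        TreeNode(name=outgroup_id, length=half),
        orient(neigh, out_id, half),
    ])
    return PhyloTree(root, rooted=True, clamped=tree.clamped)


@dataclass(frozen=True)
class MonophylyReport:
    outgroup_id: str
    monophyletic: dict[str, bool]
    singletons: tuple[str, ...]

    @property
    def n_species(self) -> int:
        return len(self.monophyletic)

    @property
    def n_monophyletic(self) -> int:
        return sum(self.monophyletic.values())

    @property
    def all_monophyletic(self) -> bool:
        return all(self.monophyletic.values())


def species_monophyly(tree: PhyloTree, species_map: Mapping[str, str],
                      outgroup_id: str) -> MonophylyReport:
    """Root at the outgroup and test each ingroup species for monophyly.

    A species is monophyletic when some clade of the rooted tree contains
    exactly its sequences; single-sequence species are trivially
    monophyletic and reported as singletons.
    """
    leaves = tree.leaf_names()
    if outgroup_id not in leaves:
        raise ValueError(f"outgroup {outgroup_id!r} not in tree")
    unmapped = [l for l in leaves if l != outgroup_id
                and l not in species_map]
    if unmapped:
        raise ValueError(f"leaves without species label: {sorted(unmapped)}")

    rooted = tree if tree.rooted else root_at_outgroup(tree, outgroup_id)
    clades = rooted.clades()

    members: dict[str, set[str]] = {}
    for leaf in leaves:
        if leaf == outgroup_id:
            continue
        members.setdefault(species_map[leaf], set()).add(leaf)

    mono: dict[str, bool] = {}
    singles: list[str] = []
    for sp, ids in members.items():
        if len(ids) == 1:
            mono[sp] = True
            singles.append(sp)
        else:
            mono[sp] = frozenset(ids) in clades
    return MonophylyReport(outgroup_id, mono, tuple(sorted(singles)))
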