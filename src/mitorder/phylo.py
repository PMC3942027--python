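"""Thin wrapper around dendropy trees.

Provides what the gene-order analyses need from a phylogeny and nothing
more: leaf lookup, patristic distances, and a root-independent enumeration
of branches.  Branches are identified by the bipartition of the leaf set
they induce, so path indicators (used by the branch-specific GOL
decomposition) do not depend on where the tree happens to be rooted; the
two edges incident to a degree-2 root are merged into a single branch.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .errors import FormatError, LookupError_

__all__ = ["Branch", "PhyloTree", "read_tree", "write_tree"]


@dataclass(frozen=True)
class Branch:
    """One unrooted branch, identified by the smaller side of its split."""

    branch_id: str
    length: float
    clade: frozenset  # leaf labels on one (canonical) side of the split

    def on_path(self, leaf_a: str, leaf_b: str) -> bool:
        return (leaf_a in self.clade) != (leaf_b in self.clade)


class PhyloTree:
    """Rooted tree with branch lengths and a genome-id leaf mapping."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = []
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise FormatError("tree has an unlabeled leaf")
            labels.append(leaf.taxon.label)
        if len(set(labels)) != len(labels):
            raise FormatError("tree has duplicate leaf labels")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise FormatError(f"negative branch length {edge.length}")
        self._leaves = tuple(sorted(labels))
        self._branches = self._collect_branches()

    # -- basic accessors -------------------------------------------------

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return self._leaves

    @property
    def branches(self) -> tuple[Branch, ...]:
        """All unrooted branches (pendant and internal), deduplicated."""
        return self._branches

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def __len__(self) -> int:
        return len(self._leaves)

    def _collect_branches(self) -> tuple[Branch, ...]:
        all_leaves = frozenset(self._leaves)
        by_split: dict[frozenset, float] = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            clade = frozenset(
                lf.taxon.label for lf in node.leaf_iter()
            )
            other = all_leaves - clade
            if not other:
                continue  # edge above the whole leaf set carries no split
            key = min(clade, other, key=lambda s: (len(s), tuple(sorted(s))))
            length = node.edge.length or 0.0
            # both root-adjacent edges induce the same split: merge lengths
            by_split[key] = by_split.get(key, 0.0) + length
        branches = []
        for clade in sorted(by_split, key=lambda s: (len(s), tuple(sorted(s)))):
            branch_id = "|".join(sorted(clade))
            branches.append(Branch(branch_id, by_split[clade], clade))
        return tuple(branches)

    # -- distances -------------------------------------------------------

    def patristic_distance_matrix(self) -> pd.DataFrame:
        """Leaf-by-leaf matrix of path-length (patristic) distances."""
        pdm = self._tree.phylogenetic_distance_matrix()
        labels = self._leaves
        taxa = {t.label: t for t in self._tree.taxon_namespace}
        n = len(labels)
        mat = np.zeros((n, n))
        for i, a in enumerate(labels):
            for j in range(i + 1, n):
                d = pdm.patristic_distance(taxa[a], taxa[labels[j]])
                mat[i, j] = mat[j, i] = d
        return pd.DataFrame(mat, index=labels, columns=labels)

    def patristic_distance(self, a: str, b: str) -> float:
        for label in (a, b):
            if label not in self._leaves:
                raise LookupError_(f"leaf {label!r} not in tree")
        if a == b:
            return 0.0
        total = 0.0
        for br in self._branches:
            if br.on_path(a, b):
                total += br.length
        return total

    # -- serialization ---------------------------------------------------

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True)

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises several parser errors
            raise FormatError(f"could not parse newick: {exc}") from exc
        return cls(tree)


def read_tree(path) -> PhyloTree:
    """Read a rooted newick tree with branch lengths."""
    with open(path) as fh:
        return PhyloTree.from_newick(fh.read())


def write_tree(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_newick())
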