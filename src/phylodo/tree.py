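"""Phylogenies: Newick I/O (via dendropy) and a compiled array form.

Branch lengths are in expected substitutions per site (the unit fixed by the
generator normalization).  The likelihood machinery consumes a compiled
postorder representation; the dendropy tree remains the structural source of
truth so rerooting and serialization stay standard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from ._util import path_or_text as _path_or_text

__all__ = ["Phylogeny", "CompiledTree"]


@dataclass(eq=False)
class CompiledTree:
    """Array view of a rooted tree for pruning-style dynamic programs."""

    children: list[list[int]]  # child node ids per node
    parent: np.ndarray  # parent id, -1 at root
    lengths: np.ndarray  # branch length above each node, 0 at root
    postorder: np.ndarray  # node ids, children before parents
    leaf_index: dict[str, int]  # leaf name -> node id

    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    @property
    def root(self) -> int:
        return int(self.postorder[-1])


class Phylogeny:
    """A tree with named leaves and nonnegative branch lengths."""

    def __init__(self, dtree: dendropy.Tree):
        self._tree = dtree
        self._compiled: CompiledTree | None = None
        names = [leaf.taxon.label for leaf in dtree.leaf_node_iter()]
        if len(set(names)) != len(names):
            raise ValueError("duplicate leaf names")
        for edge in dtree.preorder_edge_iter():
            if edge.length is None:
                if edge.head_node is not dtree.seed_node:
                    warnings.warn("missing branch length set to 0")
                edge.length = 0.0
            elif edge.length < 0:
                warnings.warn(f"negative branch length {edge.length} clamped to 0")
                edge.length = 0.0

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, path_or_text) -> "Phylogeny":
        text = _path_or_text(path_or_text)
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True
            )
        except dendropy.utility.error.DataParseError as exc:
            kind = "duplicate leaf names" if "Duplicate taxon" in str(exc) else "malformed newick"
            raise ValueError(f"{kind}: {exc}") from None
        return cls(dtree)

    def to_newick(self, path=None, digits: int = 10) -> str:
        text = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=f".{digits}g",
        ).strip() + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    # -- basic queries -----------------------------------------------------

    @property
    def leaf_names(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return len(self._tree.leaf_nodes())

    def tree_length(self) -> float:
        return float(
            sum(e.length or 0.0 for e in self._tree.preorder_edge_iter())
        )

    def scaled(self, factor: float) -> "Phylogeny":
        clone = self._tree.clone(depth=1)
        for e in clone.preorder_edge_iter():
            if e.length is not None:
                e.length = e.length * factor
        return Phylogeny(clone)

    def pruned_to(self, names) -> "Phylogeny":
        """Restrict the tree to the given leaf set (for row resampling)."""
        keep = set(names)
        missing = keep - set(self.leaf_names)
        if missing:
            raise ValueError(f"leaves not in tree: {sorted(missing)}")
        clone = self._tree.clone(depth=1)
        clone.retain_taxa_with_labels(sorted(keep))
        clone.seed_node.edge.length = 0.0
        return Phylogeny(clone)

    def rerooted_above(self, leaf_name: str, fraction: float = 0.5) -> "Phylogeny":
        """Reroot on the branch above a leaf (for pulley-principle checks)."""
        clone = self._tree.clone(depth=1)
        node = None
        for leaf in clone.leaf_node_iter():
            if leaf.taxon.label == leaf_name:
                node = leaf
                break
        if node is None:
            raise ValueError(f"no leaf named {leaf_name!r}")
        total = node.edge.length or 0.0
        clone.reroot_at_edge(
            node.edge,
            length1=total * (1 - fraction),
            length2=total * fraction,
            update_bipartitions=False,
        )
        return Phylogeny(clone)

    # -- compiled form -----------------------------------------------------

    def compiled(self) -> CompiledTree:
        if self._compiled is None:
            nodes = list(self._tree.postorder_node_iter())
            index = {id(n): i for i, n in enumerate(nodes)}
            children: list[list[int]] = [[] for _ in nodes]
            parent = np.full(len(nodes), -1, dtype=int)
            lengths = np.zeros(len(nodes))
            leaf_index: dict[str, int] = {}
            for i, n in enumerate(nodes):
                if n.parent_node is not None:
                    parent[i] = index[id(n.parent_node)]
                    lengths[i] = n.edge.length or 0.0
                for c in n.child_nodes():
                    children[i].append(index[id(c)])
                if n.is_leaf():
                    leaf_index[n.taxon.label] = i
            self._compiled = CompiledTree(
                children=children,
                parent=parent,
                lengths=lengths,
                postorder=np.arange(len(nodes)),
                leaf_index=leaf_index,
            )
        return self._compiled
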