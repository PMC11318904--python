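"""Rooted phylogenies and the tree-metric primitives built on them.

A :class:`Phylogeny` wraps a rooted, edge-weighted dendropy tree and exposes
the quantities every downstream community statistic consumes: the cophenetic
(patristic) distance matrix between tips, Faith's phylogenetic diversity of a
tip subset, and the set of edges spanned by a tip subset (used by the
phylogenetic Sorensen decomposition).

Branch lengths may be zero (e.g. polytomies resolved with zero-length edges)
but never negative; ultrametricity is not assumed anywhere. Internal node
labels are preserved on round-trip but ignored by all metrics. The edge above
the root, if present in the input file, is preserved on output but does not
contribute to any metric.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import dendropy
import numpy as np
from skbio import DistanceMatrix

from .errors import DomainError, LookupError_, TreeFormatError, ValidationError

__all__ = [
    "Phylogeny",
    "read_tree",
    "write_tree",
    "cophenetic_distances",
    "faith_pd",
]


class Phylogeny:
    """A validated rooted tree with non-negative branch lengths.

    Parameters
    ----------
    tree:
        A rooted ``dendropy.Tree``. Missing branch lengths are treated as 0.

    Attributes
    ----------
    tip_labels:
        Tip labels in a fixed traversal order; all metrics index tips by
        position in this list.
    edge_lengths:
        Length of every edge (one per non-root node), shape ``(E,)``.
    edge_tips:
        Boolean incidence matrix of shape ``(E, T)``: ``edge_tips[e, t]`` is
        True when tip ``t`` descends from edge ``e``'s child node.
    """

    def __init__(self, tree: dendropy.Tree):
        if tree.seed_node is None:
            raise ValidationError("tree has no root node")
        self._tree = tree
        tips = [leaf for leaf in tree.leaf_node_iter()]
        labels = []
        for leaf in tips:
            label = leaf.taxon.label if leaf.taxon is not None else leaf.label
            if label is None or str(label).strip() == "":
                raise ValidationError("every tip must carry a non-empty label")
            labels.append(str(label))
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValidationError(f"duplicate tip labels: {dupes}")
        self.tip_labels: list[str] = labels
        self._tip_index = {lab: i for i, lab in enumerate(labels)}
        self._leaf_nodes = tips

        # One edge per non-root node; record length and the tips below it.
        n_tips = len(labels)
        edge_nodes = [nd for nd in tree.preorder_node_iter() if nd.parent_node is not None]
        lengths = np.zeros(len(edge_nodes), dtype=float)
        incidence = np.zeros((len(edge_nodes), n_tips), dtype=bool)
        node_edge = {id(nd): e for e, nd in enumerate(edge_nodes)}
        # postorder: propagate tip sets upward
        below: dict[int, np.ndarray] = {}
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                label = nd.taxon.label if nd.taxon is not None else nd.label
                mask = np.zeros(n_tips, dtype=bool)
                mask[self._tip_index[str(label)]] = True
            else:
                mask = np.zeros(n_tips, dtype=bool)
                for ch in nd.child_nodes():
                    mask |= below[id(ch)]
            below[id(nd)] = mask
            if nd.parent_node is not None:
                e = node_edge[id(nd)]
                bl = nd.edge.length
                if bl is None:
                    bl = 0.0
                bl = float(bl)
                if not np.isfinite(bl):
                    raise ValidationError("branch lengths must be finite")
                if bl < 0:
                    raise ValidationError(f"negative branch length {bl!r}")
                lengths[e] = bl
                incidence[e] = mask
        self.edge_lengths: np.ndarray = lengths
        self.edge_tips: np.ndarray = incidence
        self._edge_tip_counts = incidence.sum(axis=1)
        self._edge_tips_f32 = incidence.astype(np.float32)

    # ------------------------------------------------------------------ #

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def total_branch_length(self) -> float:
        """Sum of all branch lengths (root edge excluded)."""
        return float(self.edge_lengths.sum())

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def tip_indices(self, taxa: Iterable[str]) -> np.ndarray:
        """Map tip labels to positional indices, erroring on unknown taxa."""
        taxa = list(taxa)
        missing = [t for t in taxa if t not in self._tip_index]
        if missing:
            raise LookupError_(f"taxa not in tree: {sorted(missing)}")
        return np.asarray([self._tip_index[t] for t in taxa], dtype=np.intp)

    # -- spanning-subtree machinery ------------------------------------ #

    def spanning_edges(self, taxa: Iterable[str], include_root: bool = True) -> np.ndarray:
        """Boolean mask over edges spanned by ``taxa``.

        With ``include_root`` the mask covers the union of tip-to-root paths;
        without it, edges on or above the taxa's most recent common ancestor
        are dropped, leaving only the minimal connecting subtree.
        """
        idx = self.tip_indices(taxa)
        if idx.size == 0:
            raise DomainError("empty taxon set has no spanning subtree")
        counts = self.edge_tips[:, idx].sum(axis=1)
        if include_root:
            return counts > 0
        return (counts > 0) & (counts < idx.size)

    def faith_pd(self, taxa: Iterable[str], include_root: bool = True) -> float:
        """Faith's PD: total branch length of the subtree spanning ``taxa``."""
        mask = self.spanning_edges(taxa, include_root=include_root)
        return float(self.edge_lengths[mask].sum())

    def pd_batch(self, communities: np.ndarray, include_root: bool = True) -> np.ndarray:
        """Faith's PD for many communities at once.

        ``communities`` is a boolean/0-1 array of shape ``(T, S)`` (tips x
        communities); returns shape ``(S,)``. Used by the null machinery.
        """
        comm = np.ascontiguousarray(communities, dtype=np.float32)
        counts = self._edge_tips_f32 @ comm  # (E, S)
        present = counts > 0
        if not include_root:
            richness = comm.sum(axis=0)  # (S,)
            present &= counts < richness[np.newaxis, :]
        return self.edge_lengths @ present

    # -- I/O ------------------------------------------------------------ #

    def write(self, path, format: str = "newick") -> None:
        write_tree(self, path, format=format)

    def as_newick(self) -> str:
        s = self._tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip()

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny: {self.n_tips} tips, total branch length {self.total_branch_length:g}>"


def read_tree(path, format: str = "newick") -> Phylogeny:
    """Read a rooted phylogeny from a Newick or NEXUS file.

    Parameters
    ----------
    path:
        File path (or string path) to read.
    format:
        ``"newick"`` or ``"nexus"``.
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"unknown tree format {format!r}")
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema=format,
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except (dendropy.utility.error.DataParseError, ValueError) as exc:
        if "uplicate" in str(exc):
            raise ValidationError(f"duplicate tip labels in {path}: {exc}") from exc
        raise TreeFormatError(f"could not parse {path} as {format}: {exc}") from exc
    return Phylogeny(tree)


def tree_from_newick(newick: str) -> Phylogeny:
    """Build a :class:`Phylogeny` from a Newick string in memory."""
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except (dendropy.utility.error.DataParseError, ValueError) as exc:
        if "uplicate" in str(exc):
            raise ValidationError(f"duplicate tip labels: {exc}") from exc
        raise TreeFormatError(f"could not parse newick string: {exc}") from exc
    return Phylogeny(tree)


def write_tree(tree: Phylogeny, path, format: str = "newick") -> None:
    """Write a phylogeny to Newick or NEXUS, preserving labels and lengths."""
    if format not in ("newick", "nexus"):
        raise ValueError(f"unknown tree format {format!r}")
    tree.dendropy_tree.write(
        path=str(path),
        schema=format,
        suppress_rooting=True,
        unquoted_underscores=True,
    )


def cophenetic_distances(tree: Phylogeny) -> DistanceMatrix:
    """All-pairs patristic distances between tips.

    Entry (i, j) is the sum of branch lengths along the path between tips i
    and j. Computed as depth(i) + depth(j) - 2 depth(lca(i, j)) by a single
    postorder sweep; O(T^2) overall.
    """
    n = tree.n_tips
    D = np.zeros((n, n), dtype=float)
    depth: dict[int, float] = {}
    dtree = tree.dendropy_tree
    for nd in dtree.preorder_node_iter():
        if nd.parent_node is None:
            depth[id(nd)] = 0.0
        else:
            bl = nd.edge.length or 0.0
            depth[id(nd)] = depth[id(nd.parent_node)] + float(bl)

    tip_depth = np.zeros(n)
    below: dict[int, np.ndarray] = {}
    for nd in dtree.postorder_node_iter():
        if nd.is_leaf():
            label = nd.taxon.label if nd.taxon is not None else nd.label
            i = tree.tip_indices([str(label)])[0]
            tip_depth[i] = depth[id(nd)]
            below[id(nd)] = np.asarray([i], dtype=np.intp)
        else:
            groups = [below.pop(id(ch)) for ch in nd.child_nodes()]
            h = depth[id(nd)]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    a, b = groups[gi], groups[gj]
                    block = tip_depth[a][:, None] + tip_depth[b][None, :] - 2.0 * h
                    D[np.ix_(a, b)] = block
                    D[np.ix_(b, a)] = block.T
            below[id(nd)] = np.concatenate(groups) if groups else np.asarray([], dtype=np.intp)
    # exact symmetry and zero diagonal by construction; clip tiny negatives
    np.fill_diagonal(D, 0.0)
    D[D < 0] = 0.0
    return DistanceMatrix(D, ids=tree.tip_labels)


def faith_pd(tree: Phylogeny, taxa: Iterable[str] | Sequence[str], include_root: bool = True) -> float:
    """Module-level convenience wrapper around :meth:`Phylogeny.faith_pd`."""
    taxa = list(taxa)
    if not taxa:
        raise DomainError("Faith's PD is undefined for an empty taxon set")
    return tree.faith_pd(taxa, include_root=include_root)
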