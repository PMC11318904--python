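"""Pairwise community dissimilarity, phylogenetic and species-based.

Both variants follow the same Sorensen-family algebra on a triplet
(a, b, c): ``a`` is what the two communities share, ``b`` and ``c`` what is
unique to each. For the species variant these are species counts; for the
phylogenetic variant (PhyloSor) they are branch lengths of the two spanning
subtrees — ``a`` the length lying in both, ``b``/``c`` the lengths unique to
each. The total dissimilarity is decomposed, Baselga-style, into a true
turnover (replacement) part and a nestedness (richness-difference) part:

    beta_sor = (b + c) / (2a + b + c)          total dissimilarity
    beta_sim = min(b, c) / (a + min(b, c))     turnover
    beta_sne = beta_sor - beta_sim             nestedness

so beta_sor = beta_sim + beta_sne exactly, and a nested pair (one community's
branches/species a subset of the other's) has beta_sim = 0.

Shared branch length is computed on the spanning subtrees including their
paths to the root when ``include_root`` is set (the default, consistent with
Faith's PD), which makes a + b = PD(community 1) hold by construction.

COMDIST is the mean cophenetic distance over all between-community tip
pairs; a hierarchical clustering of the resulting site x site matrix
summarises which communities draw on similar parts of the phylogeny.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix

from .community import CommunityMatrix
from .errors import DomainError, ValidationError
from .trees import Phylogeny, cophenetic_distances

__all__ = [
    "BetaComponents",
    "BetaDecomposition",
    "BetaMatrices",
    "phylosor_pair",
    "sorensen_pair",
    "beta_matrices",
    "comdist",
    "comdist_matrix",
    "Dendrogram",
    "cluster_dendrogram",
]

LINKAGE_METHODS = ("average", "complete", "single")


@dataclass(frozen=True)
class BetaComponents:
    """Shared / unique quantities for one community pair.

    ``a`` is shared (branch length or species count), ``b`` unique to the
    first community, ``c`` unique to the second.
    """

    a: float
    b: float
    c: float


@dataclass(frozen=True)
class BetaDecomposition:
    """Sorensen dissimilarity split into turnover and nestedness."""

    beta_sor: float
    beta_sim: float
    beta_sne: float
    variant: str  # "species" | "phylogenetic"

    @property
    def similarity(self) -> float:
        """The Sorensen-type similarity 2a/(2a+b+c) = 1 - beta_sor."""
        return 1.0 - self.beta_sor


def _decompose(comp: BetaComponents, variant: str) -> BetaDecomposition:
    a, b, c = comp.a, comp.b, comp.c
    denom = 2 * a + b + c
    beta_sor = (b + c) / denom if denom > 0 else 0.0
    m = min(b, c)
    beta_sim = m / (a + m) if (a + m) > 0 else 0.0
    beta_sne = beta_sor - beta_sim
    if beta_sne < 0:  # roundoff when b ~ c; mathematically beta_sne >= 0
        beta_sim, beta_sne = beta_sor, 0.0
    return BetaDecomposition(beta_sor, beta_sim, beta_sne, variant)


def phylosor_pair(
    taxa1, taxa2, tree: Phylogeny, include_root: bool = True
) -> tuple[BetaComponents, BetaDecomposition]:
    """PhyloSor components and decomposition for one pair of communities."""
    taxa1, taxa2 = list(taxa1), list(taxa2)
    if not taxa1 or not taxa2:
        raise DomainError("both communities must be non-empty")
    e1 = tree.spanning_edges(taxa1, include_root=include_root)
    e2 = tree.spanning_edges(taxa2, include_root=include_root)
    w = tree.edge_lengths
    comp = BetaComponents(
        a=float(w[e1 & e2].sum()),
        b=float(w[e1 & ~e2].sum()),
        c=float(w[e2 & ~e1].sum()),
    )
    return comp, _decompose(comp, "phylogenetic")


def sorensen_pair(taxa1, taxa2) -> tuple[BetaComponents, BetaDecomposition]:
    """Species-level Sorensen components and decomposition."""
    s1, s2 = set(taxa1), set(taxa2)
    if not s1 or not s2:
        raise DomainError("both communities must be non-empty")
    comp = BetaComponents(
        a=float(len(s1 & s2)), b=float(len(s1 - s2)), c=float(len(s2 - s1))
    )
    return comp, _decompose(comp, "species")


@dataclass
class BetaMatrices:
    """Site x site dissimilarity matrices for one variant."""

    sor: DistanceMatrix
    sim: DistanceMatrix
    sne: DistanceMatrix
    variant: str


def beta_matrices(
    matrix: CommunityMatrix,
    tree: Phylogeny | None = None,
    include_root: bool = True,
) -> BetaMatrices:
    """All pairwise decompositions over a community matrix.

    With a tree, the phylogenetic (PhyloSor) variant; without, the species
    variant.
    """
    sites = matrix.sites
    n = len(sites)
    sor = np.zeros((n, n))
    sim = np.zeros((n, n))
    sne = np.zeros((n, n))
    communities = [matrix.species_at(s) for s in sites]
    edge_sets = None
    if tree is not None:
        edge_sets = [tree.spanning_edges(c, include_root=include_root) for c in communities]
    for i in range(n):
        for j in range(i + 1, n):
            if tree is not None:
                w = tree.edge_lengths
                e1, e2 = edge_sets[i], edge_sets[j]
                comp = BetaComponents(
                    a=float(w[e1 & e2].sum()),
                    b=float(w[e1 & ~e2].sum()),
                    c=float(w[e2 & ~e1].sum()),
                )
                dec = _decompose(comp, "phylogenetic")
            else:
                _, dec = sorensen_pair(communities[i], communities[j])
            sor[i, j] = sor[j, i] = dec.beta_sor
            sim[i, j] = sim[j, i] = dec.beta_sim
            sne[i, j] = sne[j, i] = dec.beta_sne
    variant = "phylogenetic" if tree is not None else "species"
    return BetaMatrices(
        sor=DistanceMatrix(sor, ids=sites),
        sim=DistanceMatrix(sim, ids=sites),
        sne=DistanceMatrix(sne, ids=sites),
        variant=variant,
    )


def comdist(taxa1, taxa2, dist: DistanceMatrix) -> float:
    """Mean cophenetic distance over all between-community tip pairs.

    Shared species contribute their zero self-distances, so two identical
    single-species communities are at distance 0.
    """
    taxa1, taxa2 = list(taxa1), list(taxa2)
    if not taxa1 or not taxa2:
        raise DomainError("both communities must be non-empty")
    index = {lab: i for i, lab in enumerate(dist.ids)}
    i1 = np.asarray([index[t] for t in taxa1], dtype=np.intp)
    i2 = np.asarray([index[t] for t in taxa2], dtype=np.intp)
    return float(dist.data[np.ix_(i1, i2)].mean())


def comdist_matrix(
    matrix: CommunityMatrix, tree: Phylogeny, dist: DistanceMatrix | None = None
) -> DistanceMatrix:
    """Site x site COMDIST matrix (unweighted, presence/absence)."""
    if dist is None:
        dist = cophenetic_distances(tree)
    sites = matrix.sites
    communities = [matrix.species_at(s) for s in sites]
    n = len(sites)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = comdist(communities[i], communities[j], dist)
    return DistanceMatrix(out, ids=sites)


@dataclass
class Dendrogram:
    """Agglomerative clustering of sites with merge heights.

    ``merges`` is a scipy-style linkage matrix; heights are the raw
    between-cluster distances at each merge (not halved).
    """

    labels: list[str]
    merges: np.ndarray
    method: str

    def to_newick(self) -> str:
        """Serialize with branch lengths = parent height - child height."""
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}
        reprs = {i: self.labels[i] for i in range(n)}
        for k, (i, j, h, _) in enumerate(self.merges):
            i, j = int(i), int(j)
            node = n + k
            heights[node] = float(h)
            bl_i = float(h) - heights[i]
            bl_j = float(h) - heights[j]
            reprs[node] = f"({reprs[i]}:{bl_i:.10g},{reprs[j]}:{bl_j:.10g})"
        return reprs[n + len(self.merges) - 1] + ";"


def cluster_dendrogram(dist: DistanceMatrix, method: str = "average") -> Dendrogram:
    """Hierarchical agglomerative clustering of a site distance matrix.

    ``method`` is the linkage rule (average = UPGMA, complete, single).
    Output heights follow the raw merge-distance convention.
    """
    if method not in LINKAGE_METHODS:
        raise ValueError(f"method must be one of {LINKAGE_METHODS}")
    data = np.asarray(dist.data, dtype=float)
    if data.shape[0] < 2:
        raise DomainError("clustering requires at least 2 sites")
    if not np.allclose(data, data.T):
        raise ValidationError("distance matrix must be symmetric")
    Z = scipy_linkage(squareform(data, checks=False), method=method)
    return Dendrogram(labels=list(dist.ids), merges=Z, method=method)
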