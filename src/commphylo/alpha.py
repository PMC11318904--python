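"""Alpha phylogenetic community structure: MPD, MNTD, Faith's PD and their
standardized effect sizes under a taxon-label-shuffling null.

The null model permutes tip labels on the phylogeny uniformly at random
(equivalently, relabels the columns of the occurrence matrix) while leaving
each site's row untouched, so per-site richness is preserved by construction
and every species in the tree's tip pool is exchangeable. Each permutation is
applied once and every site's metric is recomputed from it, giving, per site,
a null ensemble whose sample mean and standard deviation standardize the
observed metric:

    SES = (observed - mean_null) / sd_null

with the conventional sign flips NRI = -SES(MPD) and NTI = -SES(MNTD), so
that positive NRI/NTI indicates phylogenetic clustering (co-occurring taxa
more closely related than expected) and negative values overdispersion.
SES.PD keeps its natural sign: negative means less branch length than
expected for the site's richness. Indices with |value| >= 1.96 are flagged
as significant, the two-sided 5% normal demarcation.

An exhaustive mode replaces Monte-Carlo permutations by enumerating every
distinct assignment of the community's richness to tip identities (all
C(T, r) subsets, each equally probable under uniform label permutation);
feasible only for small trees, it is the exact reference the Monte-Carlo
mode is tested against.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .community import CommunityMatrix
from .errors import DomainError, LookupError_
from .trees import Phylogeny, cophenetic_distances

__all__ = [
    "mpd",
    "mntd",
    "NullEnsemble",
    "shuffle_null",
    "ses_indices",
    "SIGNIFICANCE_THRESHOLD",
]

SIGNIFICANCE_THRESHOLD = 1.96

METRICS = ("MPD", "MNTD", "PD")

_EXHAUSTIVE_LIMIT = 500_000  # max number of enumerated communities


def _as_array(dist) -> tuple[np.ndarray, list[str]]:
    if isinstance(dist, DistanceMatrix):
        return dist.data, list(dist.ids)
    raise TypeError("dist must be a skbio DistanceMatrix")


def mpd(taxa, dist: DistanceMatrix) -> float:
    """Mean pairwise distance among ``taxa`` (unordered pairs, unweighted).

    Returns NaN with a warning when fewer than two taxa are given.
    """
    D, ids = _as_array(dist)
    idx = _lookup(taxa, ids)
    if idx.size < 2:
        warnings.warn("MPD undefined for fewer than 2 taxa; returning NaN")
        return float("nan")
    sub = D[np.ix_(idx, idx)]
    r = idx.size
    return float(sub.sum() / (r * (r - 1)))


def mntd(taxa, dist: DistanceMatrix) -> float:
    """Mean distance from each taxon to its nearest co-occurring taxon."""
    D, ids = _as_array(dist)
    idx = _lookup(taxa, ids)
    if idx.size < 2:
        warnings.warn("MNTD undefined for fewer than 2 taxa; returning NaN")
        return float("nan")
    sub = D[np.ix_(idx, idx)].astype(float).copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def _lookup(taxa, ids) -> np.ndarray:
    index = {lab: i for i, lab in enumerate(ids)}
    taxa = list(taxa)
    missing = [t for t in taxa if t not in index]
    if missing:
        raise LookupError_(f"taxa not in distance matrix: {sorted(missing)}")
    return np.asarray([index[t] for t in taxa], dtype=np.intp)


@dataclass
class NullEnsemble:
    """Null distribution of one metric at one site."""

    metric: str
    site: str
    values: np.ndarray
    iterations: int
    seed: int | None

    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[np.isfinite(self.values)]
        self.mean = float(finite.mean()) if finite.size else float("nan")
        self.sd = float(finite.std(ddof=1)) if finite.size > 1 else float("nan")


class _Engine:
    """Precomputed state shared by observed and null computations."""

    def __init__(self, matrix: CommunityMatrix, tree: Phylogeny, include_root: bool):
        missing = [sp for sp in matrix.species if sp not in set(tree.tip_labels)]
        if missing:
            raise LookupError_(f"species absent from tree: {missing[:10]}")
        self.matrix = matrix
        self.tree = tree
        self.include_root = include_root
        self.D = cophenetic_distances(tree).data
        # site communities as tip-index arrays over the FULL tree tip pool
        self.site_idx: list[np.ndarray] = []
        for site in matrix.sites:
            self.site_idx.append(tree.tip_indices(matrix.species_at(site)))
        self.T = tree.n_tips

    # -- single-permutation metric kernels ------------------------------ #

    def _mpd_many(self, idx_sets: np.ndarray) -> np.ndarray:
        """MPD for a stack of communities given as an (m, r) index array."""
        m, r = idx_sets.shape
        sub = self.D[idx_sets[:, :, None], idx_sets[:, None, :]]
        return sub.sum(axis=(1, 2)) / (r * (r - 1))

    def _mntd_many(self, idx_sets: np.ndarray) -> np.ndarray:
        m, r = idx_sets.shape
        sub = self.D[idx_sets[:, :, None], idx_sets[:, None, :]].copy()
        ar = np.arange(r)
        sub[:, ar, ar] = np.inf
        return sub.min(axis=2).mean(axis=1)

    def _pd_many(self, idx_sets: np.ndarray) -> np.ndarray:
        m, r = idx_sets.shape
        comm = np.zeros((self.T, m), dtype=np.float32)
        comm[idx_sets.ravel(), np.repeat(np.arange(m), r)] = 1.0
        return self.tree.pd_batch(comm, include_root=self.include_root)

    def metric_many(self, metric: str, idx_sets: np.ndarray) -> np.ndarray:
        if metric == "MPD":
            return self._mpd_many(idx_sets)
        if metric == "MNTD":
            return self._mntd_many(idx_sets)
        if metric == "PD":
            return self._pd_many(idx_sets)
        raise ValueError(f"unknown metric {metric!r}")

    def observed(self, metric: str) -> np.ndarray:
        out = np.full(len(self.site_idx), np.nan)
        for s, idx in enumerate(self.site_idx):
            if metric in ("MPD", "MNTD") and idx.size < 2:
                continue
            if idx.size == 0:
                continue
            out[s] = self.metric_many(metric, idx[None, :])[0]
        return out

    def null_matrix(self, metric: str, iterations: int, rng: np.random.Generator,
                    chunk: int = 200) -> np.ndarray:
        """Null values, shape (n_sites, iterations).

        Each iteration draws one uniform permutation of all tip labels and
        recomputes the metric for every site from that same permutation.
        """
        S = len(self.site_idx)
        out = np.full((S, iterations), np.nan)
        done = 0
        while done < iterations:
            k = min(chunk, iterations - done)
            perms = np.empty((k, self.T), dtype=np.intp)
            for i in range(k):
                perms[i] = rng.permutation(self.T)
            for s, idx in enumerate(self.site_idx):
                if idx.size == 0 or (metric in ("MPD", "MNTD") and idx.size < 2):
                    continue
                out[s, done:done + k] = self.metric_many(metric, perms[:, idx])
            done += k
        return out

    def exhaustive_matrix(self, metric: str) -> dict[int, np.ndarray]:
        """Exact null per distinct richness: metric over all C(T, r) subsets."""
        by_r: dict[int, np.ndarray] = {}
        for idx in self.site_idx:
            r = idx.size
            if r in by_r or r == 0 or (metric in ("MPD", "MNTD") and r < 2):
                continue
            n_comb = math.comb(self.T, r)
            if n_comb > _EXHAUSTIVE_LIMIT:
                raise DomainError(
                    f"exhaustive null infeasible: C({self.T},{r}) = {n_comb} communities"
                )
            sets = np.fromiter(
                (i for combo in combinations(range(self.T), r) for i in combo),
                dtype=np.intp, count=n_comb * r,
            ).reshape(n_comb, r)
            vals = np.empty(n_comb)
            for start in range(0, n_comb, 4096):
                stop = min(start + 4096, n_comb)
                vals[start:stop] = self.metric_many(metric, sets[start:stop])
            by_r[r] = vals
        return by_r


def shuffle_null(
    matrix: CommunityMatrix,
    tree: Phylogeny,
    metric: str,
    iterations: int = 999,
    seed: int | None = None,
    include_root: bool = True,
    exhaustive: bool = False,
) -> dict[str, NullEnsemble]:
    """Taxon-label-shuffling null ensemble of one metric for every site.

    Returns a mapping site label -> :class:`NullEnsemble`. With
    ``exhaustive=True`` the ensemble enumerates all distinct communities of
    each site's richness instead of sampling permutations (small trees only).
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    eng = _Engine(matrix, tree, include_root)
    if exhaustive:
        by_r = eng.exhaustive_matrix(metric)
        out = {}
        for site, idx in zip(matrix.sites, eng.site_idx):
            vals = by_r.get(idx.size, np.asarray([np.nan]))
            out[site] = NullEnsemble(metric, site, vals, len(vals), seed)
        return out
    rng = np.random.default_rng(seed)
    nulls = eng.null_matrix(metric, iterations, rng)
    return {
        site: NullEnsemble(metric, site, nulls[s], iterations, seed)
        for s, site in enumerate(matrix.sites)
    }


def ses_indices(
    matrix: CommunityMatrix,
    tree: Phylogeny,
    iterations: int = 999,
    seed: int | None = None,
    include_root: bool = True,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Per-site NRI, NTI and SES.PD under the label-shuffling null.

    Returns a DataFrame with one row per site: observed MPD/MNTD/PD, the
    three standardized indices, their |index| >= 1.96 significance flags,
    and the observed value's rank within each null ensemble. Sites with
    richness < 2 get NaN NRI/NTI (MPD/MNTD undefined) but a valid SES.PD.
    A zero null standard deviation yields NaN (flagged not significant),
    never an infinite index. Fully reproducible from ``seed``.
    """
    eng = _Engine(matrix, tree, include_root)
    rng = np.random.default_rng(seed)
    obs = {m: eng.observed(m) for m in METRICS}
    nulls: dict[str, np.ndarray] = {}
    if exhaustive:
        for m in METRICS:
            by_r = eng.exhaustive_matrix(m)
            S = len(eng.site_idx)
            max_len = max((v.size for v in by_r.values()), default=1)
            arr = np.full((S, max_len), np.nan)
            for s, idx in enumerate(eng.site_idx):
                if idx.size in by_r:
                    vals = by_r[idx.size]
                    arr[s, : vals.size] = vals
            nulls[m] = arr
    else:
        for m in METRICS:
            nulls[m] = eng.null_matrix(m, iterations, rng)

    rows = []
    summary = matrix.summarize()
    for s, site in enumerate(matrix.sites):
        row: dict = {
            "site": site,
            "elevation": float(matrix.elevations.iloc[s]),
            "richness": int(summary.richness.iloc[s]),
        }
        ses = {}
        for m in METRICS:
            null_vals = nulls[m][s]
            finite = null_vals[np.isfinite(null_vals)]
            mean = finite.mean() if finite.size else np.nan
            sd = finite.std(ddof=1) if finite.size > 1 else np.nan
            o = obs[m][s]
            if np.isfinite(o) and np.isfinite(sd) and sd > 0:
                ses[m] = (o - mean) / sd
            else:
                ses[m] = np.nan
            row[m.lower()] = o
            row[f"{m.lower()}_null_mean"] = mean
            row[f"{m.lower()}_null_sd"] = sd
            row[f"{m.lower()}_obs_rank"] = (
                int((finite <= o).sum()) if np.isfinite(o) and finite.size else np.nan
            )
        row["nri"] = -ses["MPD"]
        row["nti"] = -ses["MNTD"]
        row["ses_pd"] = ses["PD"]
        for col in ("nri", "nti", "ses_pd"):
            v = row[col]
            row[f"{col}_significant"] = bool(np.isfinite(v) and abs(v) >= SIGNIFICANCE_THRESHOLD)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["iterations"] = iterations
    df.attrs["seed"] = seed
    df.attrs["include_root"] = include_root
    df.attrs["exhaustive"] = exhaustive
    return df
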