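"""Regression of community-structure indices on environmental predictors.

The modelling convention is small-sample information-theoretic: every
candidate ordinary-least-squares model is scored by its maximized Gaussian
log-likelihood with the ML (divide-by-n) residual variance,

    logLik = -(n/2) (log 2*pi + log(RSS/n) + 1),

the residual variance is counted as an estimated parameter (so an
intercept-only model has k = 2), and models are ranked by

    AICc = -2 logLik + 2k + 2k(k+1)/(n - k - 1),

with Akaike weights w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2). This is
the convention of R's ``logLik.lm``/AICc as used in ecological multimodel
inference; with only a handful of sites the small-sample correction term
dominates and punishes every extra predictor heavily.

Also here: z-scoring (sample sd), second-order polynomial fits with a
t-test on the quadratic term, Pearson correlation, and a seed-reproducible
one-sided Mantel permutation test between two distance matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from .errors import DomainError, ValidationError

__all__ = [
    "zscore",
    "ModelFit",
    "fit_ols_ml",
    "aicc",
    "rank_models",
    "candidate_rankings",
    "Poly2Fit",
    "fit_poly2",
    "CorrelationResult",
    "pearson",
    "MantelResult",
    "mantel",
]


def zscore(values) -> np.ndarray:
    """Standardize to mean 0, sample (n-1) standard deviation 1."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DomainError("z-scoring needs at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DomainError("z-scoring a constant vector")
    return (x - x.mean()) / sd


@dataclass
class ModelFit:
    """One fitted OLS model scored for information-theoretic ranking.

    ``k`` counts the intercept, the slopes, and the residual variance.
    """

    response: str
    predictors: tuple[str, ...]
    n: int
    k: int
    coefficients: np.ndarray
    rss: float
    loglik: float
    aicc: float

    @property
    def name(self) -> str:
        return " + ".join(self.predictors) if self.predictors else "Null"


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC; requires n - k - 1 > 0."""
    if n - k - 1 <= 0:
        raise DomainError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _design(X: pd.DataFrame | np.ndarray | None, n: int) -> tuple[np.ndarray, tuple[str, ...]]:
    if X is None:
        return np.ones((n, 1)), ()
    if isinstance(X, pd.DataFrame):
        names = tuple(str(c) for c in X.columns)
        mat = X.to_numpy(dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
        if mat.ndim == 1:
            mat = mat[:, None]
        names = tuple(f"x{i + 1}" for i in range(mat.shape[1]))
    return np.column_stack([np.ones(n), mat]), names


def fit_ols_ml(
    y, X: pd.DataFrame | np.ndarray | None = None, response: str = "y"
) -> ModelFit:
    """Least-squares fit scored with the Gaussian ML log-likelihood.

    ``X`` holds the predictor columns (no intercept column; one is always
    added). ``X=None`` fits the intercept-only (null) model.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    design, names = _design(X, n)
    p = design.shape[1]
    if n <= p:
        raise DomainError(f"need more observations ({n}) than coefficients ({p})")
    if np.linalg.matrix_rank(design) < p:
        raise ValidationError("design matrix is rank deficient")
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    rss = float(resid @ resid)
    if rss <= 0 or rss < 1e-12 * max(1.0, float(y @ y)):
        raise DomainError("residual sum of squares is (numerically) zero; "
                          "Gaussian likelihood is unbounded")
    loglik = -(n / 2.0) * (np.log(2 * np.pi) + np.log(rss / n) + 1.0)
    k = p + 1  # + residual variance
    return ModelFit(
        response=response,
        predictors=names,
        n=n,
        k=k,
        coefficients=beta,
        rss=rss,
        loglik=float(loglik),
        aicc=aicc(float(loglik), k, n),
    )


def rank_models(fits: list[ModelFit]) -> pd.DataFrame:
    """Sort fits by AICc and attach Delta-AICc and Akaike weights."""
    if not fits:
        raise DomainError("no models to rank")
    rows = pd.DataFrame(
        {
            "response": [f.response for f in fits],
            "model": [f.name for f in fits],
            "k": [f.k for f in fits],
            "loglik": [f.loglik for f in fits],
            "aicc": [f.aicc for f in fits],
        }
    )
    rows["delta_aicc"] = rows["aicc"] - rows["aicc"].min()
    rel = np.exp(-rows["delta_aicc"] / 2.0)
    rows["weight"] = rel / rel.sum()
    return rows.sort_values(["aicc", "model"], kind="mergesort").reset_index(drop=True)


def candidate_rankings(
    table: pd.DataFrame,
    responses: list[str],
    predictors: list[str],
) -> pd.DataFrame:
    """Rank, per response, all subsets of the predictors (null included).

    With three predictors this is the fixed eight-model candidate set:
    null, each single predictor, each pair, and the full model.
    """
    frames = []
    for resp in responses:
        y = table[resp].to_numpy(dtype=float)
        fits = []
        for r in range(len(predictors) + 1):
            for cols in combinations(predictors, r):
                X = table[list(cols)] if cols else None
                fits.append(fit_ols_ml(y, X, response=resp))
        frames.append(rank_models(fits))
    return pd.concat(frames, ignore_index=True)


@dataclass
class Poly2Fit:
    """Second-order polynomial fit with a test on the quadratic term."""

    fit: ModelFit
    quadratic_coefficient: float
    quadratic_p: float
    exact: bool  # True when RSS ~ 0 (perfect quadratic), p reported as 0


def fit_poly2(y, x, response: str = "y") -> Poly2Fit:
    """Fit y ~ x + x^2 and report the quadratic term's two-sided t p-value.

    Internally the basis is orthonormalized (QR) for conditioning; the
    reported p-value is invariant to the raw-vs-orthogonal basis choice.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.size
    if n < 4:
        raise DomainError("second-order fit needs at least 4 points")
    raw = np.column_stack([np.ones(n), x, x * x])
    if np.linalg.matrix_rank(raw) < 3:
        raise ValidationError("x gives a rank-deficient quadratic basis")
    Q, R = np.linalg.qr(raw)
    gamma, _, _, _ = np.linalg.lstsq(Q, y, rcond=None)
    resid = y - Q @ gamma
    rss = float(resid @ resid)
    beta = np.linalg.solve(R, gamma)
    loglik = (
        -(n / 2.0) * (np.log(2 * np.pi) + np.log(rss / n) + 1.0)
        if rss > 0
        else np.inf
    )
    k = 4
    fit = ModelFit(
        response=response,
        predictors=("x", "x^2"),
        n=n,
        k=k,
        coefficients=beta,
        rss=rss,
        loglik=float(loglik) if np.isfinite(loglik) else np.inf,
        aicc=aicc(loglik, k, n) if np.isfinite(loglik) else -np.inf,
    )
    tiny = 1e-12 * max(1.0, float(y @ y))
    if rss <= tiny:
        return Poly2Fit(fit, float(beta[2]), 0.0, exact=True)
    # orthonormal basis: cov(gamma) = sigma^2 I; quadratic term is gamma[2]
    sigma2 = rss / (n - 3)
    tstat = gamma[2] / np.sqrt(sigma2)
    p = 2.0 * stats.t.sf(abs(tstat), df=n - 3)
    return Poly2Fit(fit, float(beta[2]), float(p), exact=False)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


def pearson(x, y) -> CorrelationResult:
    """Pearson correlation with a two-sided t-test p-value (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    if x.size < 3:
        raise DomainError("correlation test needs at least 3 points")
    if x.std() == 0 or y.std() == 0:
        raise DomainError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), int(x.size))


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    permutations: int
    seed: int | None


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    permutations: int = 999,
    seed: int | None = None,
) -> MantelResult:
    """One-sided (greater) Mantel permutation test.

    The statistic is the Pearson correlation of the lower-triangle entries.
    Rows and columns of the second matrix are permuted jointly;
    p = (1 + #{permuted r >= observed r}) / (permutations + 1).
    """
    if list(d1.ids) != list(d2.ids):
        if set(d1.ids) != set(d2.ids):
            raise ValidationError("distance matrices have different labels")
        d2 = d2.filter(d1.ids)
    A, B = d1.data, d2.data
    n = A.shape[0]
    if n < 3:
        raise DomainError("Mantel test needs at least 3 objects")
    tri = np.tril_indices(n, k=-1)
    a = A[tri]

    def corr(b):
        return np.corrcoef(a, b)[0, 1]

    r_obs = corr(B[tri])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        count += corr(B[np.ix_(perm, perm)][tri]) >= r_obs
    p = (1 + count) / (permutations + 1)
    return MantelResult(float(r_obs), float(p), permutations, seed)
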