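"""Univariate linear mixed-model association scan with kinship.

Model per marker:

    y = W a + x b + u + e,   u ~ MVN(0, lambda * tau^-1 * K),
                             e ~ MVN(0, tau^-1 * I_n)

where y is the quantitative phenotype (habitat altitude, m a.s.l.), W the
covariate matrix (intercept plus principal components), x the marker dosage,
K a genomic relationship matrix and lambda the ratio of the two variance
components.  The variance ratio is estimated once under the null by REML
(spectral decomposition of K, 1-D profile optimisation on log lambda) and
reused for every marker — the EMMAX-style approximation, recorded in the
scan metadata.  Setting ``per_variant_lambda=True`` re-optimises lambda for
each marker instead.

Per-marker effects are generalised least squares in the whitened space
defined by the null fit; significance is a two-sided Wald t-test with
n - c - 1 degrees of freedom, thresholded by Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simulate import GenotypeMatrix

__all__ = [
    "compute_grm",
    "pc_covariates",
    "ld_prune",
    "fit_null",
    "NullFit",
    "association_scan",
    "conditional_scan",
    "bonferroni_threshold",
    "clustered_percentage",
    "VariantCounts",
    "AssociationResult",
]

EIG_CLIP_REL = 1e-8  # eigenvalues below this fraction of the max are clipped to 0


@dataclass(frozen=True)
class VariantCounts:
    """Bookkeeping of the marker panel entering the scan."""

    n_snps: int
    n_indels: int

    @property
    def total(self) -> int:
        return self.n_snps + self.n_indels


@dataclass
class NullFit:
    """REML fit of the covariates-only mixed model."""

    lambda_hat: float
    tau_hat: float
    loglik: float
    boundary: bool  # lambda unidentified / pinned at the search boundary
    eigvals: np.ndarray
    eigvecs: np.ndarray


@dataclass
class AssociationResult:
    """Per-variant scan output plus scan-level metadata."""

    table: pd.DataFrame  # chrom pos ref alt maf beta se p significant testable
    alpha: float
    n_tests: int
    bonferroni_p: float
    lambda_hat: float
    tau_hat: float
    approximation: str  # "null-lambda-reuse" or "per-variant-lambda"


def _impute_dosages(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing (<0 or NaN) entries per variant; return (X, freq)."""
    X = np.asarray(dosages, dtype=float).copy()
    miss = ~np.isfinite(X) | (X < 0)
    X[miss] = np.nan
    col_mean = np.nanmean(np.where(miss, np.nan, X), axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    idx = np.where(miss)
    X[idx] = col_mean[idx[1]]
    return X, col_mean / 2.0


def compute_grm(
    genotypes: GenotypeMatrix | np.ndarray, maf_min: float = 0.0
) -> np.ndarray:
    """Centered, variance-scaled genomic relationship matrix.

    K = Z Z^T / m* with Z_ij = (x_ij - 2 p_j) / sqrt(2 p_j (1 - p_j)) over
    the m* variants passing the MAF filter after mean imputation of missing
    dosages.  Monomorphic variants are excluded.  The result is symmetrised
    and its negative eigenvalues (below EIG_CLIP_REL of the largest) clipped
    so it is positive semidefinite.
    """
    dosages = genotypes.dosages if isinstance(genotypes, GenotypeMatrix) else genotypes
    X, p = _impute_dosages(dosages)
    maf = np.minimum(p, 1 - p)
    keep = (maf >= maf_min) & (maf > 0)
    if not keep.any():
        raise ValueError("no variants pass the MAF filter")
    Xk, pk = X[:, keep], p[keep]
    Z = (Xk - 2 * pk) / np.sqrt(2 * pk * (1 - pk))
    K = Z @ Z.T / Z.shape[1]
    K = (K + K.T) / 2
    w, V = np.linalg.eigh(K)
    tol = EIG_CLIP_REL * max(w.max(), 0.0)
    if w.min() < -tol:
        # genuinely indefinite input would indicate a numerical fault upstream
        raise np.linalg.LinAlgError("relatedness matrix not PSD beyond tolerance")
    w = np.clip(w, 0.0, None)
    return (V * w) @ V.T


def ld_prune(
    dosages: np.ndarray, window: int = 50, step: int = 5, r2_max: float = 0.2
) -> np.ndarray:
    """Greedy pairwise LD pruning (window in variants, sliding by step).

    Within each window, later variants correlated at r^2 > r2_max with a
    retained earlier variant are dropped.  Returns the boolean keep mask.
    """
    X, _ = _impute_dosages(dosages)
    m = X.shape[1]
    keep = np.ones(m, dtype=bool)
    sd = X.std(axis=0)
    keep &= sd > 0
    Xc = X - X.mean(axis=0)
    for start in range(0, m, step):
        idx = [j for j in range(start, min(start + window, m)) if keep[j]]
        for a_i, j in enumerate(idx):
            if not keep[j]:
                continue
            for l in idx[a_i + 1 :]:
                if not keep[l]:
                    continue
                r = (Xc[:, j] @ Xc[:, l]) / (len(Xc) * sd[j] * sd[l])
                if r * r > r2_max:
                    keep[l] = False
    return keep


def pc_covariates(
    genotypes: GenotypeMatrix, k: int = 3, *, prune: bool = True
) -> np.ndarray:
    """Top-k GRM eigenvectors on an LD-pruned panel, as stratification covariates.

    Vectors are unit-norm with sign fixed so the largest-magnitude loading
    is positive.  Returns an n x k array (n x 0 for k = 0).
    """
    n = genotypes.n_samples
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n_samples={n}")
    if k == 0:
        return np.empty((n, 0))
    dosages = genotypes.dosages
    if prune:
        keep = ld_prune(dosages)
        if keep.any():
            dosages = np.asarray(dosages)[:, keep]
    K = compute_grm(dosages)
    w, V = np.linalg.eigh(K)
    order = np.argsort(w)[::-1]
    pcs = V[:, order[:k]]
    for j in range(k):
        i = np.argmax(np.abs(pcs[:, j]))
        if pcs[i, j] < 0:
            pcs[:, j] = -pcs[:, j]
    return pcs


def _reml_criterion(
    log_lambda: float, s: np.ndarray, yr: np.ndarray, Wr: np.ndarray
) -> tuple[float, float]:
    """REML log-likelihood (profiled over alpha and tau) and tau_hat at lambda.

    Operates in the eigenbasis of K: s are eigenvalues, yr/Wr the rotated
    phenotype and covariates.
    """
    lam = np.exp(log_lambda)
    n, c = Wr.shape
    d = lam * s + 1.0
    Wd = Wr / d[:, None]
    WtHiW = Wr.T @ Wd
    WtHiy = Wd.T @ yr
    sign, logdet_WtHiW = np.linalg.slogdet(WtHiW)
    if sign <= 0:
        return -np.inf, np.nan
    alpha = np.linalg.solve(WtHiW, WtHiy)
    resid = yr - Wr @ alpha
    yPy = float(resid @ (resid / d))
    if yPy <= 0:
        return -np.inf, np.nan
    df = n - c
    ll = 0.5 * (
        df * np.log(df / (2 * np.pi))
        - df
        - np.sum(np.log(d))
        - logdet_WtHiW
        - df * np.log(yPy)
    )
    tau_hat = df / yPy
    return ll, tau_hat


def fit_null(
    y: np.ndarray,
    W: np.ndarray,
    kinship: np.ndarray,
    *,
    log_lambda_range: tuple[float, float] = (-10.0, 10.0),
    n_grid: int = 101,
) -> NullFit:
    """REML estimate of the variance ratio lambda under the null model.

    K is eigendecomposed once; the profiled restricted likelihood is
    evaluated on a natural-log grid over ``log_lambda_range`` and refined
    with bounded Brent search around the grid argmax.  tau follows in
    closed form.  If K is (numerically) the identity, lambda is
    unidentified; the fit is returned with ``boundary=True``.
    """
    y = np.asarray(y, dtype=float)
    W = np.atleast_2d(np.asarray(W, dtype=float))
    if W.shape[0] != y.shape[0]:
        raise ValueError("y and W have mismatched sample dimensions")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(W))):
        raise ValueError("y and W must be finite")
    K = np.asarray(kinship, dtype=float)
    K = (K + K.T) / 2
    s, U = np.linalg.eigh(K)
    tol = EIG_CLIP_REL * max(s.max(), 1.0)
    if s.min() < -tol:
        raise np.linalg.LinAlgError("kinship not PSD beyond clipping tolerance")
    s = np.clip(s, 0.0, None)
    yr, Wr = U.T @ y, U.T @ W

    lo, hi = log_lambda_range
    grid = np.linspace(lo, hi, n_grid)
    lls = np.array([_reml_criterion(g, s, yr, Wr)[0] for g in grid])
    i = int(np.argmax(lls))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        lambda g: -_reml_criterion(g, s, yr, Wr)[0],
        bounds=(a, b),
        method="bounded",
        options={"xatol": 1e-8},
    )
    best = res.x if -res.fun >= lls[i] else grid[i]
    ll, tau_hat = _reml_criterion(best, s, yr, Wr)
    flat = np.ptp(lls[np.isfinite(lls)]) < 1e-6
    boundary = bool(i in (0, n_grid - 1) or flat)
    return NullFit(float(np.exp(best)), float(tau_hat), float(ll), boundary, s, U)


def _scan_core(
    X: np.ndarray,
    maf: np.ndarray,
    y: np.ndarray,
    W: np.ndarray,
    null: NullFit,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """GLS beta, SE, Wald p and testability per variant at the null lambda."""
    n, c = W.shape
    d = null.lambda_hat * null.eigvals + 1.0
    sw = 1.0 / np.sqrt(d)
    yd = (null.eigvecs.T @ y) * sw
    Wd = (null.eigvecs.T @ W) * sw[:, None]
    Xd = (null.eigvecs.T @ X) * sw[:, None]

    Q, _ = np.linalg.qr(Wd)
    ry = yd - Q @ (Q.T @ yd)
    rX = Xd - Q @ (Q.T @ Xd)

    xx = np.einsum("ij,ij->j", rX, rX)
    xy = rX.T @ ry
    yy = float(ry @ ry)
    df = n - c - 1
    testable = xx > 1e-10 * n
    beta = np.full(X.shape[1], np.nan)
    se = np.full(X.shape[1], np.nan)
    p = np.full(X.shape[1], np.nan)
    t_ok = testable & (df > 0)
    beta[t_ok] = xy[t_ok] / xx[t_ok]
    rss = np.clip(yy - beta[t_ok] ** 2 * xx[t_ok], 0.0, None)
    sigma2 = rss / df
    se[t_ok] = np.sqrt(sigma2 / xx[t_ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta[t_ok] / se[t_ok]
    p[t_ok] = 2 * stats.t.sf(np.abs(tstat), df)
    p[t_ok] = np.clip(p[t_ok], np.finfo(float).tiny, 1.0)
    return beta, se, p, t_ok


def association_scan(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    covariates: np.ndarray | None,
    kinship: np.ndarray,
    alpha: float = 0.05,
    *,
    maf_min: float = 0.05,
    maf_inclusive: bool = True,
    null: NullFit | None = None,
    per_variant_lambda: bool = False,
) -> AssociationResult:
    """Genome-wide mixed-model scan of dosages against the phenotype.

    Covariates (PCs etc.) are augmented with an intercept column.  Variants
    failing the MAF filter are reported untestable and excluded from the
    Bonferroni denominator, as are post-imputation constant dosages.
    """
    y = np.asarray(phenotype, dtype=float)
    n = genotypes.n_samples
    if y.shape[0] != n:
        raise ValueError("phenotype length does not match genotypes")
    W = np.ones((n, 1))
    if covariates is not None and np.size(covariates):
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            raise ValueError("covariate rows do not match n_samples")
        W = np.hstack([W, C])

    X, p_freq = _impute_dosages(genotypes.dosages)
    maf = np.minimum(p_freq, 1 - p_freq)
    pass_maf = maf >= maf_min if maf_inclusive else maf > maf_min

    if null is None:
        null = fit_null(y, W, kinship)

    if per_variant_lambda:
        beta = np.full(X.shape[1], np.nan)
        se = np.full(X.shape[1], np.nan)
        p = np.full(X.shape[1], np.nan)
        testable = np.zeros(X.shape[1], dtype=bool)
        for j in np.where(pass_maf)[0]:
            nj = fit_null(y, np.hstack([W, X[:, j : j + 1]]), kinship)
            b, s_, pv, ok = _scan_core(X[:, j : j + 1], maf[j : j + 1], y, W, nj)
            beta[j], se[j], p[j], testable[j] = b[0], s_[0], pv[0], ok[0]
        approximation = "per-variant-lambda"
    else:
        beta, se, p, testable = _scan_core(X, maf, y, W, null)
        approximation = "null-lambda-reuse"

    testable = testable & pass_maf
    beta = np.where(testable, beta, np.nan)
    se = np.where(testable, se, np.nan)
    p = np.where(testable, p, np.nan)

    n_tests = int(testable.sum())
    if n_tests == 0:
        raise ValueError("no testable variants after filtering")
    bonf = alpha / n_tests
    table = genotypes.variants.copy()
    table["maf"] = maf
    table["beta"] = beta
    table["se"] = se
    table["p"] = p
    table["testable"] = testable
    table["significant"] = testable & (p < bonf)
    return AssociationResult(
        table, alpha, n_tests, bonf, null.lambda_hat, null.tau_hat, approximation
    )


def conditional_scan(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    covariates: np.ndarray | None,
    condition_dosage: np.ndarray,
    kinship: np.ndarray,
    alpha: float = 0.05,
    **kwargs,
) -> AssociationResult:
    """Association scan conditional on a dosage column (e.g. haplotype A copies).

    The conditioning dosage is appended to the covariate matrix; variants
    collinear with it become untestable and are recorded as such.
    """
    cond = np.asarray(condition_dosage, dtype=float).reshape(-1, 1)
    if cond.shape[0] != genotypes.n_samples:
        raise ValueError("condition dosage length does not match n_samples")
    if covariates is not None and np.size(covariates):
        cov = np.hstack([np.atleast_2d(np.asarray(covariates, dtype=float)), cond])
    else:
        cov = cond
    return association_scan(genotypes, phenotype, cov, kinship, alpha, **kwargs)


def bonferroni_threshold(alpha: float, n_tests: int) -> tuple[float, float]:
    """Genome-wide significance threshold alpha / n_tests and its -log10."""
    if n_tests < 1:
        raise ZeroDivisionError("n_tests must be >= 1")
    p = alpha / n_tests
    return p, -np.log10(p)


def clustered_percentage(region_counts, n_total: int) -> float:
    """Percentage of significant variants falling in the given region clusters."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    clustered = int(np.sum(np.fromiter(region_counts, dtype=int)))
    return 100.0 * clustered / n_total
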