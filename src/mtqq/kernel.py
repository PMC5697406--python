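"""Weighted kernel association test for heteroplasmy load.

The test asks whether the per-individual profile of minor-allele fractions
over the cohort's union of heteroplasmic sites explains a phenotype beyond
the covariates.  With genotype matrix X (n x m), per-site weights w (scaled
pathogenicity scores) and covariates C, the null model is an OLS fit of the
(optionally log-transformed) phenotype on [1, C]; with residuals r the score
statistic is

    Q = r' X W^2 X' r,     W = diag(w).

Under the null, Q is distributed as a weighted sum of independent 1-df
chi-squares whose weights are the eigenvalues of sigma^2 * W X' P0 X W (P0
the projection off the covariate space).  The analytic p-value matches the
first three cumulants of that mixture to a non-central chi-square
(moment-matching); a residual-permutation test serves as the independent
oracle.  Entries of X follow the cohort rule: the minor allele is re-counted
from each sample's quality-filtered bases and the fraction is recorded only
when the minor count strictly exceeds 5, else 0 (binary mode records the
indicator instead).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calling import AlleleCountTable, _major_minor

__all__ = [
    "HetGenotypeMatrix",
    "KernelTestResult",
    "KernelAssociationModel",
    "KernelTestBattery",
    "build_het_matrix",
    "pc_covariates",
    "skat",
    "skat_permutation",
]


@dataclass
class HetGenotypeMatrix:
    """n samples x m union heteroplasmic sites.

    ``values[i, j]`` is the minor-allele fraction of sample i at site j
    (mode 'maf', entries in [0, 0.5]) or the 0/1 occupancy (mode 'binary').
    """

    values: np.ndarray
    samples: list[str]
    sites: list[tuple[int, str]]  # (position, minor allele)
    mode: str = "maf"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.sites)):
            raise ValueError("matrix shape does not match samples x sites")
        if self.mode == "binary":
            if not np.isin(self.values, (0.0, 1.0)).all():
                raise ValueError("binary mode entries must be 0/1")
        elif self.mode == "maf":
            if self.values.min() < 0 or self.values.max() > 0.5:
                raise ValueError("maf mode entries must lie in [0, 0.5]")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{pos}{alt}" for pos, alt in self.sites]
        return pd.DataFrame(self.values, index=self.samples, columns=cols)


def build_het_matrix(
    tables: list[AlleleCountTable],
    union_sites: list[tuple[int, str]],
    mode: str = "maf",
    min_minor_count: int = 5,
    exclude_polymorphic: set[tuple[int, str]] | None = None,
) -> HetGenotypeMatrix:
    """Re-count every sample x site cell from quality-filtered counts.

    ``union_sites`` is the cohort-wide list of (position, minor allele) from
    heteroplasmy calling.  For every sample x site cell the four base totals
    are re-counted and the cell becomes the sample's own minor-allele
    (second-most-frequent base) fraction — or 1 in binary mode — only when
    that minor count strictly exceeds ``min_minor_count``, else 0; this
    applies to samples never called heteroplasmic at the site too.  Sites in
    ``exclude_polymorphic`` (population-level polymorphisms) are dropped.
    """
    from .reference import base_index

    if exclude_polymorphic:
        sites = [s for s in union_sites if s not in exclude_polymorphic]
    else:
        sites = list(union_sites)
    n, m = len(tables), len(sites)
    values = np.zeros((n, m))
    if m == 0:
        return HetGenotypeMatrix(values, [t.sample for t in tables], sites, mode=mode)
    pos_arr = np.array([pos for pos, _ in sites])
    if tables and not ((pos_arr >= 1) & (pos_arr <= tables[0].genome_length)).all():
        warnings.warn("some sites fall outside the count tables; 0 used", stacklevel=2)
    for i, table in enumerate(tables):
        ok = (pos_arr >= 1) & (pos_arr <= table.genome_length)
        sub = table.counts[np.where(ok, pos_arr, 1) - 1]  # (m, 4, 2)
        totals = sub.sum(axis=2)  # (m, 4)
        minor_count = np.partition(totals, 2, axis=1)[:, 2]  # second largest
        depth = totals.sum(axis=1)
        hit = ok & (minor_count > min_minor_count) & (depth > 0)
        if mode == "binary":
            values[i, hit] = 1.0
        else:
            values[i, hit] = np.minimum(
                minor_count[hit] / depth[hit], 0.5
            )
    return HetGenotypeMatrix(
        values, [t.sample for t in tables], sites, mode=mode
    )


def pc_covariates(genotypes: np.ndarray | pd.DataFrame, k: int = 2) -> np.ndarray:
    """Top-k principal coordinates of a (samples x variants) 0/1 matrix.

    Columns are centered; the sign of each component is fixed by making its
    largest-magnitude variant loading positive.  Returns an (n, k') array
    with k' <= k when the matrix has lower rank.
    """
    G = np.asarray(genotypes, dtype=float)
    if G.ndim != 2:
        raise ValueError("genotype matrix must be 2-D")
    n, m = G.shape
    if n < k + 1 or m < k:
        raise ValueError(f"need >= {k + 1} samples and >= {k} variants")
    centered = G - G.mean(axis=0)
    if not centered.any():
        raise ValueError("genotype matrix has zero variance (identical rows)")
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    tol = S.max() * max(n, m) * np.finfo(float).eps
    rank = int((S > tol).sum())
    kk = min(k, rank)
    if kk < k:
        warnings.warn(f"rank {rank} < k={k}: returning {kk} PCs", stacklevel=2)
    pcs = U[:, :kk] * S[:kk]
    for j in range(kk):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            pcs[:, j] = -pcs[:, j]
    return pcs


@dataclass
class KernelTestResult:
    """Outcome of one kernel association test."""

    q: float
    p: float
    method: str  # 'moment-matching' | 'permutation'
    n: int
    m: int
    eigenvalues: np.ndarray = field(default_factory=lambda: np.array([]))
    n_perm: int | None = None
    degenerate: bool = False
    response: str = "y"

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "response": self.response,
                    "Q": self.q,
                    "p": self.p,
                    "method": self.method,
                    "n": self.n,
                    "m": self.m,
                    "n_eigenvalues": len(self.eigenvalues),
                    "degenerate": self.degenerate,
                }
            ]
        )

    def __str__(self) -> str:
        return self.summary().to_string(index=False)


def _liu_pvalue(q: float, lambdas: np.ndarray) -> float:
    """Moment-matching tail probability for Q ~ sum lambda_i chi2_1.

    The first three cumulants (and the kurtosis) of the mixture are matched
    to a scaled non-central chi-square (Liu-Tang-Zhang style matching).
    """
    lambdas = np.asarray(lambdas, dtype=float)
    c1 = lambdas.sum()
    c2 = (lambdas**2).sum()
    c3 = (lambdas**3).sum()
    c4 = (lambdas**4).sum()
    if c2 <= 0:
        return 1.0
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        dof = a**2 - 2 * delta
    else:
        delta = 0.0
        dof = 1.0 / s2
    mu_q, sigma_q = c1, np.sqrt(2 * c2)
    mu_x = dof + delta
    sigma_x = np.sqrt(2 * (dof + 2 * delta))
    t_star = (q - mu_q) / sigma_q * sigma_x + mu_x
    if delta > 0:
        p = stats.ncx2.sf(t_star, dof, delta)
    else:
        p = stats.chi2.sf(t_star, dof)
    return float(min(max(p, 0.0), 1.0))


class KernelAssociationModel:
    """Variance-component score test of a weighted heteroplasmy-load kernel.

    Parameters
    ----------
    y : array-like
        Phenotype values, one per sample.
    X : HetGenotypeMatrix or array
        n x m genotype matrix (minor-allele fractions or 0/1).
    C : array-like or None
        Covariate matrix (n x p), e.g. age, copy number and the top two
        principal components of population structure.
    weights : array-like or None
        Per-site non-negative weights (scaled pathogenicity scores); missing
        (NaN) weights are replaced by the median of the observed ones.
    log_transform : bool
        Log-transform the phenotype before fitting the null model (requires
        strictly positive values).
    """

    def __init__(
        self,
        y,
        X,
        C=None,
        weights=None,
        log_transform: bool = False,
        response: str = "y",
    ) -> None:
        self.X = X.values if isinstance(X, HetGenotypeMatrix) else np.asarray(X, float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        n, m = self.X.shape
        y = np.asarray(y, dtype=float)
        if len(y) != n:
            raise ValueError("y and X have different numbers of samples")
        if log_transform:
            if np.any(y <= 0):
                raise ValueError("log transform requires strictly positive phenotype")
            y = np.log(y)
        self.y = y
        if C is None:
            self.C = np.empty((n, 0))
        else:
            self.C = np.atleast_2d(np.asarray(C, dtype=float))
            if self.C.shape[0] != n:
                self.C = self.C.T
            if self.C.shape[0] != n:
                raise ValueError("C is not aligned with y")
        if weights is None:
            w = np.ones(m)
        else:
            w = np.asarray(weights, dtype=float).copy()
            if len(w) != m:
                raise ValueError("weights are not aligned with the sites")
            if np.isnan(w).any():
                observed = w[~np.isnan(w)]
                if observed.size == 0:
                    raise ValueError("all weights missing")
                fill = float(np.median(observed))
                warnings.warn(
                    f"{int(np.isnan(w).sum())} missing weights set to the "
                    f"median observed weight {fill:.3g}",
                    stacklevel=2,
                )
                w[np.isnan(w)] = fill
            if (w < 0).any():
                raise ValueError("weights must be non-negative")
        self.weights = w
        self.response = response

    # -- null model pieces ------------------------------------------------

    def _null_fit(self):
        n = len(self.y)
        Z = np.column_stack([np.ones(n), self.C])
        beta, *_ = np.linalg.lstsq(Z, self.y, rcond=None)
        resid = self.y - Z @ beta
        dof = n - np.linalg.matrix_rank(Z)
        sigma2 = resid @ resid / dof
        return Z, resid, sigma2

    def _statistic(self, resid: np.ndarray) -> float:
        G = self.X * self.weights  # X W
        s = G.T @ resid
        return float(s @ s)

    def fit(
        self, method: str = "moment", n_perm: int = 1000, seed: int = 0
    ) -> KernelTestResult:
        """Compute Q and its p-value.

        ``method='moment'`` uses the analytic chi-square-mixture
        approximation; ``method='permutation'`` permutes the null-model
        residuals (p = (1 + #{Q* >= Q}) / (1 + n_perm)).
        """
        Z, resid, sigma2 = self._null_fit()
        q = self._statistic(resid)
        n, m = self.X.shape
        G = self.X * self.weights
        if not G.any():
            warnings.warn("genotype matrix is all zero: degenerate test", stacklevel=2)
            return KernelTestResult(
                q=0.0, p=1.0, method="degenerate", n=n, m=m, degenerate=True,
                response=self.response,
            )
        if method == "moment":
            # residualize G off the covariate space: M = P0 G
            coef, *_ = np.linalg.lstsq(Z, G, rcond=None)
            M = G - Z @ coef
            A = (M.T @ M) * sigma2
            lambdas = np.linalg.eigvalsh(A)
            lambdas = lambdas[lambdas > max(lambdas.max(), 0) * 1e-12]
            p = _liu_pvalue(q, lambdas)
            return KernelTestResult(
                q=q, p=p, method="moment-matching", n=n, m=m,
                eigenvalues=lambdas, response=self.response,
            )
        if method == "permutation":
            if n_perm < 100:
                raise ValueError("n_perm must be >= 100")
            rng = np.random.default_rng(seed)
            count = 0
            for _ in range(n_perm):
                q_perm = self._statistic(rng.permutation(resid))
                if q_perm >= q:
                    count += 1
            p = (1 + count) / (1 + n_perm)
            return KernelTestResult(
                q=q, p=p, method="permutation", n=n, m=m, n_perm=n_perm,
                response=self.response,
            )
        raise ValueError(f"unknown method {method!r}")


class KernelTestBattery:
    """Analytic kernel tests for many phenotypes sharing one (X, C, w).

    The chi-square-mixture eigenvalues come from the residualized weighted
    genotype matrix, which does not depend on the phenotype; they are
    computed once and rescaled by each null model's residual variance.
    Results are identical to running :func:`skat` per trait.
    """

    def __init__(self, X, C=None, weights=None) -> None:
        n = (X.n if isinstance(X, HetGenotypeMatrix) else np.asarray(X).shape[0])
        probe = KernelAssociationModel(np.zeros(n), X, C, weights)
        self._model = probe
        self.Z = np.column_stack([np.ones(n), probe.C])
        self.G = probe.X * probe.weights
        coef, *_ = np.linalg.lstsq(self.Z, self.G, rcond=None)
        M = self.G - self.Z @ coef
        base = np.linalg.eigvalsh(M.T @ M)
        self.base_eigenvalues = base[base > max(base.max(), 0) * 1e-12] if base.size else base
        self._dof = n - np.linalg.matrix_rank(self.Z)

    def test(
        self, y, log_transform: bool = False, response: str = "y"
    ) -> KernelTestResult:
        y = np.asarray(y, dtype=float)
        if log_transform:
            if np.any(y <= 0):
                raise ValueError("log transform requires strictly positive phenotype")
            y = np.log(y)
        beta, *_ = np.linalg.lstsq(self.Z, y, rcond=None)
        resid = y - self.Z @ beta
        sigma2 = resid @ resid / self._dof
        s = self.G.T @ resid
        q = float(s @ s)
        n, m = self.G.shape
        if not self.G.any():
            return KernelTestResult(
                q=0.0, p=1.0, method="degenerate", n=n, m=m,
                degenerate=True, response=response,
            )
        lambdas = self.base_eigenvalues * sigma2
        return KernelTestResult(
            q=q, p=_liu_pvalue(q, lambdas), method="moment-matching",
            n=n, m=m, eigenvalues=lambdas, response=response,
        )


def skat(
    y, C, X, w=None, log_transform: bool = False, response: str = "y"
) -> KernelTestResult:
    """Analytic (moment-matching) kernel association test."""
    return KernelAssociationModel(
        y, X, C, w, log_transform=log_transform, response=response
    ).fit(method="moment")


def skat_permutation(
    y, C, X, w=None, n_perm: int = 1000, seed: int = 0,
    log_transform: bool = False, response: str = "y"
) -> KernelTestResult:
    """Permutation oracle for the analytic p-value."""
    return KernelAssociationModel(
        y, X, C, w, log_transform=log_transform, response=response
    ).fit(method="permutation", n_perm=n_perm, seed=seed)
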