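"""Lagged VAR design construction and ordinary least squares.

Every Granger-causality flavour in this package shares the same stacked
regression  Y = X B + E,  where for n genes observed at T time points and
model order p:

* ``Y`` (m x n, m = T - p) holds the responses at times p+1 .. T;
* ``X`` (m x n*p) holds the lagged predictors, ordered lag 1 first: row t of
  X is [y'_{p+t-1}, y'_{p+t-2}, ..., y'_t] (most recent lag first), and
  within each lag block genes appear in ``gene_ids`` order;
* ``B`` (n*p x n) stacks the transposed lag coefficient matrices
  [A_1'; A_2'; ...; A_p'], so B[(l-1)*n + g, h] is the effect of gene g at
  lag l on gene h.

Models are intercept-free; expression data are z-scored upstream (see
:func:`standardize`).  Rank deficiency is an error here — the condition for
OLS is m >= n*p, i.e. T >= (n+1)p — and the regularized module handles the
n >> T regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import InvalidOrderError, ParameterError, SingularDesignError
from .io_formats import ExpressionMatrix

__all__ = [
    "VarDesign",
    "CoefficientMatrix",
    "RegressionResult",
    "standardize",
    "build_design",
    "ols_estimate",
    "rss_for_subset",
]


@dataclass
class VarDesign:
    """Stacked response and lagged predictor matrices for one dataset."""

    Y: np.ndarray  # (m, n)
    X: np.ndarray  # (m, n*p), lag blocks ordered lag 1, 2, ..., p
    p: int
    m: int
    gene_ids: list[str]

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if self.m != self.Y.shape[0] or self.m < 1:
            raise ParameterError("inconsistent design: m != rows of Y or m < 1")
        if self.Y.shape[1] != n or self.X.shape != (self.m, n * self.p):
            raise ParameterError("inconsistent design matrix shapes")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class CoefficientMatrix:
    """VAR coefficients in lag-block layout: B is (n*p) x n.

    ``B[(lag-1)*n + g, h]`` is the effect of gene g at that lag on gene h.
    """

    B: np.ndarray
    p: int
    gene_ids: list[str]

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if self.B.shape != (n * self.p, n):
            raise ParameterError(
                f"coefficient matrix shape {self.B.shape} does not match "
                f"n={n}, p={self.p}"
            )
        if not np.all(np.isfinite(self.B)):
            raise ParameterError("non-finite coefficient")

    def lag_view(self) -> np.ndarray:
        """B reshaped to (p, n_source, n_target)."""
        n = len(self.gene_ids)
        return self.B.reshape(self.p, n, n)

    def aggregate_scores(self, aggregation: str = "max") -> np.ndarray:
        """Collapse |B| over lags into an (n_source, n_target) score matrix."""
        A = np.abs(self.lag_view())
        if aggregation == "max":
            return A.max(axis=0)
        if aggregation == "sum":
            return A.sum(axis=0)
        if aggregation == "l2":
            return np.sqrt((A**2).sum(axis=0))
        raise ParameterError(f"unknown aggregation {aggregation!r}")

    def pair_entries(self, source_idx: int, target_idx: int) -> np.ndarray:
        """The p lag coefficients for one directed pair."""
        n = len(self.gene_ids)
        rows = source_idx + n * np.arange(self.p)
        return self.B[rows, target_idx]


@dataclass
class RegressionResult:
    coefficients: CoefficientMatrix
    residuals: np.ndarray  # (m, n)
    rss: np.ndarray  # (n,) per-target residual square sum

    @classmethod
    def from_B(cls, design: VarDesign, B: np.ndarray) -> "RegressionResult":
        resid = design.Y - design.X @ B
        rss = np.einsum("ij,ij->j", resid, resid)
        coef = CoefficientMatrix(B=B, p=design.p, gene_ids=list(design.gene_ids))
        return cls(coefficients=coef, residuals=resid, rss=rss)


def standardize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score each gene across time (population 1/T variance).

    Idempotent; constant genes are centred and left at zero variance rather
    than divided by zero.
    """
    v = expr.values
    mu = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, keepdims=True)
    sd = np.where(sd < 1e-15, 1.0, sd)
    return ExpressionMatrix(list(expr.gene_ids), (v - mu) / sd,
                            list(expr.time_labels) if expr.time_labels else None)


def build_design(expr: ExpressionMatrix, p: int) -> VarDesign:
    """Build the stacked VAR(p) design from an expression matrix."""
    n, T = expr.values.shape
    if not 1 <= p <= T - 1:
        raise InvalidOrderError(f"model order p={p} needs 1 <= p <= T-1={T - 1}")
    m = T - p
    V = expr.values
    Y = np.ascontiguousarray(V[:, p:].T)
    X = np.empty((m, n * p))
    for lag in range(1, p + 1):
        X[:, (lag - 1) * n : lag * n] = V[:, p - lag : T - lag].T
    return VarDesign(Y=Y, X=X, p=p, m=m, gene_ids=list(expr.gene_ids))


def _solve_normal_equations(G: np.ndarray, C: np.ndarray) -> np.ndarray:
    try:
        cho = scipy.linalg.cho_factor(G, lower=True, check_finite=False)
    except scipy.linalg.LinAlgError as exc:
        raise SingularDesignError(
            "X'X is singular; the OLS condition T >= (n+1)p is violated — "
            "use a regularized estimator (ridge/lasso) instead"
        ) from exc
    # Cholesky pivots fall like sqrt(eigenvalues); ratio 1e-7 ~ cond 1e14
    d = np.diag(cho[0])
    if d.min() <= 0 or d.min() / d.max() < 1e-7:
        raise SingularDesignError(
            "X'X is numerically rank deficient; use a regularized estimator"
        )
    return scipy.linalg.cho_solve(cho, C, check_finite=False)


def ols_estimate(design: VarDesign) -> RegressionResult:
    """Ordinary least squares B = (X'X)^{-1} X'Y with per-target RSS."""
    X, Y = design.X, design.Y
    k = X.shape[1]
    if design.m < k:
        raise SingularDesignError(
            f"under-determined design (m={design.m} rows < {k} predictors); "
            "the OLS condition T >= (n+1)p is violated — use ridge/lasso"
        )
    B = _solve_normal_equations(X.T @ X, X.T @ Y)
    return RegressionResult.from_B(design, B)


def rss_for_subset(
    expr: ExpressionMatrix, p: int, excluded_gene: str
) -> tuple[np.ndarray, list[str]]:
    """Per-target RSS of the OLS fit on all genes except ``excluded_gene``.

    This is the reduced model of the conditional Granger test: comparing the
    full-model RSS of a target with its RSS after dropping one candidate
    source measures that source's unique predictive contribution.  Returns
    the RSS vector and the gene order it refers to.
    """
    if excluded_gene not in expr.gene_ids:
        raise ParameterError(f"gene {excluded_gene!r} not in expression matrix")
    keep = [i for i, g in enumerate(expr.gene_ids) if g != excluded_gene]
    sub = ExpressionMatrix(
        [expr.gene_ids[i] for i in keep],
        expr.values[keep],
        list(expr.time_labels) if expr.time_labels else None,
    )
    result = ols_estimate(build_design(sub, p))
    return result.rss, list(sub.gene_ids)
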