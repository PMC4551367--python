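"""Mutual-information network baselines: ARACNE, MRNET and TD variants.

These are the information-theoretic comparison methods.  A pairwise MI
matrix is estimated either by equal-frequency binning with ceil(sqrt(T))
bins and the Miller-Madow bias correction (default — robust for the very
short series this package targets) or by the Gaussian closed form
-0.5*ln(1 - rho^2) (exact for jointly Gaussian data, handy for tests).

ARACNE prunes the weakest edge of every triangle by the data-processing
inequality; MRNET scores predictors per target by greedy
max-relevance-min-redundancy forward selection.  Both yield undirected
networks, reported as both directed orientations of each surviving pair.

The time-delayed (TD) variants first take, for every ordered pair, the
maximum MI over source lags 1..max_lag, recording the best lag; the usual
algorithm then runs on the lag-maximized matrix, and each surviving edge is
oriented toward the direction (and lag) that achieved the maximum.  This
is the simplified TD-ARACNE (built like TD-MRNET), not the original
dynamic-programming TD-ARACNE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, ParameterError
from .evaluation import EdgeRanking
from .io_formats import ExpressionMatrix

__all__ = [
    "MiMatrix",
    "mi_matrix",
    "time_delayed_mi_matrix",
    "aracne",
    "mrnet",
]


@dataclass
class MiMatrix:
    """Pairwise MI estimates; ``best_lag`` present only for TD variants."""

    values: np.ndarray  # (n, n); symmetric for zero-lag, directed for TD
    gene_ids: list[str]
    estimator: str
    best_lag: np.ndarray | None = None

    @property
    def is_time_delayed(self) -> bool:
        return self.best_lag is not None

    def symmetrized(self) -> np.ndarray:
        return np.maximum(self.values, self.values.T)


def _equal_frequency_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Rank-based discretization; ties broken by original order."""
    order = np.argsort(values, axis=1, kind="stable")
    ranks = np.empty_like(order)
    T = values.shape[1]
    np.put_along_axis(ranks, order, np.arange(T)[None, :], axis=1)
    return (ranks * n_bins) // T


def _binned_mi_from_onehot(Zi: np.ndarray, Zj: np.ndarray,
                           miller_madow: bool = True) -> np.ndarray:
    """MI between every row-pair of two one-hot tensors (ni,T,B) x (nj,T,B)."""
    T = Zi.shape[1]
    # joint counts per pair via one chunked einsum
    C = np.einsum("itb,jtc->ijbc", Zi, Zj)
    P = C / T
    Pi = P.sum(axis=3, keepdims=True)
    Pj = P.sum(axis=2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(P > 0, P / (Pi * Pj), 1.0)
        mi = np.where(P > 0, P * np.log(ratio), 0.0).sum(axis=(2, 3))
    if miller_madow:
        k_joint = (C > 0).sum(axis=(2, 3))
        k_i = (C.sum(axis=3) > 0).sum(axis=2)
        k_j = (C.sum(axis=2) > 0).sum(axis=2)
        mi = mi + (k_joint - k_i - k_j + 1) / (2.0 * T)
    return np.maximum(mi, 0.0)


def _pairwise_binned_mi(A: np.ndarray, Bm: np.ndarray | None = None,
                        chunk: int = 64) -> np.ndarray:
    """MI matrix between rows of A and rows of B (default A) by binning."""
    T = A.shape[1]
    n_bins = int(np.ceil(np.sqrt(T)))
    if Bm is None:
        Bm = A
    da = _equal_frequency_bins(A, n_bins)
    db = da if Bm is A else _equal_frequency_bins(Bm, n_bins)
    eye = np.eye(n_bins)
    Za = eye[da]  # (n, T, B) one-hot
    Zb = Za if Bm is A else eye[db]
    n_a = Za.shape[0]
    out = np.empty((n_a, Zb.shape[0]))
    for lo in range(0, n_a, chunk):
        hi = min(lo + chunk, n_a)
        out[lo:hi] = _binned_mi_from_onehot(Za[lo:hi], Zb)
    return out


def _pairwise_gaussian_mi(A: np.ndarray, Bm: np.ndarray | None = None
                          ) -> np.ndarray:
    if Bm is None:
        Bm = A
    Az = A - A.mean(axis=1, keepdims=True)
    Bz = Bm - Bm.mean(axis=1, keepdims=True)
    sa = np.sqrt((Az**2).sum(axis=1))
    sb = np.sqrt((Bz**2).sum(axis=1))
    sa = np.where(sa < 1e-15, np.inf, sa)  # constant genes -> rho 0
    sb = np.where(sb < 1e-15, np.inf, sb)
    rho = (Az @ Bz.T) / np.outer(sa, sb)
    rho = np.clip(rho, -0.999999999, 0.999999999)
    return -0.5 * np.log1p(-(rho**2))


def mi_matrix(expr: ExpressionMatrix, estimator: str = "binned") -> MiMatrix:
    """Zero-lag pairwise MI for all gene pairs (diagonal included but
    ignored by downstream algorithms)."""
    if expr.n_times < 4:
        raise InsufficientDataError("MI estimation needs T >= 4")
    if estimator not in ("binned", "gaussian"):
        raise ParameterError(f"unknown MI estimator {estimator!r}")
    V = expr.values
    const = V.std(axis=1) < 1e-15
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant gene(s); their MI rows are zero"
        )
    if estimator == "binned":
        M = _pairwise_binned_mi(V)
        if const.any():
            M[const, :] = 0.0
            M[:, const] = 0.0
    else:
        M = _pairwise_gaussian_mi(V)
    return MiMatrix(values=M, gene_ids=list(expr.gene_ids), estimator=estimator)


def time_delayed_mi_matrix(
    expr: ExpressionMatrix, max_lag: int, estimator: str = "binned"
) -> MiMatrix:
    """Lag-maximized MI: values[i, j] = max over lag 1..max_lag of
    MI(x_i delayed by lag, x_j), with the argmax lag recorded (ties take
    the smallest lag)."""
    if max_lag < 1:
        raise ParameterError("max_lag must be >= 1")
    if expr.n_times <= max_lag + 3:
        raise InsufficientDataError("TD MI needs T > max_lag + 3")
    if estimator not in ("binned", "gaussian"):
        raise ParameterError(f"unknown MI estimator {estimator!r}")
    V = expr.values
    n, T = V.shape
    best = np.full((n, n), -np.inf)
    best_lag = np.ones((n, n), dtype=int)
    for lag in range(1, max_lag + 1):
        A = V[:, : T - lag]  # source, shifted back
        Bm = V[:, lag:]  # target, present
        M = (_pairwise_binned_mi(A, Bm) if estimator == "binned"
             else _pairwise_gaussian_mi(A, Bm))
        better = M > best  # strict: ties keep the smaller lag
        best_lag[better] = lag
        np.maximum(best, M, out=best)
    return MiMatrix(values=best, gene_ids=list(expr.gene_ids),
                    estimator=estimator, best_lag=best_lag)


def _orient(mi: MiMatrix, i: int, j: int) -> tuple[int, int]:
    """Direction of an undirected pair in TD mode: the orientation whose
    lag-maximized MI is larger; exact ties go to the lexicographic pair."""
    vij, vji = mi.values[i, j], mi.values[j, i]
    if vij > vji:
        return i, j
    if vji > vij:
        return j, i
    return (i, j) if mi.gene_ids[i] <= mi.gene_ids[j] else (j, i)


def _pairs_to_ranking(mi: MiMatrix, keep: np.ndarray, scores: np.ndarray,
                      label: str) -> EdgeRanking:
    ids = np.asarray(mi.gene_ids, dtype=object)
    srcs, tgts, vals = [], [], []
    iu, ju = np.where(np.triu(keep, k=1))
    for i, j in zip(iu, ju):
        if mi.is_time_delayed:
            a, b = _orient(mi, int(i), int(j))
            srcs.append(ids[a])
            tgts.append(ids[b])
            vals.append(scores[i, j])
        else:
            srcs.extend((ids[i], ids[j]))
            tgts.extend((ids[j], ids[i]))
            vals.extend((scores[i, j], scores[i, j]))
    return EdgeRanking.from_arrays(
        np.asarray(srcs, dtype=object), np.asarray(tgts, dtype=object),
        np.asarray(vals, dtype=float), method_label=label,
    )


def aracne(mi: MiMatrix, dpi_epsilon: float = 0.0) -> EdgeRanking:
    """ARACNE: prune each triangle's weakest edge by the data-processing
    inequality, then rank survivors by MI.

    Edge (i, j) is removed when some third gene k satisfies
    MI(i,j) < min(MI(i,k), MI(j,k)) - dpi_epsilon.  In TD mode the matrix
    is symmetrized by the max over orientations for pruning, and each
    surviving edge is oriented by its recorded best lag.
    """
    if dpi_epsilon < 0:
        raise ParameterError("dpi_epsilon must be >= 0")
    M = mi.symmetrized().copy()
    n = M.shape[0]
    np.fill_diagonal(M, -np.inf)
    keep = np.ones((n, n), dtype=bool)
    for i in range(n):
        W = np.minimum(M[i][None, :], M)  # (j, k): min of the two other legs
        W[:, i] = -np.inf
        np.fill_diagonal(W, -np.inf)
        thresh = W.max(axis=1)
        keep[i] = ~(M[i] < thresh - dpi_epsilon)
    keep &= keep.T
    np.fill_diagonal(keep, False)
    return _pairs_to_ranking(mi, keep, mi.symmetrized(),
                             "td-aracne" if mi.is_time_delayed else "aracne")


def mrnet(mi: MiMatrix) -> EdgeRanking:
    """MRNET: greedy max-relevance-min-redundancy per target.

    For each target, predictors are selected one at a time by the MRMR
    score  MI(candidate, target) - mean MI(candidate, already-selected);
    selection stops when the best score is non-positive.  An undirected
    pair's score is the larger of its two directional scores; TD mode
    orients by the recorded best lag instead.
    """
    S = mi.symmetrized()
    n = S.shape[0]
    score = np.full((n, n), -np.inf)  # score[p, t]: p selected for target t
    for t in range(n):
        rel = S[:, t].copy()
        rel[t] = -np.inf
        avail = np.ones(n, dtype=bool)
        avail[t] = False
        red_sum = np.zeros(n)
        n_sel = 0
        while avail.any():
            cand = np.where(avail, rel - (red_sum / n_sel if n_sel else 0.0),
                            -np.inf)
            b = int(np.argmax(cand))
            if cand[b] <= 0:
                break
            score[b, t] = cand[b]
            avail[b] = False
            red_sum += S[:, b]
            n_sel += 1
    pair_score = np.maximum(score, score.T)
    keep = np.isfinite(pair_score)
    np.fill_diagonal(keep, False)
    return _pairs_to_ranking(mi, keep, pair_score,
                             "td-mrnet" if mi.is_time_delayed else "mrnet")
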