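"""Edge rankings and their evaluation against a golden standard.

Every inference method in this package reduces to a ranked list of directed
candidate edges.  Evaluation follows the usual network-inference protocol:
precision-recall curves over ranking prefixes, and precision/recall/F1 at a
fixed cutoff k.  At k equal to the golden-standard size precision equals
recall equals F1, which is the single-number summary used throughout the
benchmark.

The evaluation universe is the set of all ordered non-self gene pairs;
methods that return sparse lists (e.g. ARACNE after pruning) are padded with
zero-score edges in deterministic lexicographic order so every prefix is
well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ParameterError

if TYPE_CHECKING:  # pragma: no cover
    from .var_core import CoefficientMatrix

__all__ = [
    "EdgeRanking",
    "PrcCurve",
    "rank_from_coefficients",
    "prc",
    "f1_at_k",
    "topk_overlap",
    "pad_ranking",
    "edge_set_accuracy",
    "pvalue_distribution_report",
]


class EdgeRanking:
    """An ordered list of scored directed edges.

    Entries are sorted by score descending; ties are broken by an optional
    secondary key (e.g. the F statistic) and then lexicographically by
    (source, target) so rankings are bit-stable across runs.  Self-edges and
    duplicate ordered pairs are disallowed.
    """

    def __init__(self, frame: pd.DataFrame, method_label: str = ""):
        self._df = frame.reset_index(drop=True)
        self.method_label = method_label

    @classmethod
    def from_arrays(
        cls,
        sources,
        targets,
        scores,
        p_values=None,
        secondary=None,
        method_label: str = "",
        presorted: bool = False,
    ) -> "EdgeRanking":
        sources = np.asarray(sources, dtype=object)
        targets = np.asarray(targets, dtype=object)
        scores = np.asarray(scores, dtype=float)
        if not (len(sources) == len(targets) == len(scores)):
            raise ParameterError("ranking arrays must have equal length")
        if np.any(sources == targets):
            raise ParameterError("self-edges are not allowed in a ranking")
        if not presorted:
            # integer codes make the lexicographic tie-break cheap at 1e6 rows
            src_codes = pd.Index(np.unique(sources)).get_indexer(sources)
            tgt_codes = pd.Index(np.unique(targets)).get_indexer(targets)
            keys = [tgt_codes, src_codes]
            if secondary is not None:
                keys.append(-np.asarray(secondary, dtype=float))
            keys.append(-scores)
            order = np.lexsort(keys)
            sources, targets, scores = sources[order], targets[order], scores[order]
            if p_values is not None:
                p_values = np.asarray(p_values, dtype=float)[order]
        data = {"source": sources, "target": targets, "score": scores}
        if p_values is not None:
            data["p_value"] = np.asarray(p_values, dtype=float)
        df = pd.DataFrame(data)
        if df.duplicated(["source", "target"]).any():
            raise ParameterError("duplicate ordered pair in ranking")
        return cls(df, method_label=method_label)

    def __len__(self) -> int:
        return len(self._df)

    @property
    def sources(self) -> np.ndarray:
        return self._df["source"].to_numpy()

    @property
    def targets(self) -> np.ndarray:
        return self._df["target"].to_numpy()

    @property
    def scores(self) -> np.ndarray:
        return self._df["score"].to_numpy()

    @property
    def p_values(self) -> np.ndarray | None:
        if "p_value" in self._df.columns:
            return self._df["p_value"].to_numpy()
        return None

    def entries(self) -> list[tuple]:
        return list(self._df.itertuples(index=False, name=None))

    def to_frame(self) -> pd.DataFrame:
        return self._df.copy()

    def head(self, k: int) -> pd.DataFrame:
        return self._df.head(k)


@dataclass
class PrcCurve:
    """Precision-recall points swept over every ranking prefix."""

    recall: np.ndarray
    precision: np.ndarray
    auprc: float

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.recall.tolist(), self.precision.tolist()))


def rank_from_coefficients(
    B: "CoefficientMatrix",
    gene_ids: Iterable[str] | None = None,
    aggregation: str = "max",
    method_label: str = "",
) -> EdgeRanking:
    """Rank directed edges by the magnitude of their VAR coefficients.

    score(i -> j) aggregates |B| over the p lag entries of the pair; the
    autoregressive diagonal is excluded.  ``aggregation`` is one of ``max``
    (default), ``sum`` or ``l2``.
    """
    gene_ids = list(gene_ids) if gene_ids is not None else list(B.gene_ids)
    S = B.aggregate_scores(aggregation)  # (n, n): source rows, target cols
    n = len(gene_ids)
    if S.shape != (n, n):
        raise ParameterError("gene_ids length does not match coefficient matrix")
    src, tgt = np.where(~np.eye(n, dtype=bool))
    ids = np.asarray(gene_ids, dtype=object)
    return EdgeRanking.from_arrays(
        ids[src], ids[tgt], S[src, tgt], method_label=method_label
    )


def _gold_pairs(gold) -> set[tuple[str, str]]:
    """Accept a GoldStandard, an EdgeList, or a bare collection of pairs."""
    if hasattr(gold, "edge_pairs"):
        return set(gold.edge_pairs())
    if hasattr(gold, "pairs"):
        return set(gold.pairs())
    return {(str(a), str(b)) for a, b, *_ in gold}


def _hit_mask(ranking: EdgeRanking, gold_pairs: set[tuple[str, str]]) -> np.ndarray:
    idx = pd.MultiIndex.from_arrays([ranking.sources, ranking.targets])
    gold_idx = pd.MultiIndex.from_tuples(sorted(gold_pairs)) if gold_pairs else \
        pd.MultiIndex.from_arrays([[], []])
    return idx.isin(gold_idx)


def prc(ranking: EdgeRanking, gold) -> PrcCurve:
    """Precision-recall at every prefix of the ranking.

    AUPRC uses step interpolation: the area is the sum of precision at each
    recall increment, with no linear interpolation between PR points.
    """
    pairs = _gold_pairs(gold)
    if not pairs:
        raise ParameterError("golden standard is empty")
    hits = _hit_mask(ranking, pairs)
    if not hits.any():
        warnings.warn("ranking shares no edges with the golden standard")
    G = len(pairs)
    cum = np.cumsum(hits)
    ranks = np.arange(1, len(hits) + 1)
    precision = cum / ranks
    recall = cum / G
    auprc = float(precision[hits].sum() / G) if hits.any() else 0.0
    return PrcCurve(recall=recall, precision=precision, auprc=auprc)


def f1_at_k(ranking: EdgeRanking, gold, k: int) -> tuple[float, float, float]:
    """Precision, recall and F1 on the top-k prefix.

    When k equals the golden-standard size, precision = recall = F1.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    pairs = _gold_pairs(gold)
    if not pairs:
        raise ParameterError("golden standard is empty")
    if k > len(ranking):
        warnings.warn(
            f"k={k} exceeds ranking length {len(ranking)}; evaluating full list"
        )
        k = len(ranking)
    hits = int(_hit_mask(ranking, pairs)[:k].sum())
    precision = hits / k
    recall = hits / len(pairs)
    f1 = 0.0 if hits == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def topk_overlap(ranking: EdgeRanking, gold, k: int) -> int:
    """Number of golden-standard edges among the top k ranked edges."""
    if k < 1:
        raise ParameterError("k must be >= 1")
    pairs = _gold_pairs(gold)
    if not pairs:
        return 0
    if k > len(ranking):
        warnings.warn(
            f"k={k} exceeds ranking length {len(ranking)}; evaluating full list"
        )
        k = len(ranking)
    return int(_hit_mask(ranking, pairs)[:k].sum())


def pad_ranking(ranking: EdgeRanking, gene_ids: Iterable[str]) -> EdgeRanking:
    """Extend a sparse ranking to the full ordered-pair universe.

    Missing pairs get score 0 and are appended in lexicographic order, so
    prefixes of any depth are defined for every method.
    """
    ids_sorted = sorted(str(g) for g in gene_ids)
    n = len(ids_sorted)
    pos = {g: i for i, g in enumerate(ids_sorted)}
    try:
        src_i = [pos[s] for s in ranking.sources]
        tgt_i = [pos[t] for t in ranking.targets]
    except KeyError as exc:
        raise ParameterError(
            f"ranking contains gene {exc.args[0]!r} outside the universe"
        ) from None
    have = np.zeros((n, n), dtype=bool)
    have[src_i, tgt_i] = True
    np.fill_diagonal(have, True)
    miss_s, miss_t = np.where(~have)
    if len(miss_s) == 0:
        return ranking
    arr = np.asarray(ids_sorted, dtype=object)
    df = ranking.to_frame()
    pad = pd.DataFrame(
        {
            "source": arr[miss_s],
            "target": arr[miss_t],
            "score": np.zeros(len(miss_s)),
        }
    )
    if "p_value" in df.columns:
        pad["p_value"] = np.nan
    out = pd.concat([df, pad], ignore_index=True)
    return EdgeRanking(out, method_label=ranking.method_label)


def edge_set_accuracy(edges, gold) -> float:
    """Fraction of candidate directed edges present in the golden standard."""
    cand = _gold_pairs(edges)
    if not cand:
        raise ParameterError("candidate edge set is empty")
    pairs = _gold_pairs(gold)
    return len(cand & pairs) / len(cand)


def pvalue_distribution_report(
    rankings_by_scenario: Mapping[str, EdgeRanking | np.ndarray],
) -> pd.DataFrame:
    """Summaries of log10 p per scenario (one row per scenario label).

    Accepts EdgeRankings carrying p-values or bare p-value arrays, and
    reports count, quartiles, median and mean of log10 p, enabling the
    classic three-scenario comparison (random pairs vs within-set pairs vs
    golden-standard pairs).
    """
    rows = []
    for label, obj in rankings_by_scenario.items():
        p = obj.p_values if isinstance(obj, EdgeRanking) else np.asarray(obj, float)
        if p is None:
            raise ParameterError(f"scenario {label!r} carries no p-values")
        p = np.asarray(p, dtype=float)
        p = p[np.isfinite(p)]
        if p.size == 0:
            raise ParameterError(f"scenario {label!r} has no finite p-values")
        logp = np.log10(np.maximum(p, 1e-300))
        rows.append(
            {
                "scenario": label,
                "n": int(p.size),
                "q25_log10_p": float(np.quantile(logp, 0.25)),
                "median_log10_p": float(np.median(logp)),
                "q75_log10_p": float(np.quantile(logp, 0.75)),
                "mean_log10_p": float(np.mean(logp)),
            }
        )
    return pd.DataFrame(rows).set_index("scenario")
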