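"""Readers and writers for all on-disk artifacts.

Everything is plain tab-separated text:

* expression matrices — header row of time labels, first column ``gene_id``,
  genes in rows, time points in columns (the usual GEO series-matrix
  orientation; internal math transposes at a single documented boundary);
* edge lists — ``source<TAB>target[<TAB>weight]``, used for prior-knowledge
  graphs and golden standards; undirected files are symmetrized on read;
* edge rankings — ``rank source target score p_value`` with a header line,
  plus an optional SIF dialect for network viewers;
* configs — YAML (or JSON, which YAML subsumes).

Loaders validate strictly: duplicate gene identifiers, non-numeric cells,
missing values and malformed lines are rejected with the offending location
rather than silently dropped.  Gene identifiers are opaque strings and are
matched by exact equality everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError
from .evaluation import EdgeRanking

__all__ = [
    "ExpressionMatrix",
    "EdgeList",
    "read_expression",
    "write_expression",
    "read_edge_list",
    "write_edge_list",
    "read_ranking",
    "write_ranking",
    "read_config",
    "write_config",
]


@dataclass
class ExpressionMatrix:
    """A gene x time expression matrix.

    ``values`` has one row per gene (order matching ``gene_ids``) and one
    column per time point.  No missing values are allowed: the loader rejects
    NaN, and imputation is deliberately out of scope.
    """

    gene_ids: list[str]
    values: np.ndarray
    time_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise FormatError("expression values must be a 2-D matrix")
        n, T = self.values.shape
        if len(self.gene_ids) != n:
            raise FormatError(
                f"{len(self.gene_ids)} gene ids for {n} expression rows"
            )
        if T < 2:
            raise FormatError(f"need at least 2 time points, got {T}")
        seen: set[str] = set()
        for g in self.gene_ids:
            if g in seen:
                raise FormatError(f"duplicate gene id {g!r}")
            seen.add(g)
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite expression value for gene "
                f"{self.gene_ids[bad[0]]!r} at time column {bad[1]}"
            )
        if self.time_labels is not None:
            self.time_labels = [str(t) for t in self.time_labels]
            if len(self.time_labels) != T:
                raise FormatError(
                    f"{len(self.time_labels)} time labels for {T} columns"
                )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    def index_of(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in expression matrix") from None


@dataclass
class EdgeList:
    """A weighted directed edge list ``(source, target, weight)``.

    When loaded from an undirected file every stored pair also carries its
    reverse with equal weight, so downstream code only ever deals with the
    directed case.
    """

    edges: list[tuple[str, str, float]] = field(default_factory=list)
    directed: bool = True

    def __post_init__(self) -> None:
        self.edges = [(str(s), str(t), float(w)) for s, t, w in self.edges]
        for s, t, w in self.edges:
            if not math.isfinite(w):
                raise FormatError(f"non-finite weight on edge {s!r}->{t!r}")

    def __len__(self) -> int:
        return len(self.edges)

    def pairs(self) -> set[tuple[str, str]]:
        return {(s, t) for s, t, _ in self.edges}

    def nodes(self) -> set[str]:
        out: set[str] = set()
        for s, t, _ in self.edges:
            out.add(s)
            out.add(t)
        return out


def read_expression(path) -> ExpressionMatrix:
    """Load a tab-separated expression matrix (genes x time)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse expression file {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise FormatError(
            f"{path}: need at least 2 time columns, found {df.shape[1]}"
        )
    ids = [str(g) for g in df.index]
    dupes = df.index[df.index.duplicated()].unique()
    if len(dupes):
        raise FormatError(f"{path}: duplicate gene id {str(dupes[0])!r}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric expression cell ({exc})") from exc
    if np.isnan(values).any():
        g, t = np.argwhere(np.isnan(values))[0]
        raise FormatError(
            f"{path}: missing/NaN value for gene {ids[g]!r} "
            f"in column {df.columns[t]!r}"
        )
    return ExpressionMatrix(ids, values, [str(c) for c in df.columns])


def write_expression(expr: ExpressionMatrix, path) -> None:
    labels = expr.time_labels or [f"t{i + 1}" for i in range(expr.n_times)]
    df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=labels)
    df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def read_edge_list(
    path,
    directed: bool = True,
    default_weight: float = 1.0,
    allow_self_loops: bool = False,
) -> EdgeList:
    """Load a ``source target [weight]`` TSV.

    With ``directed=False`` each input pair is materialized in both
    directions with equal weight (E_ij = E_ji).  A header line starting with
    ``source`` is tolerated and skipped.
    """
    edges: list[tuple[str, str, float]] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].strip().lower() == "source":
                continue
            if len(parts) not in (2, 3):
                raise FormatError(
                    f"{path}: line {lineno}: expected 2 or 3 tab-separated "
                    f"fields, found {len(parts)}"
                )
            s, t = parts[0].strip(), parts[1].strip()
            if not s or not t:
                raise FormatError(f"{path}: line {lineno}: empty node id")
            if s == t and not allow_self_loops:
                raise FormatError(f"{path}: line {lineno}: self-loop on {s!r}")
            if len(parts) == 3:
                try:
                    w = float(parts[2])
                except ValueError:
                    raise FormatError(
                        f"{path}: line {lineno}: bad weight {parts[2]!r}"
                    ) from None
                if not math.isfinite(w):
                    raise FormatError(
                        f"{path}: line {lineno}: non-finite weight"
                    )
            else:
                w = default_weight
            for a, b in ((s, t),) if directed else ((s, t), (t, s)):
                if (a, b) not in seen:
                    seen.add((a, b))
                    edges.append((a, b, w))
    return EdgeList(edges, directed=directed)


def write_edge_list(edge_list: EdgeList, path) -> None:
    with open(path, "w") as fh:
        for s, t, w in edge_list.edges:
            fh.write(f"{s}\t{t}\t{w:.17g}\n")


def write_ranking(ranking: EdgeRanking, path, dialect: str = "tsv") -> None:
    """Write an edge ranking as TSV (default) or SIF.

    The TSV dialect has columns ``rank source target score p_value`` (the
    p-value field is left empty when the method carries none).  The SIF
    dialect writes ``source gc target`` for network viewers.
    """
    df = ranking.to_frame()
    if dialect == "sif":
        with open(path, "w") as fh:
            for s, t in zip(df["source"], df["target"]):
                fh.write(f"{s}\tgc\t{t}\n")
        return
    if dialect != "tsv":
        raise FormatError(f"unknown ranking dialect {dialect!r}")
    with open(path, "w") as fh:
        fh.write("rank\tsource\ttarget\tscore\tp_value\n")
        has_p = "p_value" in df.columns and df["p_value"].notna().any()
        for rank, row in enumerate(df.itertuples(index=False), start=1):
            p = f"{row.p_value:.12g}" if has_p and not math.isnan(row.p_value) else ""
            fh.write(f"{rank}\t{row.source}\t{row.target}\t{row.score:.12g}\t{p}\n")


def read_ranking(path, method_label: str = "") -> EdgeRanking:
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    for col in ("source", "target", "score"):
        if col not in df.columns:
            raise FormatError(f"{path}: ranking file lacks column {col!r}")
    p = df["p_value"].to_numpy(dtype=float) if "p_value" in df.columns else None
    if p is not None and np.isnan(p).all():
        p = None
    return EdgeRanking.from_arrays(
        df["source"].to_numpy(),
        df["target"].to_numpy(),
        df["score"].to_numpy(dtype=float),
        p_values=p,
        method_label=method_label,
        presorted=True,
    )


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
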