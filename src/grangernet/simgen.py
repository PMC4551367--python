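"""Modularized hierarchical simulation benchmark.

Real regulatory networks are hierarchical: a handful of master regulators
sit above layers of effectors.  The generator mimics this with a three-layer
1 -> 3 -> 9 module (13 genes, 12 edges) repeated ``module_repeats`` times,
plus random cross-module "perturbation" edges.  Master regulators are
activated at random; a module's genes survive the activation filter iff its
master is active, mirroring the real-data step where only differentially
expressed genes enter the analysis.  Surviving genes are padded with
isolated periodic background genes up to ``total_nodes``, and every retained
edge receives a lag drawn from 1..max_lag and a coefficient from
U(coeff_range).  The retained network is the golden standard.

Expression dynamics (per time point, after max_lag random N(0,1) starts):

* masters and isolated genes follow a periodic AR(2),
      x_t = sqrt(3) * d * x_{t-1} - d^2 * x_{t-2} + e_t,
  whose characteristic roots d * exp(+-i*pi/6) give a period of 12 time
  points and slow decay d ~ U(decay_range).  (The textbook complex-
  conjugate construction a = 2 cos(pi/6) = sqrt(3), b = -|root|^2 = -d^2;
  the sign-flipped variant with +d^2, which is explosive, is available
  behind ``ar2_positive_sign`` for comparison.)
* effectors are linear in their parents' past:
      x_t(k) = sum_parents r(j=>k) * x(j, t - lag(j=>k)) + e_t(k).

Noise e is N(0, noise_sigma^2) everywhere.  Each gene is finally z-scored
across time.  All randomness flows from ``seed`` through three independent
substreams (network / expression / prior), so one config is bit-reproducible
end to end.

The prior-knowledge graph is the bidirectional clique over each module's
surviving members — deliberately coarse group information: of the 13*12=156
ordered pairs in a full module only the 12 true edges are real, a prior
accuracy of ~7.7 %.  Cross-module perturbation edges are never in the prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateSimulationError, ParameterError
from .io_formats import EdgeList, ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "GoldStandard",
    "GoldEdge",
    "generate_network",
    "generate_expression",
    "generate_prior_clique",
]

MODULE_SIZE = 13  # 1 master -> 3 mid -> 9 leaves
MODULE_EDGES = 12


@dataclass
class SimulationConfig:
    """Study conditions for the simulation benchmark.

    Defaults are the benchmark's reference conditions: 60 modules (780 base
    genes), ~5/6 of masters active so ~650 genes survive filtering, padding
    to 1000 total, 20 time points, lags up to 3, unit-variance noise.
    """

    module_repeats: int = 60
    perturbation_edges: int = 700
    activation_rate: float = 5.0 / 6.0  # P(master regulator is active)
    total_nodes: int = 1000
    T: int = 20
    max_lag: int = 3
    noise_sigma: float = 1.0
    decay_range: tuple[float, float] = (0.95, 1.0)
    coeff_range: tuple[float, float] = (-1.0, 1.0)
    seed: int = 0
    ar2_positive_sign: bool = False  # explosive +d^2 AR(2) variant

    def __post_init__(self) -> None:
        if self.module_repeats < 1:
            raise ParameterError("module_repeats must be >= 1")
        if not 0.0 < self.activation_rate <= 1.0:
            raise ParameterError("activation_rate must lie in (0, 1]")
        if self.T <= self.max_lag:
            raise ParameterError("need T > max_lag")
        if self.max_lag < 1:
            raise ParameterError("max_lag must be >= 1")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        if self.perturbation_edges < 0:
            raise ParameterError("perturbation_edges must be >= 0")


@dataclass(frozen=True)
class GoldEdge:
    source: str
    target: str
    lag: int
    coefficient: float


@dataclass
class GoldStandard:
    """Ground-truth network: retained directed edges plus gene roles."""

    edges: list[GoldEdge]
    nodes: list[str]  # deterministic order: module genes, then isolated
    roles: dict[str, str]  # gene -> master | effector | isolated
    modules: list[list[str]] = field(default_factory=list)  # surviving members

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for e in self.edges:
            if e.source == e.target:
                raise ParameterError(f"self-loop on {e.source!r}")
            if e.source not in node_set or e.target not in node_set:
                raise ParameterError(f"edge endpoint outside node set: {e}")
            if e.lag < 1:
                raise ParameterError("edge lag must be >= 1")

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(e.source, e.target) for e in self.edges}

    def to_edge_list(self) -> EdgeList:
        return EdgeList(
            [(e.source, e.target, e.coefficient) for e in self.edges],
            directed=True,
        )


def _module_gene(module: int, position: int) -> str:
    """Stable gene names: position 0 = master, 1-3 = mid, 4-12 = leaf."""
    if position == 0:
        return f"M{module:03d}.master"
    if position <= 3:
        return f"M{module:03d}.mid{position}"
    return f"M{module:03d}.leaf{position - 3}"


def _module_structure(module: int) -> list[tuple[str, str]]:
    edges = []
    master = _module_gene(module, 0)
    for mid in range(1, 4):
        edges.append((master, _module_gene(module, mid)))
        for k in range(3):
            leaf = 4 + (mid - 1) * 3 + k
            edges.append((_module_gene(module, mid), _module_gene(module, leaf)))
    return edges


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def generate_network(cfg: SimulationConfig) -> GoldStandard:
    """Build the golden-standard network under activation filtering."""
    rng = _rng(cfg.seed, 0)
    R = cfg.module_repeats
    members = [[_module_gene(k, pos) for pos in range(MODULE_SIZE)]
               for k in range(R)]
    module_of = {g: k for k, mem in enumerate(members) for g in mem}
    structure: list[tuple[str, str]] = []
    for k in range(R):
        structure.extend(_module_structure(k))

    # cross-module perturbation edges; never into a master (masters stay
    # purely AR(2)-driven so the gold standard matches the dynamics)
    all_genes = [g for mem in members for g in mem]
    non_master = [g for g in all_genes if not g.endswith("master")]
    existing = set(structure)
    perturb: list[tuple[str, str]] = []
    guard = 0
    while len(perturb) < cfg.perturbation_edges:
        guard += 1
        if guard > 100 * max(cfg.perturbation_edges, 1):
            raise DegenerateSimulationError(
                "cannot place the requested number of perturbation edges"
            )
        s = all_genes[rng.integers(len(all_genes))]
        t = non_master[rng.integers(len(non_master))]
        if module_of[s] == module_of[t] or (s, t) in existing:
            continue
        existing.add((s, t))
        perturb.append((s, t))

    active_modules = rng.random(R) < cfg.activation_rate
    surviving = {g for k in range(R) if active_modules[k] for g in members[k]}
    if not surviving:
        raise DegenerateSimulationError(
            "activation filtering left zero genes; raise activation_rate"
        )
    retained = [e for e in structure if module_of[e[0]] == module_of[e[1]]
                and e[0] in surviving]
    retained += [(s, t) for s, t in perturb
                 if s in surviving and t in surviving]

    lags = rng.integers(1, cfg.max_lag + 1, size=len(retained))
    coeffs = rng.uniform(*cfg.coeff_range, size=len(retained))
    edges = [GoldEdge(s, t, int(l), float(c))
             for (s, t), l, c in zip(retained, lags, coeffs)]

    n_iso = cfg.total_nodes - len(surviving)
    if n_iso < 0:
        raise ParameterError(
            f"total_nodes={cfg.total_nodes} below the {len(surviving)} "
            "surviving module genes"
        )
    isolated = [f"ISO{i:04d}" for i in range(n_iso)]
    nodes = [g for mem in members for g in mem if g in surviving] + isolated

    has_parent = {e.target for e in edges}
    roles = {}
    for g in nodes:
        if g in has_parent:
            roles[g] = "effector"
        elif g.startswith("ISO"):
            roles[g] = "isolated"
        else:
            roles[g] = "master"
    surviving_members = [[g for g in mem if g in surviving] for mem in members]
    return GoldStandard(
        edges=edges,
        nodes=nodes,
        roles=roles,
        modules=[mem for mem in surviving_members if mem],
    )


def generate_expression(gold: GoldStandard, cfg: SimulationConfig) -> ExpressionMatrix:
    """Simulate the time series implied by a golden standard."""
    rng = _rng(cfg.seed, 1)
    nodes = gold.nodes
    n, T, L = len(nodes), cfg.T, cfg.max_lag
    idx = {g: i for i, g in enumerate(nodes)}

    ar2_mask = np.array([gold.roles[g] != "effector" for g in nodes])
    decay = rng.uniform(*cfg.decay_range, size=n)
    a = np.sqrt(3.0) * decay
    b = (decay**2) if cfg.ar2_positive_sign else -(decay**2)

    e_src = np.array([idx[e.source] for e in gold.edges], dtype=int)
    e_tgt = np.array([idx[e.target] for e in gold.edges], dtype=int)
    e_lag = np.array([e.lag for e in gold.edges], dtype=int)
    e_cof = np.array([e.coefficient for e in gold.edges])

    x = np.empty((n, T))
    x[:, :L] = rng.standard_normal((n, L))
    for t in range(L, T):
        noise = cfg.noise_sigma * rng.standard_normal(n)
        vals = np.zeros(n)
        vals[ar2_mask] = (a * x[:, t - 1] + b * x[:, t - 2])[ar2_mask]
        if len(e_src):
            np.add.at(vals, e_tgt, e_cof * x[e_src, t - e_lag])
        x[:, t] = vals + noise

    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd = np.where(sd < 1e-15, 1.0, sd)
    x = (x - mu) / sd
    return ExpressionMatrix(list(nodes), x, [f"t{i + 1}" for i in range(T)])


def generate_prior_clique(gold: GoldStandard, cfg: SimulationConfig) -> EdgeList:
    """Bidirectional clique prior over each module's surviving members.

    Weight 1 on every ordered within-module pair; cross-module perturbation
    edges are never included, so the prior carries group information only.
    """
    edges: list[tuple[str, str, float]] = []
    for mem in gold.modules:
        for s in mem:
            for t in mem:
                if s != t:
                    edges.append((s, t, 1.0))
    return EdgeList(edges, directed=True)
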