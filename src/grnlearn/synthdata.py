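"""Synthetic gold-standard GRN topologies and linear-Gaussian expression data.

The generator emulates the statistical structure of the DREAM5 in silico
benchmark: a directed regulatory network whose edges all originate at
TF-encoding genes, skewed TF out-degrees (a minority of TFs are hubs),
linear-Gaussian dependence of targets on their regulators, disconnected
decoy genes, and a large-p-small-n sample size.  It does not attempt the
kinetic (ODE/stochastic) simulation of the original benchmark: each gene is
drawn from a structural equation model in topological order.

Defaults mirror the DREAM5 in silico conditions: 178 TFs + 1370 targets
(1548 connected genes), 4012 directed edges, 17 decoy TFs and 78 decoy
targets, n = 805 samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .containers import ExpressionMatrix, GoldStandard
from .gbn import DAGStructure, GBNModel

__all__ = ["GeneratorConfig", "generate_topology", "sample_expression", "standardize"]

logger = logging.getLogger(__name__)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic benchmark generator."""

    n_tfs: int = 178
    n_targets: int = 1370
    n_edges: int = 4012
    hub_exponent: float = 1.0
    coef_low: float = 0.3
    coef_high: float = 1.0
    noise_sd: float = 1.0
    n_decoy_tfs: int = 17
    n_decoy_targets: int = 78
    n_samples: int = 805
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_tfs,
            self.n_targets,
            self.n_edges,
            self.n_decoy_tfs,
            self.n_decoy_targets,
            self.n_samples,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.coef_low > self.coef_high or self.coef_low < 0:
            raise ValueError("need 0 <= coef_low <= coef_high")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.hub_exponent <= 0:
            raise ValueError("hub_exponent must be > 0")
        if self.n_edges > 0 and self.n_tfs == 0:
            raise ValueError("cannot place edges without TFs")
        if self.n_edges > self.n_tfs * (self.n_tfs + self.n_targets - 1):
            raise ValueError("n_edges exceeds the number of possible TF-sourced pairs")


def _gene_names(config: GeneratorConfig) -> tuple[list[str], list[str], list[str]]:
    tfs = [f"tf{i + 1}" for i in range(config.n_tfs)]
    targets = [f"g{i + 1}" for i in range(config.n_targets)]
    decoys = [f"decoytf{i + 1}" for i in range(config.n_decoy_tfs)] + [
        f"decoyg{i + 1}" for i in range(config.n_decoy_targets)
    ]
    return tfs, targets, decoys


def generate_topology(config: GeneratorConfig) -> GoldStandard:
    """Draw a directed TF-sourced network with skewed TF out-degrees.

    TF i (rank i) gets out-degree weight proportional to rank^(-hub_exponent),
    so low-rank TFs act as hubs.  TF->TF edges only run from lower to higher
    rank, which keeps the graph acyclic and makes linear-Gaussian sampling
    well defined.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    tfs, targets, decoys = _gene_names(config)
    # capacity per TF under the rank rule: higher-rank TFs + all targets
    capacity = [
        (config.n_tfs - rank - 1) + config.n_targets for rank in range(config.n_tfs)
    ]
    if config.n_edges > sum(capacity):
        raise ValueError(
            f"n_edges={config.n_edges} infeasible under the TF-rank rule "
            f"(capacity {sum(capacity)})"
        )
    weights = np.array(
        [(rank + 1.0) ** (-config.hub_exponent) for rank in range(config.n_tfs)]
    )
    edges: set[tuple[str, str]] = set()
    used = np.zeros(config.n_tfs, dtype=int)
    alive = np.array(capacity) > 0
    while len(edges) < config.n_edges:
        w = np.where(alive, weights, 0.0)
        src = int(rng.choice(config.n_tfs, p=w / w.sum()))
        allowed = [tfs[r] for r in range(src + 1, config.n_tfs)] + targets
        allowed = [t for t in allowed if (tfs[src], t) not in edges]
        tgt = allowed[int(rng.integers(len(allowed)))]
        edges.add((tfs[src], tgt))
        used[src] += 1
        if used[src] >= capacity[src]:
            alive[src] = False
    gene_ids = tfs + targets + decoys
    tf_ids = set(tfs) | {d for d in decoys if d.startswith("decoytf")}
    gold = GoldStandard(tf_ids=tf_ids, edges=edges, gene_ids=gene_ids)
    logger.info(
        "generated topology: %d genes, %d TFs, %d edges",
        len(gene_ids),
        len(tf_ids),
        len(edges),
    )
    return gold


def sample_expression(
    gold: GoldStandard, config: GeneratorConfig
) -> tuple[ExpressionMatrix, GBNModel]:
    """Sample expression from a linear-Gaussian structural equation model.

    Each gene is the linear-Gaussian child of its regulators, drawn in
    topological order; regression coefficients are Rademacher-sign times
    Uniform[coef_low, coef_high]; every residual (and every root or decoy
    gene) has standard deviation ``noise_sd``.  Returns the raw samples
    together with the true generating :class:`GBNModel` so downstream
    estimates can be checked against the truth.  Deterministic given
    ``config.seed`` (one generator stream: topology coefficients first, then
    noise).
    """
    rng = np.random.default_rng((config.seed, 1))
    nodes = list(gold.gene_ids)
    structure = DAGStructure.from_edges(nodes, gold.edges)
    order = _topological_order(structure)
    beta: dict[str, dict[str, float]] = {}
    for node in nodes:
        parents = sorted(structure.parent_sets[node])
        signs = rng.choice([-1.0, 1.0], size=len(parents))
        mags = rng.uniform(config.coef_low, config.coef_high, size=len(parents))
        beta[node] = dict(zip(parents, map(float, signs * mags)))
    nu = {node: config.noise_sd**2 for node in nodes}
    mu = {node: 0.0 for node in nodes}
    model = GBNModel(structure=structure, beta=beta, nu=nu, mu=mu)

    idx = {g: i for i, g in enumerate(nodes)}
    values = np.zeros((config.n_samples, len(nodes)))
    noise = rng.normal(0.0, config.noise_sd, size=values.shape)
    for node in order:
        i = idx[node]
        col = noise[:, i].copy()
        for parent, coef in beta[node].items():
            col += coef * values[:, idx[parent]]
        values[:, i] = col
    X = ExpressionMatrix(values=values, gene_ids=nodes, standardized=False)
    return X, model


def _topological_order(structure: DAGStructure) -> list[str]:
    remaining = {n: set(p) for n, p in structure.parent_sets.items()}
    children: dict[str, set[str]] = {n: set() for n in structure.nodes}
    for child, parents in remaining.items():
        for p in parents:
            children[p].add(child)
    ready = sorted(n for n, p in remaining.items() if not p)
    order: list[str] = []
    while ready:
        node = ready.pop()
        order.append(node)
        for ch in children[node]:
            remaining[ch].discard(node)
            if not remaining[ch]:
                ready.append(ch)
    if len(order) != len(structure.nodes):
        raise ValueError("regulatory graph contains a directed cycle")
    return order


def standardize(X: ExpressionMatrix) -> ExpressionMatrix:
    """Scale every gene column to sample mean 0 and sd 1 (n-1 denominator)."""
    sd = X.values.std(axis=0, ddof=1)
    bad = [g for g, s in zip(X.gene_ids, sd) if s == 0 or not np.isfinite(s)]
    if bad:
        raise ValueError(f"constant expression columns cannot be standardized: {bad}")
    values = (X.values - X.values.mean(axis=0)) / sd
    return replace(X, values=values, standardized=True)
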