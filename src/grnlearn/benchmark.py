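"""Matched-size comparison of hill climbing and glasso on synthetic benchmarks.

Reproduces, at desk scale, the study design used to compare the learners:
generate a TF-sourced gold standard and linear-Gaussian expression data,
learn one network with glasso at a fixed penalty and one greedy hill-climbing
path, take the hill-climbing snapshot whose moralized (undirected) edge count
is closest to the glasso network size, and compare true positives and
precision-network log-likelihood at that matched size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .bn2pn import bn_to_precision, moralize
from .evaluation import true_positive_count
from .gbn import fit_local_params, hill_climb, sample_covariance
from .gbn import _moral_edge_count  # shared moral-count helper
from .precision import glasso, pn_loglik
from .synthdata import GeneratorConfig, generate_topology, sample_expression, standardize

__all__ = ["MatchedComparison", "compare_hc_glasso", "default_benchmark_config"]

logger = logging.getLogger(__name__)


def default_benchmark_config(seed: int) -> GeneratorConfig:
    """Scaled-down benchmark conditions: 200 genes (20 TFs), 400 gold edges,
    n = 800 samples."""
    return GeneratorConfig(
        n_tfs=20,
        n_targets=180,
        n_edges=400,
        n_decoy_tfs=0,
        n_decoy_targets=0,
        n_samples=800,
        seed=seed,
    )


@dataclass
class MatchedComparison:
    seed: int
    glasso_n_edges: int
    hc_n_edges: int
    glasso_tp: int
    hc_tp: int
    glasso_loglik: float
    hc_loglik: float


def compare_hc_glasso(
    seed: int,
    config: GeneratorConfig | None = None,
    lam: float = 0.6,
) -> MatchedComparison:
    """One seeded benchmark run comparing the two learners at matched size."""
    config = config or default_benchmark_config(seed)
    gold = generate_topology(config)
    X, _truth = sample_expression(gold, config)
    Xs = standardize(X)
    S = sample_covariance(Xs)
    gmodel = glasso(S, lam, gene_ids=list(Xs.gene_ids))
    g_edges = gmodel.edges()
    target_size = len(g_edges)

    _final, trace = hill_climb(Xs, max_iter=target_size + 100)
    # walk the greedy path and find the snapshot with the closest moral size
    parent_sets: dict[str, set[str]] = {n: set() for n in trace.nodes}
    best_iter, best_count, best_gap = 0, 0, abs(target_size)
    for row in trace.rows:
        parent, child = row.edge
        if row.move == "add":
            parent_sets[child].add(parent)
        elif row.move == "delete":
            parent_sets[child].discard(parent)
        else:
            parent_sets[child].discard(parent)
            parent_sets[parent].add(child)
        count = _moral_edge_count(parent_sets)
        gap = abs(count - target_size)
        if gap < best_gap:
            best_iter, best_count, best_gap = row.iteration, count, gap
    bn = fit_local_params(trace.structure_at(best_iter), Xs)
    moral_edges = moralize(bn.structure)
    pn = bn_to_precision(bn)
    result = MatchedComparison(
        seed=seed,
        glasso_n_edges=target_size,
        hc_n_edges=best_count,
        glasso_tp=true_positive_count(g_edges, gold),
        hc_tp=true_positive_count(moral_edges, gold),
        glasso_loglik=pn_loglik(gmodel, Xs),
        hc_loglik=pn_loglik(pn, Xs),
    )
    logger.info(
        "seed %d: |E| %d vs %d, TP %d vs %d, loglik %.1f vs %.1f (hc vs glasso)",
        seed,
        result.hc_n_edges,
        result.glasso_n_edges,
        result.hc_tp,
        result.glasso_tp,
        result.hc_loglik,
        result.glasso_loglik,
    )
    return result
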