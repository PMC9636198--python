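"""Scoring learned undirected networks against a directed gold standard.

An undirected edge {a, b} is a true positive (TP) when the gold standard
contains a->b or b->a.  Precision = TP / |E| and recall = TP / P with
P the number of gold edges; in ``tf_only`` mode every learned edge between
two non-TF genes is removed before either measure is computed, mirroring the
DREAM5 convention of scoring only TF-target predictions.  FP/TN-derived
quantities should be interpreted with caution on real data: curated gold
standards are incomplete, so an unmatched edge is not necessarily wrong.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bn2pn import bn_to_precision
from .containers import ExpressionMatrix, GoldStandard
from .precision import GlassoConfig, PrecisionModel, glasso, hglasso, pn_loglik, sfglasso

__all__ = [
    "true_positive_count",
    "connected_tf_count",
    "precision_recall",
    "run_sweep",
    "SWEEP_COLUMNS",
]

logger = logging.getLogger(__name__)

SWEEP_COLUMNS = [
    "method",
    "setting",
    "n_edges",
    "tp",
    "connected_tfs",
    "loglik",
    "precision",
    "recall",
    "mode",
]


def _canon(edge) -> tuple[str, str]:
    a, b = edge
    return (a, b) if a <= b else (b, a)


def _clean_edges(edges) -> set[tuple[str, str]]:
    out = set()
    dropped = 0
    for e in edges:
        a, b = e
        if a == b:
            dropped += 1
            continue
        out.add(_canon((a, b)))
    if dropped:
        logger.info("stripped %d self-loop(s) from learned edge set", dropped)
    return out


def true_positive_count(edges, gold: GoldStandard) -> int:
    """Undirected edges {a, b} with a->b or b->a in the gold standard."""
    undirected = _clean_edges(edges)
    gold_undirected = {_canon(e) for e in gold.edges}
    return len(undirected & gold_undirected)


def connected_tf_count(edges, tf_ids) -> int:
    """TF-encoding genes with degree >= 1 in the undirected edge set."""
    tf_ids = set(tf_ids)
    connected = set()
    for a, b in _clean_edges(edges):
        if a in tf_ids:
            connected.add(a)
        if b in tf_ids:
            connected.add(b)
    return len(connected)


def precision_recall(
    edges, gold: GoldStandard, mode: str = "all", restrict_to=None
) -> tuple[float, float]:
    """(precision, recall) of an undirected edge set against the gold standard.

    ``mode='tf_only'`` drops learned edges with no TF endpoint before both
    measures.  ``restrict_to`` optionally names the genes actually observed;
    gold edges outside it are dropped from P with a logged count.
    """
    if mode not in ("all", "tf_only"):
        raise ValueError(f"unknown mode {mode!r}")
    undirected = _clean_edges(edges)
    if mode == "tf_only":
        undirected = {
            e for e in undirected if e[0] in gold.tf_ids or e[1] in gold.tf_ids
        }
    gold_edges = set(gold.edges)
    if restrict_to is not None:
        observed = set(restrict_to)
        dropped = {e for e in gold_edges if e[0] not in observed or e[1] not in observed}
        if dropped:
            logger.info("dropped %d gold edge(s) outside the observed genes", len(dropped))
        gold_edges -= dropped
    if not undirected:
        raise ValueError("precision is undefined for an empty edge list")
    if not gold_edges:
        raise ValueError("recall is undefined for an empty gold standard")
    gold_undirected = {_canon(e) for e in gold_edges}
    tp = len(undirected & gold_undirected)
    return tp / len(undirected), tp / len(gold_edges)


@dataclass
class _Setting:
    label: str
    edges: set[tuple[str, str]]
    model: PrecisionModel | None


def _hc_settings(spec: dict, X: ExpressionMatrix) -> list[_Setting]:
    from .gbn import hill_climb

    checkpoints = spec.get("checkpoints", [])
    max_iter = spec.get("max_iter", max(checkpoints, default=100) * 2 + 50)
    _model, trace = hill_climb(
        X,
        max_iter=max_iter,
        checkpoints=checkpoints,
        reversals=spec.get("reversals", True),
        max_parents=spec.get("max_parents"),
    )
    out = []
    for count in sorted(trace.checkpoints):
        bn = trace.checkpoints[count]
        pn = bn_to_precision(bn)
        if spec.get("edge_source", "moral") == "moral":
            from .bn2pn import moralize

            edges = moralize(bn.structure)
        else:
            edges = pn.edges()
        out.append(_Setting(label=f"checkpoint={count}", edges=set(edges), model=pn))
    return out


def _glasso_family_settings(spec: dict, S, gene_ids) -> list[_Setting]:
    method = spec["method"]
    config = spec.get("config") or GlassoConfig()
    out = []
    if method == "glasso":
        for lam in spec["lambdas"]:
            model = glasso(S, lam, config=config, gene_ids=gene_ids)
            out.append(_Setting(label=f"lambda={lam:g}", edges=model.edges(), model=model))
    elif method == "hglasso":
        for l1, l2, l3 in spec["grid"]:
            model, _dec = hglasso(S, l1, l2, l3, gene_ids=gene_ids)
            out.append(
                _Setting(
                    label=f"l1={l1:g},l2={l2:g},l3={l3:g}", edges=model.edges(), model=model
                )
            )
    elif method == "sfglasso":
        for alpha in spec["alphas"]:
            model, _rec = sfglasso(
                S, alpha, n_reweights=spec.get("n_reweights", 2), config=config, gene_ids=gene_ids
            )
            out.append(_Setting(label=f"alpha={alpha:g}", edges=model.edges(), model=model))
    else:
        raise ValueError(f"unknown method {method!r}")
    return out


def run_sweep(spec: dict, X: ExpressionMatrix, gold: GoldStandard) -> pd.DataFrame:
    """Learn networks over a tuning grid and score each against the gold
    standard; two rows (modes ``all`` and ``tf_only``) per setting.

    ``spec`` examples::

        {"method": "hc", "checkpoints": [100, 250, 500]}
        {"method": "glasso", "lambdas": [1.0, 0.8, 0.6]}
        {"method": "hglasso", "grid": [(0.6, 0.95, 7.0)]}
        {"method": "sfglasso", "alphas": [0.43, 0.3]}
    """
    from .gbn import sample_covariance

    method = spec["method"]
    rows = []
    if method == "hc":
        settings = _hc_settings(spec, X)
    else:
        S = sample_covariance(X)
        settings = _glasso_family_settings(spec, S, list(X.gene_ids))
    for setting in settings:
        try:
            loglik = pn_loglik(setting.model, X) if setting.model is not None else np.nan
            for mode in ("all", "tf_only"):
                edges = setting.edges
                if mode == "tf_only":
                    edges = {
                        e for e in edges if e[0] in gold.tf_ids or e[1] in gold.tf_ids
                    }
                n_edges = len(edges)
                tp = true_positive_count(edges, gold)
                rows.append(
                    {
                        "method": method,
                        "setting": setting.label,
                        "n_edges": n_edges,
                        "tp": tp,
                        "connected_tfs": connected_tf_count(edges, gold.tf_ids),
                        "loglik": loglik,
                        "precision": tp / n_edges if n_edges else np.nan,
                        "recall": tp / len(gold.edges) if gold.edges else np.nan,
                        "mode": mode,
                    }
                )
        except Exception:  # per-setting failures are logged, not fatal
            logger.exception("sweep setting %s failed", setting.label)
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)
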