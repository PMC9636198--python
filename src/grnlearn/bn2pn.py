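"""Exact conversion of a Gaussian Bayesian network to a precision network.

Writing the linear-Gaussian model as x = mu + B (x - mu) + e with
B[child, parent] = beta_{child,parent} and Cov(e) = diag(nu), the implied
covariance is Sigma = (I - B)^{-1} diag(nu) (I - B)^{-T} and the precision
matrix is its exact inverse

    Theta = (I - B)^T diag(nu)^{-1} (I - B).

The orientation of B is pinned down by the verifiable contract
Theta x Sigma = I.  The support of Theta is contained in the moral graph of
the DAG (skeleton plus marriages between co-parents); an entry inside the
moral support can still cancel to zero, which is logged when detected.
"""

from __future__ import annotations

import logging

import numpy as np

from .gbn import DAGStructure, GBNModel
from .precision import EDGE_TOLERANCE, PrecisionModel

__all__ = ["moralize", "bn_to_precision", "implied_covariance"]

logger = logging.getLogger(__name__)


def moralize(structure: DAGStructure) -> set[tuple[str, str]]:
    """Undirected moral graph: skeleton edges plus an edge between every pair
    of co-parents of a common child; endpoints lexicographically ordered."""
    edges: set[tuple[str, str]] = set()
    for child, parents in structure.parent_sets.items():
        plist = sorted(parents)
        for p in plist:
            edges.add(tuple(sorted((p, child))))
        for i in range(len(plist)):
            for j in range(i + 1, len(plist)):
                edges.add((plist[i], plist[j]))
    return edges


def _coefficient_matrix(model: GBNModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    nodes = model.structure.nodes
    idx = {g: i for i, g in enumerate(nodes)}
    p = len(nodes)
    B = np.zeros((p, p))
    for child, coeffs in model.beta.items():
        for parent, value in coeffs.items():
            B[idx[child], idx[parent]] = value
    nu = np.array([model.nu[n] for n in nodes])
    mu = np.array([model.mu[n] for n in nodes])
    return B, nu, mu


def bn_to_precision(model: GBNModel) -> PrecisionModel:
    """Theta = (I - B)^T diag(nu)^{-1} (I - B); exact inverse of the model's
    implied covariance."""
    B, nu, mu = _coefficient_matrix(model)
    if np.any(nu <= 0):
        raise ValueError("conditional variances must be positive")
    M = np.eye(len(nu)) - B
    theta = M.T @ (M / nu[:, None])
    theta = (theta + theta.T) / 2.0
    moral = moralize(model.structure)
    adj = np.abs(theta) > EDGE_TOLERANCE
    np.fill_diagonal(adj, False)
    nodes = model.structure.nodes
    support = {
        tuple(sorted((nodes[i], nodes[j])))
        for i, j in zip(*np.nonzero(np.triu(adj, 1)))
    }
    cancelled = moral - support
    if cancelled:
        logger.info(
            "%d moral edge(s) cancelled to numerically zero precision entries: %s",
            len(cancelled),
            sorted(cancelled)[:10],
        )
    extra = support - moral
    if extra:  # contract violation; should be impossible
        raise AssertionError(f"precision support outside the moral graph: {sorted(extra)}")
    return PrecisionModel(theta=theta, gene_ids=list(nodes), mu=mu)


def implied_covariance(model: GBNModel) -> np.ndarray:
    """Exact covariance Sigma = (I - B)^{-1} diag(nu) (I - B)^{-T} of the
    linear-Gaussian model."""
    B, nu, _mu = _coefficient_matrix(model)
    M = np.eye(len(nu)) - B
    K = np.linalg.solve(M, np.diag(nu))  # M^{-1} diag(nu)
    sigma = np.linalg.solve(M, K.T).T  # (M^{-1} K^T)^T = K M^{-T}
    return (sigma + sigma.T) / 2.0
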