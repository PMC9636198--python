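"""Independent oracles for the test suite.

These deliberately avoid the code paths they check: the penalized Gaussian
likelihood problems are solved by a generic monotone proximal-gradient
(ISTA) method instead of coordinate descent / ADMM, DAG scores are maximized
by exhaustive enumeration, and covariances come from plain matrix algebra.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


def _soft(x, t):
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def _is_pd(theta):
    try:
        np.linalg.cholesky(theta)
        return True
    except np.linalg.LinAlgError:
        return False


def ista_glasso(S, lam, max_iter=50_000, tol=1e-12):
    """Proximal-gradient solver for
    min_Theta -logdet Theta + tr(S Theta) + sum_ij lam_ij |theta_ij|.

    ``lam`` is a full (p x p) penalty matrix (diagonal included) or a scalar.
    Returns (theta, objective) with objective on the maximization scale
    logdet - tr - penalty.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    lam = np.full((p, p), float(lam)) if np.isscalar(lam) else np.asarray(lam, dtype=float)
    theta = np.diag(1.0 / np.diag(S))
    step = 1.0

    def smooth(t):
        sign, logdet = np.linalg.slogdet(t)
        if sign <= 0:
            return np.inf
        return -logdet + float(np.sum(S * t))

    def full_obj(t):
        return smooth(t) + float(np.sum(lam * np.abs(t)))

    obj = full_obj(theta)
    for _ in range(max_iter):
        grad = S - np.linalg.inv(theta)
        while True:
            cand = _soft(theta - step * grad, step * lam)
            cand = (cand + cand.T) / 2.0
            if _is_pd(cand):
                diff = cand - theta
                bound = (
                    smooth(theta)
                    + float(np.sum(grad * diff))
                    + float(np.sum(diff * diff)) / (2.0 * step)
                )
                if smooth(cand) <= bound + 1e-15:
                    break
            step *= 0.5
            if step < 1e-14:
                return theta, -obj
        new_obj = full_obj(cand)
        theta = cand
        step = min(step * 2.0, 1.0)
        if obj - new_obj < tol and obj - new_obj >= -1e-9:
            obj = new_obj
            break
        obj = new_obj
    return theta, -obj


def ista_hglasso(S, lam1, lam2, lam3, max_iter=50_000, tol=1e-13):
    """Proximal-gradient solver for the hub-penalized problem
    min_{Z, V hollow} -logdet(Z + V + V^T) + tr(S (Z+V+V^T))
                      + lam1 ||Z||_1 + lam2 ||V||_1 + lam3 sum_j ||V_j||_2.

    Returns (Z, V, objective-on-maximization-scale).
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    Z = np.diag(1.0 / np.diag(S))
    V = np.zeros((p, p))
    step = 0.5
    hollow = ~np.eye(p, dtype=bool)

    def theta_of(Z, V):
        return Z + V + V.T

    def smooth(Z, V):
        t = theta_of(Z, V)
        sign, logdet = np.linalg.slogdet(t)
        if sign <= 0 or not _is_pd((t + t.T) / 2.0):
            return np.inf
        return -logdet + float(np.sum(S * t))

    def pen(Z, V):
        return (
            lam1 * float(np.sum(np.abs(Z)))
            + lam2 * float(np.sum(np.abs(V)))
            + lam3 * float(np.sum(np.linalg.norm(V, axis=0)))
        )

    def prox_v(V, t):
        out = _soft(V, t * lam2) * hollow
        norms = np.linalg.norm(out, axis=0)
        scale = np.maximum(0.0, 1.0 - (t * lam3) / np.where(norms > 0, norms, 1.0))
        return out * scale

    obj = smooth(Z, V) + pen(Z, V)
    for _ in range(max_iter):
        G = S - np.linalg.inv(theta_of(Z, V))
        gZ = G
        gV = (G + G.T) * hollow
        while True:
            Zc = _soft(Z - step * gZ, step * lam1)
            Zc = (Zc + Zc.T) / 2.0
            Vc = prox_v(V - step * gV, step)
            sm = smooth(Zc, Vc)
            if np.isfinite(sm):
                dZ, dV = Zc - Z, Vc - V
                bound = (
                    smooth(Z, V)
                    + float(np.sum(gZ * dZ))
                    + float(np.sum(gV * dV))
                    + (float(np.sum(dZ * dZ)) + float(np.sum(dV * dV))) / (2.0 * step)
                )
                if sm <= bound + 1e-15:
                    break
            step *= 0.5
            if step < 1e-14:
                return Z, V, -obj
        Z, V = Zc, Vc
        new_obj = sm + pen(Z, V)
        step = min(step * 2.0, 1.0)
        if obj - new_obj < tol and obj - new_obj >= -1e-9:
            obj = new_obj
            break
        obj = new_obj
    return Z, V, -obj


def all_dags(nodes):
    """Every DAG over the given nodes as a list of (parent, child) edge lists."""
    pairs = [(a, b) for a, b in itertools.permutations(nodes, 2)]
    out = []
    for mask in itertools.product([0, 1], repeat=len(pairs)):
        edges = [p for p, keep in zip(pairs, mask) if keep]
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        if nx.is_directed_acyclic_graph(g):
            out.append(edges)
    return out


def partial_correlation(sigma, i, j, cond):
    """Partial correlation of variables i, j given the index set ``cond``,
    from the joint covariance via Schur complement."""
    sigma = np.asarray(sigma, dtype=float)
    keep = [i, j] + list(cond)
    sub = sigma[np.ix_(keep, keep)]
    prec = np.linalg.inv(sub)
    return -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])


def random_gbn(rng, n_nodes, edge_prob=0.35):
    """Random linear-Gaussian model for oracle tests."""
    from grnlearn.gbn import DAGStructure, GBNModel

    nodes = [f"v{i}" for i in range(n_nodes)]
    order = rng.permutation(n_nodes)
    parent_sets = {n: set() for n in nodes}
    for a_pos in range(n_nodes):
        for b_pos in range(a_pos + 1, n_nodes):
            if rng.random() < edge_prob:
                parent_sets[nodes[order[b_pos]]].add(nodes[order[a_pos]])
    structure = DAGStructure(
        nodes=nodes, parent_sets={k: frozenset(v) for k, v in parent_sets.items()}
    )
    beta = {
        n: {
            p: float(rng.choice([-1.0, 1.0]) * rng.uniform(0.2, 1.2))
            for p in structure.parent_sets[n]
        }
        for n in nodes
    }
    nu = {n: float(rng.uniform(0.3, 2.0)) for n in nodes}
    mu = {n: float(rng.normal(0, 1)) for n in nodes}
    return GBNModel(structure=structure, beta=beta, nu=nu, mu=mu)
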