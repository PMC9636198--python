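"""Sparse precision-matrix estimation: Glasso, Hub Glasso, Scale-Free Glasso.

All three learners estimate the precision matrix Theta = Sigma^{-1} of a
zero-mean multivariate Gaussian by maximizing a penalized log-likelihood

    log det Theta - tr(S Theta) - penalty(Theta)

over symmetric positive-definite matrices, where S is the sample covariance.
The penalty differs per learner:

* ``glasso``       -- an l1 penalty, scalar or element-wise (the block
  coordinate-descent algorithm of the graphical lasso, with an inner cyclic
  coordinate-descent lasso per column).
* ``hglasso``      -- the hub decomposition Theta = Z + V + V^T with
  lambda1 ||Z||_1 + lambda2 ||V - diag V||_1 + lambda3 sum_j ||(V - diag V)_j||_2,
  solved by ADMM.
* ``sfglasso``     -- a log penalty alpha sum_i log(||Theta_-i||_1 + eps_i)
  on node-wise l1 norms plus a diagonal penalty, maximized by a
  majorize-minimize loop of re-weighted glasso solves.

The nonzero off-diagonal support of Theta defines the undirected network.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.linalg

from .containers import ExpressionMatrix

__all__ = [
    "PrecisionModel",
    "HubDecomposition",
    "PenaltyMatrix",
    "GlassoConfig",
    "ConvergenceError",
    "glasso",
    "glasso_objective",
    "hglasso",
    "hglasso_objective",
    "sfglasso_penalty_matrix",
    "sfglasso",
    "sfglasso_objective",
    "pn_loglik",
    "u_separated",
    "kkt_violation",
]

logger = logging.getLogger(__name__)

EDGE_TOLERANCE = 1e-10


class ConvergenceError(RuntimeError):
    """An iterative solver hit its iteration budget before converging."""


@dataclass
class PrecisionModel:
    """Symmetric positive-definite precision matrix over a set of genes."""

    theta: np.ndarray
    gene_ids: list[str]
    mu: np.ndarray | None = None
    edge_tolerance: float = EDGE_TOLERANCE

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        if theta.ndim != 2 or theta.shape[0] != theta.shape[1]:
            raise ValueError("theta must be square")
        if np.max(np.abs(theta - theta.T)) > 1e-8 * max(1.0, np.max(np.abs(theta))):
            raise ValueError("theta is not symmetric")
        self.theta = (theta + theta.T) / 2.0
        self.gene_ids = list(self.gene_ids)
        if len(self.gene_ids) != theta.shape[0]:
            raise ValueError("gene_ids length does not match theta")
        if self.mu is None:
            self.mu = np.zeros(theta.shape[0])
        self.mu = np.asarray(self.mu, dtype=float)
        if np.linalg.eigvalsh(self.theta)[0] <= 0:
            raise ValueError("theta is not positive definite")

    def support(self) -> np.ndarray:
        """Boolean adjacency of the binarized network (empty diagonal)."""
        adj = np.abs(self.theta) > self.edge_tolerance
        np.fill_diagonal(adj, False)
        return adj

    def edges(self) -> set[tuple[str, str]]:
        """Undirected edges with lexicographically ordered endpoints."""
        adj = self.support()
        out: set[tuple[str, str]] = set()
        for i, j in zip(*np.nonzero(np.triu(adj, 1))):
            a, b = self.gene_ids[i], self.gene_ids[j]
            out.add((a, b) if a <= b else (b, a))
        return out

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.support(), 1)))

    def partial_correlations(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.theta))
        pc = -self.theta / np.outer(d, d)
        np.fill_diagonal(pc, 1.0)
        return pc


@dataclass
class HubDecomposition:
    """Feasible split Theta = Z + V + V^T: sparse part Z, hub columns V."""

    Z: np.ndarray
    V: np.ndarray


@dataclass
class PenaltyMatrix:
    """Element-wise l1 penalties: symmetric off-diagonal matrix + diagonal vector."""

    offdiag: np.ndarray
    diag: np.ndarray

    def __post_init__(self) -> None:
        self.offdiag = np.asarray(self.offdiag, dtype=float)
        self.diag = np.asarray(self.diag, dtype=float)
        if np.any(self.offdiag < 0) or np.any(self.diag < 0):
            raise ValueError("penalties must be nonnegative")
        if np.max(np.abs(self.offdiag - self.offdiag.T)) > 1e-12:
            raise ValueError("penalty matrix must be symmetric")

    def full(self) -> np.ndarray:
        lam = self.offdiag.copy()
        np.fill_diagonal(lam, self.diag)
        return lam

    @classmethod
    def uniform(cls, p: int, lam: float) -> "PenaltyMatrix":
        return cls(offdiag=np.full((p, p), lam), diag=np.full(p, lam))


@dataclass
class GlassoConfig:
    tol: float = 1e-6
    max_sweeps: int = 500
    inner_tol: float = 1e-9
    inner_max: int = 1000


def _as_penalty(penalty, p: int) -> PenaltyMatrix:
    if isinstance(penalty, PenaltyMatrix):
        return penalty
    lam = float(penalty)
    if lam < 0:
        raise ValueError("penalty must be >= 0")
    return PenaltyMatrix.uniform(p, lam)


def _lasso_cd(W11, s12, lam12, beta0, tol, max_iter):
    """Cyclic coordinate descent for
    min_b 0.5 b^T W11 b - s12^T b + sum_k lam12_k |b_k|  (warm-started)."""
    beta = beta0.copy()
    u = W11 @ beta
    diag = np.diag(W11)
    m = len(s12)
    order = np.arange(m)
    for it in range(max_iter):
        max_change = 0.0
        # full pass every 5th iteration, active-set passes in between
        sweep = order if it % 5 == 0 else np.nonzero(beta)[0]
        for k in sweep:
            resid = s12[k] - (u[k] - diag[k] * beta[k])
            val = abs(resid) - lam12[k]
            new = math.copysign(val, resid) / diag[k] if val > 0 else 0.0
            change = new - beta[k]
            if change != 0.0:
                u += W11[:, k] * change
                beta[k] = new
                max_change = max(max_change, abs(change))
        if max_change < tol:
            break
    return beta


def glasso(S, penalty, config: GlassoConfig | None = None, gene_ids=None) -> PrecisionModel:
    """l1-penalized Gaussian maximum likelihood by block coordinate descent.

    W is initialized to S plus the diagonal penalty; each sweep solves one
    lasso subproblem per column and writes the solution back into W; Theta is
    recovered from W and the lasso coefficients in a final cycle.  Converges
    when the mean absolute off-diagonal change of W in one sweep drops below
    ``tol`` times the mean absolute off-diagonal of S.
    """
    config = config or GlassoConfig()
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if np.any(np.diag(S) <= 0):
        raise ValueError("sample covariance has non-positive diagonal entries")
    pen = _as_penalty(penalty, p)
    W = S + np.diag(pen.diag)
    B = np.zeros((p, p))  # B[:, j] = lasso coefficients for column j
    offdiag_mask = ~np.eye(p, dtype=bool)
    scale = np.mean(np.abs(S[offdiag_mask])) if p > 1 else 1.0
    if scale <= 0:
        scale = np.mean(np.abs(np.diag(S)))
    converged = p == 1
    keep = np.arange(p)
    for sweep in range(config.max_sweeps):
        if p == 1:
            break
        w_old = W[offdiag_mask].copy()
        for j in range(p):
            rest = np.delete(keep, j)
            W11 = W[np.ix_(rest, rest)]
            s12 = S[rest, j]
            lam12 = pen.offdiag[rest, j]
            beta = _lasso_cd(W11, s12, lam12, B[rest, j], config.inner_tol, config.inner_max)
            B[rest, j] = beta
            w12 = W11 @ beta
            W[rest, j] = w12
            W[j, rest] = w12
        change = np.mean(np.abs(W[offdiag_mask] - w_old))
        if change < config.tol * scale:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"glasso did not converge in {config.max_sweeps} sweeps (last change {change:.3g})"
        )
    theta = np.zeros((p, p))
    for j in range(p):
        rest = np.delete(keep, j)
        beta = B[rest, j]
        denom = W[j, j] - W[rest, j] @ beta
        theta_jj = 1.0 / denom
        theta[j, j] = theta_jj
        theta[rest, j] = -beta * theta_jj
    theta = (theta + theta.T) / 2.0
    ids = list(gene_ids) if gene_ids is not None else [f"g{i + 1}" for i in range(p)]
    return PrecisionModel(theta=theta, gene_ids=ids)


def glasso_objective(theta, S, penalty) -> float:
    """log det Theta - tr(S Theta) - sum_ij lambda_ij |theta_ij|."""
    theta = np.asarray(theta, dtype=float)
    S = np.asarray(S, dtype=float)
    pen = _as_penalty(penalty, theta.shape[0])
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0 or np.linalg.eigvalsh((theta + theta.T) / 2.0)[0] <= 0:
        raise ValueError("theta is not positive definite")
    return float(logdet - np.trace(S @ theta) - np.sum(pen.full() * np.abs(theta)))


def kkt_violation(theta, S, penalty) -> float:
    """Max off-diagonal violation of the glasso stationarity bound
    |w_ij - s_ij| <= lambda_ij, with W = Theta^{-1} (0 at the exact optimum)."""
    theta = np.asarray(theta, dtype=float)
    S = np.asarray(S, dtype=float)
    pen = _as_penalty(penalty, theta.shape[0])
    W = np.linalg.inv(theta)
    viol = np.abs(W - S) - pen.offdiag
    np.fill_diagonal(viol, -np.inf)
    return float(np.max(viol))


# ---------------------------------------------------------------------------
# Hub Glasso


def _soft(x, t):
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def hglasso_objective(theta, S, lambda1, lambda2, lambda3, Z=None, V=None) -> float:
    """Hub-penalized objective evaluated at a decomposition (Z, V).

    When Z/V are omitted the trivial split Z = Theta, V = 0 is used.
    """
    theta = np.asarray(theta, dtype=float)
    S = np.asarray(S, dtype=float)
    if Z is None:
        Z = theta
    if V is None:
        V = np.zeros_like(theta)
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        raise ValueError("theta is not positive definite")
    Voff = V - np.diag(np.diag(V))
    return float(
        logdet
        - np.trace(S @ theta)
        - lambda1 * np.sum(np.abs(Z))
        - lambda2 * np.sum(np.abs(Voff))
        - lambda3 * np.sum(np.linalg.norm(Voff, axis=0))
    )


@dataclass
class HGlassoConfig:
    rho: float = 2.5
    tol: float = 1e-5
    max_iter: int = 10_000


def hglasso(
    S,
    lambda1: float,
    lambda2: float,
    lambda3: float,
    config: HGlassoConfig | None = None,
    gene_ids=None,
) -> tuple[PrecisionModel, HubDecomposition]:
    """Hub graphical lasso by ADMM on the split Theta = Z + V + Vt, Vt = V^T.

    Each subproblem has a closed form: an eigendecomposition step for Theta,
    soft-thresholding for Z, and an element-wise followed by column-group
    soft-threshold for V (diagonal unpenalized).  Stops when primal residuals
    fall below ``tol``.
    """
    if min(lambda1, lambda2, lambda3) < 0:
        raise ValueError("penalties must be >= 0")
    config = config or HGlassoConfig()
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    rho = config.rho
    Theta = np.diag(1.0 / np.diag(S))
    Z = Theta.copy()
    V = np.zeros((p, p))
    Vt = np.zeros((p, p))
    Gamma = np.zeros((p, p))
    Delta = np.zeros((p, p))
    for it in range(config.max_iter):
        # Theta step: argmin -logdet + tr(S Theta) + rho/2 ||Theta - A||^2
        A = Z + V + Vt - Gamma
        M = rho * (A + A.T) / 2.0 - S
        d, Q = np.linalg.eigh((M + M.T) / 2.0)
        theta_eigs = (d + np.sqrt(d * d + 4.0 * rho)) / (2.0 * rho)
        Theta = (Q * theta_eigs) @ Q.T
        prev_sum = Z + V + Vt
        # Z step
        Z = _soft(Theta - V - Vt + Gamma, lambda1 / rho)
        # V step: rho ||V - M2||^2 + lambda2 ||V||_1 + lambda3 sum_j ||V_j||_2.
        # V is kept hollow: the diagonal of Theta is carried by Z, so hub
        # columns are pure off-diagonal structure and the lambda2/lambda3 -> inf
        # limit collapses to the plain glasso at lambda1.
        M2 = ((Theta - Z - Vt + Gamma) + (Vt.T - Delta)) / 2.0
        V = _soft(M2, lambda2 / (2.0 * rho))
        np.fill_diagonal(V, 0.0)
        norms = np.linalg.norm(V, axis=0)
        shrink = np.maximum(0.0, 1.0 - (lambda3 / (2.0 * rho)) / np.where(norms > 0, norms, 1.0))
        V = V * shrink
        # Vt step (quadratic only, hollow like V)
        Vt = ((Theta - Z - V + Gamma) + (V + Delta).T) / 2.0
        np.fill_diagonal(Vt, 0.0)
        # dual updates
        R1 = Theta - Z - V - Vt
        R2 = V - Vt.T
        Gamma = Gamma + R1
        Delta = Delta + R2
        r1 = np.linalg.norm(R1) / max(1.0, np.linalg.norm(Theta))
        r2 = np.linalg.norm(R2) / max(1.0, np.linalg.norm(V))
        s = rho * np.linalg.norm(Z + V + Vt - prev_sum) / max(1.0, np.linalg.norm(Theta))
        if max(r1, r2, s) < config.tol:
            break
    else:
        raise ConvergenceError(f"hglasso ADMM did not converge in {config.max_iter} iterations")
    logger.info("hglasso converged in %d ADMM iterations", it + 1)
    Theta = (Theta + Theta.T) / 2.0
    V_final = (V + Vt.T) / 2.0
    Z_final = Theta - V_final - V_final.T  # exact feasibility
    ids = list(gene_ids) if gene_ids is not None else [f"g{i + 1}" for i in range(p)]
    model = PrecisionModel(theta=Theta, gene_ids=ids)
    return model, HubDecomposition(Z=Z_final, V=V_final)


# ---------------------------------------------------------------------------
# Scale-Free Glasso


def sfglasso_penalty_matrix(theta_prev, alpha: float, eps) -> PenaltyMatrix:
    """Re-weighted penalties lambda_ij = alpha (1/(||Theta_-i||_1 + eps_i)
    + 1/(||Theta_-j||_1 + eps_j)) with diagonal penalties beta_i = 2 alpha / eps_i.

    ||Theta_-i||_1 is the l1 norm of row i without its diagonal entry; nodes
    that already carry many/strong edges receive smaller penalties, which is
    what lets high-degree hubs emerge.
    """
    theta_prev = np.asarray(theta_prev, dtype=float)
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    eps = np.asarray(eps, dtype=float)
    if eps.ndim == 0:
        eps = np.full(theta_prev.shape[0], float(eps))
    if np.any(eps <= 0):
        raise ValueError("eps must be positive")
    absrow = np.sum(np.abs(theta_prev), axis=1) - np.abs(np.diag(theta_prev))
    inv = 1.0 / (absrow + eps)
    offdiag = alpha * (inv[:, None] + inv[None, :])
    np.fill_diagonal(offdiag, 0.0)
    return PenaltyMatrix(offdiag=offdiag, diag=2.0 * alpha / eps)


def sfglasso_objective(theta, S, alpha: float, eps, beta_diag) -> float:
    """Power-law score: log det Theta - tr(S Theta)
    - alpha sum_i log(||Theta_-i||_1 + eps_i) - sum_i beta_i |theta_ii|."""
    theta = np.asarray(theta, dtype=float)
    S = np.asarray(S, dtype=float)
    eps = np.asarray(eps, dtype=float)
    beta_diag = np.asarray(beta_diag, dtype=float)
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        raise ValueError("theta is not positive definite")
    absrow = np.sum(np.abs(theta), axis=1) - np.abs(np.diag(theta))
    return float(
        logdet
        - np.trace(S @ theta)
        - alpha * np.sum(np.log(absrow + eps))
        - np.sum(beta_diag * np.abs(np.diag(theta)))
    )


def sfglasso(
    S,
    alpha: float,
    n_reweights: int = 2,
    config: GlassoConfig | None = None,
    gene_ids=None,
    include_initial: bool = False,
) -> tuple[PrecisionModel, list[dict]]:
    """Scale-free glasso: majorize-minimize loop of re-weighted glasso solves.

    The first solve uses a uniform scalar penalty alpha; each of the
    ``n_reweights`` subsequent solves uses element-wise penalties from
    :func:`sfglasso_penalty_matrix` with eps_i equal to the previous
    iteration's theta_ii.  When ``include_initial`` is true the initial
    uniform solve counts as the first re-weight.  Returns the final model and
    one record per re-weight with the power-law objective before/after under
    that iteration's (eps, beta) weights.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if n_reweights < 1:
        raise ValueError("n_reweights must be >= 1")
    S = np.asarray(S, dtype=float)
    model = glasso(S, alpha, config=config, gene_ids=gene_ids)
    records: list[dict] = []
    n_solves = n_reweights - 1 if include_initial else n_reweights
    for it in range(n_solves):
        theta_prev = model.theta
        eps = np.abs(np.diag(theta_prev))
        pen = sfglasso_penalty_matrix(theta_prev, alpha, eps)
        obj_prev = sfglasso_objective(theta_prev, S, alpha, eps, pen.diag)
        model = glasso(S, pen, config=config, gene_ids=gene_ids)
        obj_new = sfglasso_objective(model.theta, S, alpha, eps, pen.diag)
        records.append(
            {
                "iteration": it + 1,
                "objective_prev": obj_prev,
                "objective_new": obj_new,
                "eps": eps,
                "n_edges": model.n_edges,
            }
        )
        logger.info(
            "sfglasso reweight %d: objective %.6f -> %.6f, %d edges",
            it + 1,
            obj_prev,
            obj_new,
            model.n_edges,
        )
    return model, records


# ---------------------------------------------------------------------------


def pn_loglik(model: PrecisionModel, X: ExpressionMatrix) -> float:
    """Gaussian log-likelihood of the data under the precision model:
    sum_k [ -(N/2) log 2 pi + (1/2) log det Theta - (1/2) x_k^T Theta x_k ]."""
    if list(model.gene_ids) != list(X.gene_ids):
        if set(model.gene_ids) <= set(X.gene_ids):
            X = X.subset(list(model.gene_ids))
        else:
            raise ValueError("model genes missing from data")
    theta = model.theta
    p = theta.shape[0]
    try:
        c, low = scipy.linalg.cho_factor(theta, lower=True)
    except scipy.linalg.LinAlgError as exc:
        raise ValueError("theta is not positive definite") from exc
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    centered = X.values - model.mu
    quad = float(np.sum(centered * (centered @ theta)))
    n = X.n_samples
    return -0.5 * n * p * math.log(2.0 * math.pi) + 0.5 * n * logdet - 0.5 * quad


def u_separated(edges, x: str, y: str, S, nodes=None) -> bool:
    """True iff every path between x and y in the undirected graph passes
    through S (reachability after deleting S)."""
    S = set(S)
    g = nx.Graph()
    g.add_edges_from(edges)
    if nodes is not None:
        g.add_nodes_from(nodes)
        for node in {x, y} | S:
            if node not in g:
                raise KeyError(f"unknown node {node!r}")
    else:
        g.add_nodes_from({x, y} | S)
    if x == y or x in S or y in S:
        raise ValueError("x and y must be distinct and outside S")
    g.remove_nodes_from(S)
    return not nx.has_path(g, x, y)
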