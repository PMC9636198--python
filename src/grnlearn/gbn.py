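"""Gaussian Bayesian networks: structure, parameter fitting, BIC hill climbing.

A Gaussian Bayesian network (GBN) factorizes a multivariate normal density as
a product of univariate conditional normals, one per node given its parent
set in a DAG:

    P(X_1, ..., X_N) = prod_i  N(x_i | mu_i + sum_j beta_ij (x_j - mu_j), nu_i)

with regression coefficients beta, conditional variances nu and unconditional
means mu.  Structure is learned by greedy hill climbing over single-edge
moves (add / delete / reverse) maximizing the decomposable BIC score

    BIC(G) = sum_i [ loglik_i(MLE) - (k_i / 2) log n ],   k_i = |parents_i| + 2

(k counts the regression coefficients, the intercept and the residual
variance of node i).  Local scores are computed from the centered Gram matrix
of the data, so each candidate move costs a small linear solve instead of a
pass over the raw samples, and are memoized by (node, parent set).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .containers import ExpressionMatrix

__all__ = [
    "DAGStructure",
    "GBNModel",
    "HCTrace",
    "TraceRow",
    "sample_covariance",
    "fit_local_params",
    "local_bic",
    "bic_score",
    "hill_climb",
    "bn_loglik",
    "d_separated",
]

logger = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-12


@dataclass
class DAGStructure:
    """Directed acyclic graph given as per-node parent sets."""

    nodes: list[str]
    parent_sets: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        self.nodes = list(self.nodes)
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node ids")
        ps: dict[str, frozenset[str]] = {}
        for node in self.nodes:
            parents = frozenset(self.parent_sets.get(node, frozenset()))
            if node in parents:
                raise ValueError(f"self-loop at {node}")
            unknown = parents - node_set
            if unknown:
                raise ValueError(f"unknown parents {sorted(unknown)} of {node}")
            ps[node] = parents
        self.parent_sets = ps
        if not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise ValueError("parent sets contain a directed cycle")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for child, parents in self.parent_sets.items():
            g.add_edges_from((p, child) for p in parents)
        return g

    def edges(self) -> set[tuple[str, str]]:
        """Directed edges as (parent, child) pairs."""
        return {
            (p, c) for c, parents in self.parent_sets.items() for p in parents
        }

    @property
    def n_edges(self) -> int:
        return sum(len(p) for p in self.parent_sets.values())

    @classmethod
    def from_edges(cls, nodes: list[str], edges) -> "DAGStructure":
        ps: dict[str, set[str]] = {n: set() for n in nodes}
        for parent, child in edges:
            ps[child].add(parent)
        return cls(nodes=list(nodes), parent_sets={k: frozenset(v) for k, v in ps.items()})


@dataclass
class GBNModel:
    """DAG plus fitted linear-Gaussian parameters (beta, nu, mu)."""

    structure: DAGStructure
    beta: dict[str, dict[str, float]]
    nu: dict[str, float]
    mu: dict[str, float]

    def __post_init__(self) -> None:
        for node in self.structure.nodes:
            if self.nu[node] <= 0:
                raise ValueError(f"nonpositive conditional variance at {node}")
            coeffs = self.beta.get(node, {})
            if set(coeffs) != set(self.structure.parent_sets[node]):
                raise ValueError(f"beta keys of {node} do not match its parent set")


@dataclass
class TraceRow:
    iteration: int
    move: str  # "add" | "delete" | "reverse"
    edge: tuple[str, str]  # (parent, child) before the move
    bic: float
    n_edges: int


@dataclass
class HCTrace:
    """Record of one greedy hill-climbing run.

    ``rows`` lists every accepted move in order; ``checkpoints`` maps a
    requested directed-edge count to the fitted model snapshot taken the
    first time the run reached that size; ``checkpoint_unm_edges`` holds the
    moralized (undirected) edge count at each checkpoint.
    """

    nodes: list[str]
    rows: list[TraceRow] = field(default_factory=list)
    checkpoints: dict[int, GBNModel] = field(default_factory=dict)
    checkpoint_unm_edges: dict[int, int] = field(default_factory=dict)
    converged: bool = False

    def structure_at(self, iteration: int) -> DAGStructure:
        """Replay accepted moves up to and including ``iteration`` (1-based)."""
        ps: dict[str, set[str]] = {n: set() for n in self.nodes}
        for row in self.rows:
            if row.iteration > iteration:
                break
            parent, child = row.edge
            if row.move == "add":
                ps[child].add(parent)
            elif row.move == "delete":
                ps[child].discard(parent)
            else:  # reverse: parent->child becomes child->parent
                ps[child].discard(parent)
                ps[parent].add(child)
        return DAGStructure(
            nodes=list(self.nodes), parent_sets={k: frozenset(v) for k, v in ps.items()}
        )


def sample_covariance(X: ExpressionMatrix) -> np.ndarray:
    """Sample covariance S = D^T D / (n - 1) of the centered data.

    For standardized input the diagonal is set to exactly 1 (it equals 1 up
    to floating-point rounding by the n-1 standardization convention).
    """
    n = X.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples for a covariance matrix")
    centered = X.values - X.values.mean(axis=0)
    s = centered.T @ centered / (n - 1)
    s = (s + s.T) / 2.0
    if X.standardized:
        np.fill_diagonal(s, 1.0)
    return s


class LocalScorer:
    """Memoized local Gaussian log-likelihood / BIC scores from the Gram matrix.

    For node c with parent set P, the OLS fit with intercept has MLE residual
    variance  nu = (C_cc - C_cP C_PP^{-1} C_Pc) / n  where C is the centered
    Gram matrix; the maximized local log-likelihood is the closed form
    -(n/2) (log(2 pi nu) + 1).
    """

    def __init__(self, X: ExpressionMatrix):
        self.n = X.n_samples
        self.gene_ids = list(X.gene_ids)
        self.index = {g: i for i, g in enumerate(self.gene_ids)}
        centered = X.values - X.values.mean(axis=0)
        self.gram = centered.T @ centered
        self.means = X.values.mean(axis=0)
        self._cache: dict[tuple[str, frozenset[str]], float] = {}
        self._floored: set[tuple[str, frozenset[str]]] = set()

    def mle_variance(self, child: str, parents: frozenset[str]) -> float:
        ci = self.index[child]
        if not parents:
            nu = self.gram[ci, ci] / self.n
        else:
            pi = [self.index[p] for p in parents]
            cpp = self.gram[np.ix_(pi, pi)]
            cpc = self.gram[pi, ci]
            try:
                coef = np.linalg.solve(cpp, cpc)
            except np.linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError(
                    f"rank-deficient design for node {child} with parents {sorted(parents)}"
                ) from exc
            nu = (self.gram[ci, ci] - cpc @ coef) / self.n
        key = (child, parents)
        if nu < VARIANCE_FLOOR:
            if key not in self._floored:
                self._floored.add(key)
                warnings.warn(
                    f"residual variance of {child} clamped to {VARIANCE_FLOOR:g}",
                    RuntimeWarning,
                    stacklevel=2,
                )
            nu = VARIANCE_FLOOR
        return nu

    def ols(self, child: str, parents: frozenset[str]) -> tuple[dict[str, float], float, float]:
        """OLS of child on parents: (coefficients, intercept, MLE variance)."""
        order = sorted(parents)
        ci = self.index[child]
        if not order:
            return {}, float(self.means[ci]), self.mle_variance(child, parents)
        pi = [self.index[p] for p in order]
        cpp = self.gram[np.ix_(pi, pi)]
        cpc = self.gram[pi, ci]
        try:
            coef = np.linalg.solve(cpp, cpc)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"rank-deficient design for node {child} with parents {order}"
            ) from exc
        # guard against numerically singular but solvable systems
        if not np.all(np.isfinite(coef)) or np.linalg.cond(cpp) > 1e12:
            raise np.linalg.LinAlgError(
                f"rank-deficient design for node {child} with parents {order}"
            )
        intercept = float(self.means[ci] - coef @ self.means[pi])
        nu = float((self.gram[ci, ci] - cpc @ coef) / self.n)
        if nu < VARIANCE_FLOOR:
            warnings.warn(
                f"residual variance of {child} clamped to {VARIANCE_FLOOR:g}",
                RuntimeWarning,
                stacklevel=2,
            )
            nu = VARIANCE_FLOOR
        return dict(zip(order, map(float, coef))), intercept, nu

    def local_loglik(self, child: str, parents: frozenset[str]) -> float:
        nu = self.mle_variance(child, parents)
        return -(self.n / 2.0) * (math.log(2.0 * math.pi * nu) + 1.0)

    def local_bic(self, child: str, parents: frozenset[str]) -> float:
        key = (child, parents)
        if key not in self._cache:
            k = len(parents) + 2
            self._cache[key] = self.local_loglik(child, parents) - (k / 2.0) * math.log(self.n)
        return self._cache[key]


def fit_local_params(structure: DAGStructure, X: ExpressionMatrix) -> GBNModel:
    """Maximum-likelihood fit of every node's regression on its parents.

    nu is the MLE residual variance (divide by n); mu the sample mean.
    """
    scorer = LocalScorer(X)
    beta: dict[str, dict[str, float]] = {}
    nu: dict[str, float] = {}
    mu: dict[str, float] = {}
    for node in structure.nodes:
        parents = structure.parent_sets[node]
        if X.n_samples <= len(parents) + 1:
            raise ValueError(
                f"need more than {len(parents) + 1} samples to fit node {node}"
            )
        coeffs, _intercept, variance = scorer.ols(node, parents)
        beta[node] = coeffs
        nu[node] = variance
        mu[node] = float(scorer.means[scorer.index[node]])
    return GBNModel(structure=structure, beta=beta, nu=nu, mu=mu)


def local_bic(node: str, parents, X: ExpressionMatrix) -> float:
    """Local BIC of one node: max log-likelihood minus (k/2) log n."""
    return LocalScorer(X).local_bic(node, frozenset(parents))


def bic_score(structure: DAGStructure, X: ExpressionMatrix) -> float:
    """Decomposable BIC of the whole DAG (larger is better)."""
    scorer = LocalScorer(X)
    return sum(scorer.local_bic(n, structure.parent_sets[n]) for n in structure.nodes)


_MOVE_ORDER = {"add": 0, "delete": 1, "reverse": 2}
_IMPROVE_EPS = 1e-9


def _descendants(children: dict[str, set[str]], start: str) -> set[str]:
    seen: set[str] = set()
    stack = [start]
    while stack:
        node = stack.pop()
        for nxt in children[node]:
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return seen


def _moral_edge_count(parent_sets: dict[str, set[str]]) -> int:
    edges: set[tuple[str, str]] = set()
    for child, parents in parent_sets.items():
        plist = sorted(parents)
        for p in plist:
            edges.add(tuple(sorted((p, child))))
        for i in range(len(plist)):
            for j in range(i + 1, len(plist)):
                edges.add((plist[i], plist[j]))
    return len(edges)


def hill_climb(
    X: ExpressionMatrix,
    max_iter: int = 10_000,
    checkpoints=(),
    reversals: bool = True,
    max_parents: int | None = None,
) -> tuple[GBNModel, HCTrace]:
    """Greedy BIC hill climbing from the empty graph.

    Evaluates every add / delete / reverse single-edge move, applies the best
    strictly improving acyclic one, and repeats until no move improves the
    score or ``max_iter`` accepted moves.  Ties are broken by move type
    (add < delete < reverse) then lexicographic (child, parent).  Snapshots of
    the fitted model are taken the first time the directed edge count hits
    each value in ``checkpoints``.
    """
    if max_iter < 0:
        raise ValueError("max_iter must be >= 0")
    scorer = LocalScorer(X)
    nodes = list(X.gene_ids)
    n_nodes = len(nodes)
    idx = {g: i for i, g in enumerate(nodes)}
    parent_sets: dict[str, set[str]] = {n: set() for n in nodes}
    children: dict[str, set[str]] = {n: set() for n in nodes}
    cur = {n: scorer.local_bic(n, frozenset()) for n in nodes}
    total = sum(cur.values())

    # add_delta[p, c]: gain of adding edge p->c; del_delta[p, c]: gain of
    # deleting existing p->c.  NaN marks unavailable moves.
    add_delta = np.full((n_nodes, n_nodes), np.nan)
    del_delta = np.full((n_nodes, n_nodes), np.nan)

    def refresh_child(child: str) -> None:
        c = idx[child]
        parents = frozenset(parent_sets[child])
        base = cur[child]
        add_delta[:, c] = np.nan
        del_delta[:, c] = np.nan
        at_cap = max_parents is not None and len(parents) >= max_parents
        for p_name in nodes:
            p = idx[p_name]
            if p_name == child:
                continue
            if p_name in parents:
                del_delta[p, c] = scorer.local_bic(child, parents - {p_name}) - base
            elif not at_cap:
                try:
                    add_delta[p, c] = scorer.local_bic(child, parents | {p_name}) - base
                except np.linalg.LinAlgError:
                    add_delta[p, c] = np.nan

    for node in nodes:
        refresh_child(node)

    trace = HCTrace(nodes=nodes)
    checkpoints = sorted(set(int(c) for c in checkpoints))
    pending_checkpoints = set(checkpoints)
    n_edges = 0
    iteration = 0
    if 0 in pending_checkpoints:
        trace.checkpoints[0] = fit_local_params(
            DAGStructure.from_edges(nodes, []), X
        )
        trace.checkpoint_unm_edges[0] = 0
        pending_checkpoints.discard(0)

    while iteration < max_iter:
        candidates: list[tuple[float, int, str, str, str]] = []
        with np.errstate(invalid="ignore"):
            add_mask = add_delta > _IMPROVE_EPS
            del_mask = del_delta > _IMPROVE_EPS
        for p, c in zip(*np.nonzero(add_mask)):
            candidates.append((add_delta[p, c], _MOVE_ORDER["add"], nodes[c], nodes[p], "add"))
        for p, c in zip(*np.nonzero(del_mask)):
            candidates.append((del_delta[p, c], _MOVE_ORDER["delete"], nodes[c], nodes[p], "delete"))
        if reversals:
            for child, parents in parent_sets.items():
                c = idx[child]
                for p_name in parents:
                    p = idx[p_name]
                    gain_add = add_delta[c, p]  # add child->parent edge
                    if np.isnan(gain_add):
                        continue
                    delta = del_delta[p, c] + gain_add
                    if delta > _IMPROVE_EPS:
                        candidates.append(
                            (delta, _MOVE_ORDER["reverse"], child, p_name, "reverse")
                        )
        if not candidates:
            trace.converged = True
            break
        candidates.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))

        accepted = None
        desc_cache: dict[str, set[str]] = {}
        for delta, _order, child, parent, move in candidates:
            if move == "add":
                if child not in desc_cache:
                    desc_cache[child] = _descendants(children, child)
                if parent in desc_cache[child]:
                    continue  # would create a cycle
            elif move == "reverse":
                children[parent].discard(child)
                reachable = _descendants(children, parent)
                children[parent].add(child)
                if child in reachable:
                    continue  # alternative directed path parent ~> child
            accepted = (delta, child, parent, move)
            break
        if accepted is None:
            trace.converged = True
            break

        delta, child, parent, move = accepted
        if move == "add":
            parent_sets[child].add(parent)
            children[parent].add(child)
            n_edges += 1
            affected = [child]
        elif move == "delete":
            parent_sets[child].remove(parent)
            children[parent].discard(child)
            n_edges -= 1
            affected = [child]
        else:
            parent_sets[child].remove(parent)
            children[parent].discard(child)
            parent_sets[parent].add(child)
            children[child].add(parent)
            affected = [child, parent]
        for node in affected:
            cur[node] = scorer.local_bic(node, frozenset(parent_sets[node]))
            refresh_child(node)
        total += delta
        iteration += 1
        trace.rows.append(
            TraceRow(iteration=iteration, move=move, edge=(parent, child), bic=total, n_edges=n_edges)
        )
        logger.debug("hc move %d: %s %s->%s bic=%.4f", iteration, move, parent, child, total)
        if n_edges in pending_checkpoints:
            structure = DAGStructure(
                nodes=nodes, parent_sets={k: frozenset(v) for k, v in parent_sets.items()}
            )
            trace.checkpoints[n_edges] = fit_local_params(structure, X)
            trace.checkpoint_unm_edges[n_edges] = _moral_edge_count(parent_sets)
            pending_checkpoints.discard(n_edges)

    structure = DAGStructure(
        nodes=nodes, parent_sets={k: frozenset(v) for k, v in parent_sets.items()}
    )
    model = fit_local_params(structure, X)
    logger.info(
        "hill climb finished: %d moves, %d edges, BIC %.4f, converged=%s",
        iteration,
        n_edges,
        total,
        trace.converged,
    )
    return model, trace


def bn_loglik(model: GBNModel, X: ExpressionMatrix) -> float:
    """Exact log-likelihood: sum over samples and nodes of the conditional
    normal log-density at the model's parameters."""
    missing = set(model.structure.nodes) - set(X.gene_ids)
    if missing:
        raise ValueError(f"model nodes missing from data: {sorted(missing)}")
    idx = {g: i for i, g in enumerate(X.gene_ids)}
    total = 0.0
    n = X.n_samples
    for node in model.structure.nodes:
        nu = model.nu[node]
        if nu <= 0:
            raise ValueError(f"nonpositive variance at {node}")
        pred = np.full(n, model.mu[node])
        for parent, coef in model.beta[node].items():
            pred = pred + coef * (X.values[:, idx[parent]] - model.mu[parent])
        resid = X.values[:, idx[node]] - pred
        total += -0.5 * n * math.log(2.0 * math.pi * nu) - 0.5 * float(resid @ resid) / nu
    return total


def d_separated(structure: DAGStructure, x: str, y: str, S) -> bool:
    """True iff x and y are d-separated by S in the DAG (no active path)."""
    S = set(S)
    known = set(structure.nodes)
    for node in {x, y} | S:
        if node not in known:
            raise KeyError(f"unknown node {node!r}")
    if x == y or x in S or y in S:
        raise ValueError("x and y must be distinct and outside S")
    return nx.is_d_separator(structure.to_networkx(), {x}, {y}, S)
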