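"""Graph-regularized semi-supervised label propagation.

Scores are obtained by minimizing, over a real matrix Q,

    sum_{i,j} W_ij * ||q^i - q^j||_2  +  Tr((Q - Y)^T U (Q - Y))

where W is a symmetric nonnegative graph over the entities (a re-linked
binary similarity network in miRNA space, the semantic similarity matrix in
disease space), Y holds the known causal labels (MD, or MD^T in disease
space) and U = mu*I trades label fit against graph smoothness.  The graph
penalty uses the *unsquared* row-difference norm, which is exactly the form
IRLS majorizes: at each iteration the current differences define a
reweighted graph G_ij = W_ij / (2 max(||q^i - q^j||, eps)) whose Laplacian
linear system (2 L_G + U) Q = U Y is solved in closed form.  The objective
is non-increasing across iterations (standard majorize-minimize argument)
and the iteration stops when Q moves less than ``tol`` in relative
Frobenius norm.

The miRNA-space and disease-space solutions for one similarity metric are
fused by simple averaging: MD' = (Qm + Qd^T) / 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import scipy.linalg

from .config import SolverParams
from .imputation import BinaryNetwork, ImputedNetwork
from .types import ScoreMatrix, SimilarityMatrix

log = logging.getLogger("mdcapnet")

__all__ = ["SSLProblem", "SSLSolution", "ssl_objective", "ssl_solve",
           "fuse_spaces", "run_metric"]


@dataclass
class SSLProblem:
    W: np.ndarray  # n x n symmetric nonnegative, zero diagonal
    Y: np.ndarray  # n x k labels in [0, 1]
    params: SolverParams = field(default_factory=SolverParams)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        n = self.W.shape[0]
        if self.W.shape != (n, n):
            raise ValueError("W must be square")
        if np.abs(self.W - self.W.T).max(initial=0.0) > 1e-10:
            raise ValueError("W must be symmetric")
        if (self.W < 0).any():
            raise ValueError("W must be nonnegative")
        if np.diagonal(self.W).any():
            raise ValueError("W must have a zero diagonal")
        if self.Y.ndim != 2 or self.Y.shape[0] != n:
            raise ValueError(f"Y shape {self.Y.shape} incompatible with W ({n} rows)")
        if self.Y.min(initial=0.0) < 0 or self.Y.max(initial=0.0) > 1:
            raise ValueError("Y entries must lie in [0, 1]")
        self.params.validate()


@dataclass
class SSLSolution:
    Q: np.ndarray
    objective_trace: List[float]
    iterations: int
    converged: bool


def ssl_objective(problem: SSLProblem, Q: np.ndarray) -> float:
    """Graph penalty (unsquared row-difference norms) + label-fitting trace."""
    Q = np.asarray(Q, dtype=float)
    if Q.shape != problem.Y.shape:
        raise ValueError(f"Q shape {Q.shape} != Y shape {problem.Y.shape}")
    ii, jj = np.nonzero(problem.W)
    graph_term = float(
        (problem.W[ii, jj] * np.linalg.norm(Q[ii] - Q[jj], axis=1)).sum()
    )
    R = Q - problem.Y
    fit_term = problem.params.mu * float((R * R).sum())
    return graph_term + fit_term


def _maybe_row_normalize(W: np.ndarray, enabled: bool) -> np.ndarray:
    if not enabled:
        return W
    deg = W.sum(axis=1)
    deg[deg == 0] = 1.0
    D = 1.0 / np.sqrt(deg)
    return W * D[:, None] * D[None, :]


def ssl_solve(problem: SSLProblem) -> SSLSolution:
    """IRLS iteration for the graph-regularized objective; Q0 = Y."""
    p = problem.params
    W = _maybe_row_normalize(problem.W, p.row_normalize)
    n, _ = W.shape
    Y = problem.Y
    Q = Y.copy()
    trace = [ssl_objective(problem, Q)]
    mu_diag = p.mu * np.ones(n)
    converged = False
    it = 0
    ii, jj = np.nonzero(np.triu(W, k=1))
    w_vals = W[ii, jj]
    for it in range(1, p.max_iter + 1):
        if ii.size:
            diffs = np.linalg.norm(Q[ii] - Q[jj], axis=1)
            g_vals = w_vals / (2.0 * np.maximum(diffs, p.eps))
            G = np.zeros_like(W)
            G[ii, jj] = g_vals
            G += G.T
            L = np.diag(G.sum(axis=1)) - G
        else:
            L = np.zeros_like(W)
        A = 2.0 * L + np.diag(mu_diag)
        try:
            Q_new = scipy.linalg.solve(A, mu_diag[:, None] * Y, assume_a="pos")
        except scipy.linalg.LinAlgError as exc:  # pragma: no cover - mu>0 guards
            raise ValueError(f"singular IRLS system: {exc}") from exc
        trace.append(ssl_objective(problem, Q_new))
        denom = max(np.linalg.norm(Q), 1e-30)
        delta = np.linalg.norm(Q_new - Q) / denom
        Q = Q_new
        if delta < p.tol:
            converged = True
            break
    if not converged:
        log.warning("IRLS did not converge in %d iterations", p.max_iter)
    return SSLSolution(Q, trace, it, converged)


def fuse_spaces(Qm: np.ndarray, Qd: np.ndarray) -> np.ndarray:
    """Average the miRNA-space and disease-space solutions: (Qm + Qd^T)/2."""
    Qm = np.asarray(Qm, dtype=float)
    Qd = np.asarray(Qd, dtype=float)
    if Qm.shape != Qd.T.shape:
        raise ValueError(f"shapes {Qm.shape} and {Qd.shape} are not transposable")
    return (Qm + Qd.T) / 2.0


def run_metric(
    ms_net: BinaryNetwork | ImputedNetwork,
    ds: SimilarityMatrix,
    md_net: BinaryNetwork | ImputedNetwork,
    params: Optional[SolverParams] = None,
    metric: str = "",
) -> ScoreMatrix:
    """Solve both spaces for one similarity metric and fuse the solutions.

    miRNA space: W = the (re-linked) binary similarity adjacency, Y = the
    (re-linked) association matrix.  Disease space: W = the semantic
    similarity matrix with its diagonal dropped, Y = the association matrix
    transposed.
    """
    if params is None:
        params = SolverParams()
    if isinstance(ms_net, ImputedNetwork):
        ms_net = ms_net.network
    if isinstance(md_net, ImputedNetwork):
        md_net = md_net.network
    if not md_net.is_bipartite:
        raise ValueError("md_net must be a bipartite association network")
    if ms_net.is_bipartite:
        raise ValueError("ms_net must be a square similarity network")
    if list(ms_net.row_ids) != list(md_net.row_ids):
        missing = set(ms_net.row_ids) ^ set(md_net.row_ids)
        raise ValueError(f"miRNA universes differ between networks: {sorted(missing)}")
    if list(ds.ids) != list(md_net.col_ids):
        missing = set(ds.ids) ^ set(md_net.col_ids)
        raise ValueError(f"disease universes differ: {sorted(missing)}")

    Y = md_net.adjacency
    sol_m = ssl_solve(SSLProblem(ms_net.adjacency, Y, params))
    W_d = ds.values.copy()
    np.fill_diagonal(W_d, 0.0)
    sol_d = ssl_solve(SSLProblem(W_d, Y.T, params))
    scores = fuse_spaces(sol_m.Q, sol_d.Q)
    return ScoreMatrix(scores, list(md_net.row_ids), list(md_net.col_ids),
                       provenance=f"metric:{metric}" if metric else "metric:?")
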