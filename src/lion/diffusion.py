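"""Random walk with restart on a disease subnetwork.

The walker starts on the disease's seed genes and at each step either moves
to a uniformly chosen neighbor of its current node or, with restart
probability ``r``, teleports back to the seed distribution:

    p^(k+1) = (1 - r) * W @ p^k + r * p^0

where W is the column-normalized adjacency matrix of the walk graph
(entry [i, j] = 1/degree(j) for each edge i–j) and p^0 is uniform over the
seeds.  Iteration stops at the first step whose L1 change is below ``tol``;
the fixed point p^inf scores every node by its network proximity to the
seeds, and lncRNAs are ranked by their raw p^inf entries.

For r > 0 the update is a contraction with factor (1 - r) in L1, so the
fixed point is unique and ``diffuse_closed_form`` can solve for it directly
as (I - (1 - r) W) p = r p0 — used as an independent oracle on small graphs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .exceptions import ConvergenceError, NormalizationError
from .subnet import DiseaseSubnetwork

logger = logging.getLogger(__name__)

__all__ = [
    "DiffusionParams",
    "WalkMatrix",
    "RestartVector",
    "ScoreVector",
    "column_normalize",
    "uniform_restart",
    "diffuse",
    "diffuse_closed_form",
    "rank_lncrnas",
]

#: above this node count the power iteration uses sparse mat-vec products
DENSE_THRESHOLD = 500


@dataclass(frozen=True)
class DiffusionParams:
    """Tunables of the walk: restart probability, tolerance, iteration cap."""

    r: float = 0.5
    tol: float = 1e-6
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 < self.r <= 1.0:
            raise ValueError(f"restart probability must be in (0, 1], got {self.r}")
        if self.tol <= 0:
            raise ValueError(f"tol must be positive, got {self.tol}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")


@dataclass(frozen=True)
class WalkMatrix:
    """Column-stochastic transition matrix over a fixed node order."""

    W: sp.csr_matrix
    node_order: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.node_order)


@dataclass(frozen=True)
class RestartVector:
    p0: np.ndarray
    node_order: tuple[str, ...]


@dataclass(frozen=True)
class ScoreVector:
    """p^k during iteration / p^inf at convergence, over ``node_order``."""

    p: np.ndarray
    node_order: tuple[str, ...]
    iterations: int
    final_residual: float
    residuals: tuple[float, ...] = field(default=(), repr=False)


def column_normalize(walk_edges: frozenset[tuple[str, str]] | set[tuple[str, str]],
                     node_order: tuple[str, ...]) -> WalkMatrix:
    """Build W with W[i, j] = 1/degree(j) for every undirected edge i–j."""
    index = {n: i for i, n in enumerate(node_order)}
    n = len(node_order)
    degree = np.zeros(n, dtype=np.int64)
    pairs = []
    for a, b in walk_edges:
        ia, ib = index[a], index[b]
        degree[ia] += 1
        degree[ib] += 1
        pairs.append((ia, ib))
    isolated = np.flatnonzero(degree == 0)
    if isolated.size:
        raise NormalizationError(
            "degree-0 node(s) cannot be column-normalized: "
            + ", ".join(node_order[i] for i in isolated[:5]))
    rows = np.empty(2 * len(pairs), dtype=np.int64)
    cols = np.empty(2 * len(pairs), dtype=np.int64)
    for k, (ia, ib) in enumerate(pairs):
        rows[2 * k], cols[2 * k] = ia, ib
        rows[2 * k + 1], cols[2 * k + 1] = ib, ia
    data = 1.0 / degree[cols]
    W = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    return WalkMatrix(W=W, node_order=node_order)


def uniform_restart(seeds: set[str] | frozenset[str],
                    node_order: tuple[str, ...]) -> RestartVector:
    """Restart distribution: mass 1/|seeds| on each seed, 0 elsewhere."""
    if not seeds:
        raise ValueError("seed set is empty")
    index = {n: i for i, n in enumerate(node_order)}
    missing = [s for s in seeds if s not in index]
    if missing:
        raise ValueError(f"seed(s) not in node order: {missing[:5]}")
    p0 = np.zeros(len(node_order))
    for s in seeds:
        p0[index[s]] = 1.0 / len(seeds)
    return RestartVector(p0=p0, node_order=node_order)


def diffuse(W: WalkMatrix, p0: RestartVector,
            params: DiffusionParams | None = None,
            dense_threshold: int = DENSE_THRESHOLD) -> ScoreVector:
    """Power iteration of the restart walk until the L1 change is < tol.

    Iteration starts at p^0.  Small systems use a dense matrix for the
    products; the result is identical either way.  Raises
    :class:`ConvergenceError` if ``max_iter`` is reached first.
    """
    if params is None:
        params = DiffusionParams()
    if W.node_order != p0.node_order:
        raise ValueError("walk matrix and restart vector use different node orders")
    r = params.r
    mat = W.W.toarray() if W.n <= dense_threshold else W.W
    p = p0.p0.copy()
    restart = r * p0.p0
    residuals: list[float] = []
    for k in range(1, params.max_iter + 1):
        p_next = (1.0 - r) * (mat @ p) + restart
        resid = float(np.abs(p_next - p).sum())
        residuals.append(resid)
        p = p_next
        if k % 10 == 0:
            logger.debug("iteration %d: L1 residual %.3e", k, resid)
        if resid < params.tol:
            return ScoreVector(p=p, node_order=W.node_order, iterations=k,
                               final_residual=resid,
                               residuals=tuple(residuals))
    raise ConvergenceError(
        f"no convergence after {params.max_iter} iterations "
        f"(final L1 residual {residuals[-1]:.3e} >= tol {params.tol:g})")


def diffuse_closed_form(W: WalkMatrix, p0: RestartVector,
                        r: float = 0.5) -> ScoreVector:
    """Exact fixed point by direct linear solve of (I - (1-r)W) p = r p0.

    Testing oracle for small graphs; the system is nonsingular for any
    r > 0 because W is column-stochastic.
    """
    if not 0.0 < r <= 1.0:
        raise ValueError(f"restart probability must be in (0, 1], got {r}")
    if W.node_order != p0.node_order:
        raise ValueError("walk matrix and restart vector use different node orders")
    A = np.eye(W.n) - (1.0 - r) * W.W.toarray()
    p = np.linalg.solve(A, r * p0.p0)
    return ScoreVector(p=p, node_order=W.node_order, iterations=0,
                       final_residual=0.0)


def rank_lncrnas(scores: ScoreVector,
                 sub: DiseaseSubnetwork) -> list[tuple[str, float, int]]:
    """Rank the subnetwork's lncRNAs by steady-state probability.

    Scores are the raw p^inf entries (no renormalization over lncRNAs).
    Descending by score, ties broken by identifier ascending; ranks are
    1-based ordinals.
    """
    if scores.node_order != sub.node_order:
        raise ValueError("score vector is not aligned with the subnetwork")
    index = sub.index()
    items = sorted(((l, float(scores.p[index[l]])) for l in sub.lncrnas),
                   key=lambda t: (-t[1], t[0]))
    return [(l, s, rank) for rank, (l, s) in enumerate(items, start=1)]
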