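"""Dissimilarity-based fuzzy clustering (FANNY-type) with membership exponent r.

Given a symmetric dissimilarity matrix D over n objects and a cluster count
k, the method finds a row-stochastic membership matrix U (u_iv = degree of
membership of object i in cluster v) minimizing

    F(U) = sum_v  [ sum_{i,j} u_iv^r u_jv^r d(i,j)^2 ]  /  [ sum_j u_jv^r ]

the Kaufman–Rousseeuw fuzzy-analysis objective written without the
conventional factor 2 in the denominator; the argmin is identical, only the
reported objective value is twice the factor-2 convention. The membership
exponent r > 1 controls fuzziness: r -> 1 approaches a crisp partition,
large r drives every membership toward the uniform 1/k.

No centroids exist — the objective is defined purely on pairwise
dissimilarities, which is what makes the method applicable to arbitrary
(e.g. k-mer feature) dissimilarities. The fit alternates Lagrangian
membership updates with a backtracking safeguard so the objective trace is
non-increasing; a small exhaustive/polished minimizer (`brute_force_min`)
serves as an independent correctness oracle for tiny instances.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize

from .encoding import DissimilarityMatrix

logger = logging.getLogger(__name__)

InitScheme = Literal["random_dirichlet", "spread_medoids"]


@dataclass(frozen=True)
class FannyConfig:
    """Fit settings: cluster count k, membership exponent r, convergence."""

    k: int = 2
    r: float = 2.0
    tol: float = 1e-9
    max_iter: int = 500
    n_restarts: int = 5
    seed: int = 0
    init: InitScheme = "random_dirichlet"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.r <= 1:
            raise ValueError("membership exponent r must exceed 1")
        if self.tol <= 0 or self.max_iter < 1 or self.n_restarts < 1:
            raise ValueError("invalid convergence settings")


@dataclass
class MembershipMatrix:
    """Row-stochastic n x k fuzzy membership matrix with ordered object ids."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        u = np.asarray(self.values, dtype=float)
        if u.ndim != 2 or u.shape[0] != len(self.ids):
            raise ValueError("membership shape does not match ids")
        if np.any(u < -1e-12) or np.any(u > 1 + 1e-12):
            raise ValueError("memberships must lie in [0, 1]")
        if np.abs(u.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("membership rows must sum to 1")
        self.values = np.clip(u, 0.0, 1.0)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass
class FannyResult:
    membership: MembershipMatrix
    objective: float
    hard_labels: np.ndarray
    iterations: int
    converged: bool
    restart_objectives: list[float] = field(default_factory=list)
    objective_trace: list[float] = field(default_factory=list)


def _objective_array(U: np.ndarray, D2: np.ndarray, r: float) -> float:
    W = U ** r
    P = np.einsum("iv,ij,jv->v", W, D2, W)
    Q = W.sum(axis=0)
    safe = Q > 1e-300
    return float(np.sum(P[safe] / Q[safe]))


def fanny_objective(U: MembershipMatrix, D: DissimilarityMatrix, r: float) -> float:
    """Evaluate the clustering objective exactly as defined above.

    The double sum runs over ordered pairs, so each unordered pair {i, j}
    contributes twice; no factor-2 correction is applied to the denominator.
    """
    if U.n != D.n:
        raise ValueError("membership and dissimilarity sizes disagree")
    return _objective_array(U.values, D.values ** 2, r)


def _membership_update(U: np.ndarray, D2: np.ndarray, r: float) -> np.ndarray:
    """One full Lagrangian update of all memberships.

    Stationarity of F under the row-sum constraints gives
    u_iv proportional to e_iv^(-1/(r-1)) with
    e_iv = (2 (D2 W)_iv Q_v - P_v) / Q_v^2, the partial derivative of F
    w.r.t. u_iv^r. Non-positive e (possible far from a minimum) is clipped
    to a small positive floor; the caller backtracks if the step raises F.
    """
    W = U ** r
    Q = np.maximum(W.sum(axis=0), 1e-300)
    DW = D2 @ W
    P = np.einsum("iv,iv->v", W, DW)
    e = (2.0 * DW * Q - P) / (Q ** 2)
    scale = e.max()
    if scale <= 0:  # degenerate geometry (e.g. all-zero D): stay put
        return U.copy()
    e = np.maximum(e, 1e-12 * scale)
    t = e ** (-1.0 / (r - 1.0))
    t /= t.max(axis=1, keepdims=True)  # guard against overflow before summing
    t /= t.sum(axis=1, keepdims=True)
    return t


def _init_membership(
    n: int, k: int, rng: np.random.Generator, scheme: InitScheme, D: np.ndarray
) -> np.ndarray:
    if scheme == "random_dirichlet":
        return rng.dirichlet(np.ones(k), size=n)
    # spread_medoids: greedy farthest-point medoids, memberships biased toward
    # the nearest medoid — deterministic given D.
    medoids = [int(np.argmax(D.sum(axis=1)))]
    while len(medoids) < k:
        dist_to_set = D[:, medoids].min(axis=1)
        medoids.append(int(np.argmax(dist_to_set)))
    U = np.full((n, k), 0.1 / max(k - 1, 1))
    nearest = np.argmin(D[:, medoids], axis=1)
    U[np.arange(n), nearest] = 0.9
    if k == 1:
        U[:] = 1.0
    return U / U.sum(axis=1, keepdims=True)


def _single_run(
    D2: np.ndarray, config: FannyConfig, U0: np.ndarray
) -> tuple[np.ndarray, list[float], bool, int]:
    U = U0.copy()
    obj = _objective_array(U, D2, config.r)
    trace = [obj]
    converged = False
    for it in range(1, config.max_iter + 1):
        U_full = _membership_update(U, D2, config.r)
        U_prop = U_full
        new_obj = _objective_array(U_prop, D2, config.r)
        alpha = 1.0
        # Backtrack toward the current iterate until the objective does not
        # increase; convex combinations preserve row-stochasticity.
        while new_obj > obj and alpha > 1e-6:
            alpha /= 2.0
            U_prop = U + alpha * (U_full - U)
            new_obj = _objective_array(U_prop, D2, config.r)
        if new_obj > obj:
            converged = True
            trace.append(obj)
            break
        U = U_prop
        trace.append(new_obj)
        rel = (obj - new_obj) / max(abs(obj), 1e-300)
        obj = new_obj
        if rel < config.tol:
            converged = True
            break
    return U, trace, converged, len(trace) - 1


def fanny_fit(D: DissimilarityMatrix, config: FannyConfig) -> FannyResult:
    """Minimize the fuzzy objective; best of ``n_restarts`` seeded starts.

    Deterministic given ``config.seed``. A restart whose membership matrix
    collapses a cluster (some column effectively zero everywhere) is
    re-initialized with a fresh seed and the event logged. Non-convergence
    within ``max_iter`` flags the result rather than raising.
    """
    n = D.n
    if config.k >= n:
        raise ValueError(f"k={config.k} must be smaller than n={n}")
    D2 = D.values ** 2
    rng = np.random.default_rng(config.seed)
    best: tuple[float, np.ndarray, list[float], bool, int] | None = None
    restart_objectives: list[float] = []

    def run_from(U0: np.ndarray) -> None:
        nonlocal best
        U, trace, converged, iters = _single_run(D2, config, U0)
        obj = trace[-1]
        restart_objectives.append(obj)
        if best is None or obj < best[0]:
            best = (obj, U, trace, converged, iters)

    # On tiny instances the local basins correspond to crisp partitions, so
    # enumerate them all (softened) as starts; randomized restarts cannot be
    # relied on to hit a small basin such as a singleton cluster.
    if config.k ** n <= 256:
        for assignment in itertools.product(range(config.k), repeat=n):
            U0 = np.full((n, config.k), 0.1 / max(config.k - 1, 1))
            U0[np.arange(n), assignment] = 0.9
            U0 /= U0.sum(axis=1, keepdims=True)
            run_from(U0)
    for restart in range(config.n_restarts):
        scheme = config.init if restart == 0 or config.init != "spread_medoids" \
            else "random_dirichlet"
        for attempt in range(5):
            U0 = _init_membership(n, config.k, rng, scheme, D.values)
            U, trace, converged, iters = _single_run(D2, config, U0)
            if U.max(axis=0).min() > 1e-8:
                break
            logger.info("degenerate cluster in restart %d, re-initializing", restart)
            scheme = "random_dirichlet"
        obj = trace[-1]
        restart_objectives.append(obj)
        if best is None or obj < best[0]:
            best = (obj, U, trace, converged, iters)
    obj, U, trace, converged, iters = best
    membership = MembershipMatrix(list(D.ids), U)
    labels, _ = harden(membership)
    return FannyResult(
        membership=membership,
        objective=obj,
        hard_labels=labels,
        iterations=iters,
        converged=converged,
        restart_objectives=restart_objectives,
        objective_trace=trace,
    )


def harden(U: MembershipMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Crisp labels by per-row argmax (ties go to the lowest cluster index).

    Returns ``(labels, straddlers)`` where ``straddlers`` flags objects whose
    largest membership is below 1/k + 0.05 — objects the fuzzy solution does
    not clearly commit to any cluster.
    """
    labels = np.argmax(U.values, axis=1)
    straddlers = U.values.max(axis=1) < 1.0 / U.k + 0.05
    return labels, straddlers


def _simplex_grid(k: int, resolution: int) -> np.ndarray:
    """All points of the k-simplex with coordinates that are multiples of 1/resolution."""
    pts = []
    for comp in itertools.combinations_with_replacement(range(k), resolution):
        v = np.zeros(k)
        for c in comp:
            v[c] += 1.0 / resolution
        pts.append(v)
    return np.unique(np.array(pts), axis=0)


def brute_force_min(
    D: DissimilarityMatrix | np.ndarray,
    k: int,
    r: float,
    resolution: int = 4,
) -> tuple[float, np.ndarray]:
    """Exhaustive simplex-grid search plus local polish on a tiny instance.

    Enumerates every assignment of each object to a grid point of the
    membership simplex (spacing 1/resolution), evaluates the objective for
    all ``g**n`` combinations in vectorized chunks, then polishes the best
    grid point with a softmax-parameterized quasi-Newton minimization.
    Intended purely as a test oracle; limited to n <= 6 and k <= 3.
    """
    Dv = D.values if isinstance(D, DissimilarityMatrix) else np.asarray(D, float)
    n = Dv.shape[0]
    if n > 6 or k > 3:
        raise ValueError("brute_force_min is limited to n <= 6, k <= 3")
    D2 = Dv ** 2
    grid = _simplex_grid(k, resolution)
    g = len(grid)
    best_obj = np.inf
    best_idx: tuple[int, ...] | None = None
    chunk: list[tuple[int, ...]] = []

    def flush(chunk_idx: list[tuple[int, ...]]) -> None:
        nonlocal best_obj, best_idx
        if not chunk_idx:
            return
        idx = np.array(chunk_idx)
        U = grid[idx]  # (B, n, k)
        W = U ** r
        DW = np.einsum("ij,bjk->bik", D2, W)
        P = np.einsum("bik,bik->bk", W, DW)
        Q = np.maximum(W.sum(axis=1), 1e-300)
        objs = (P / Q).sum(axis=1)
        m = int(np.argmin(objs))
        if objs[m] < best_obj:
            best_obj = float(objs[m])
            best_idx = chunk_idx[m]

    for combo in itertools.product(range(g), repeat=n):
        chunk.append(combo)
        if len(chunk) >= 8192:
            flush(chunk)
            chunk = []
    flush(chunk)
    U0 = grid[list(best_idx)]

    def softmax(z: np.ndarray) -> np.ndarray:
        z = z.reshape(n, k)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def f(z: np.ndarray) -> float:
        return _objective_array(softmax(z), D2, r)

    z0 = np.log(np.clip(U0, 1e-6, None)).ravel()
    res = minimize(f, z0, method="Nelder-Mead",
                   options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12})
    U_best, obj = (softmax(res.x), float(res.fun)) if res.fun <= best_obj \
        else (U0, best_obj)
    return obj, U_best
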