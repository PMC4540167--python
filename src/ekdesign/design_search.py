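"""Design-search algorithms: rook-clique local search, simulated annealing
over the compound criterion J_alpha, Pareto-front sampling across an
alpha-grid, the simplified exchange algorithm, greedy sequential strategies,
and Latin-hypercube baseline constructors.

Both Pareto-based algorithms confine the expensive M_EK evaluation to designs
that are non-dominated for the two D-optimality surrogates; the exchange
algorithm can further restrict to the convex hull of the front.

The inner J_alpha evaluations (millions per simulated-annealing run at the
default Nmax) are JIT-compiled; a pure-numpy reference path remains through
`fisher_information.criterion_pair` and the generic `local_optimize`, and the
two routes are asserted equal in the test suite.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from numba import njit
from scipy.spatial.distance import cdist, pdist

from .ek_criteria import ek_variance_many, mek
from .fisher_information import corr_derivatives_from_distance, criterion_pair
from .gp_core import CandidateSet, Design, GPModel
from .pareto_tools import (
    DEFAULT_TOL,
    ParetoFront,
    distinct_points,
    nondominated_filter,
    upper_convex_hull,
)

logger = logging.getLogger("ekdesign")


# ---------------------------------------------------------------------------
# configuration and results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SAConfig:
    """Simulated-annealing schedule: initial temperature T0, geometric
    cooling factor r in (0,1), iteration cap Nmax, RNG seed."""

    T0: float = 0.6
    r: float = 0.93
    Nmax: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T0 <= 0 or not (0 < self.r < 1) or self.Nmax < 1:
            raise ValueError("need T0 > 0, 0 < r < 1, Nmax >= 1")


@dataclass
class SearchResult:
    """Best design found plus a reproducible account of the run."""

    best_design: Design
    best_value: float
    counters: dict = field(default_factory=dict)
    trace: list = field(default_factory=list)
    seed: int | None = None
    config: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# JIT kernels (index-based J_alpha on a precomputed candidate-set tableau)
# ---------------------------------------------------------------------------

@njit(fastmath=False)
def _pair_idx(idx, Cq, dCq, Fq, sigma2):
    """(log det M_beta, log det M_nu) of the design Cq[idx][:, idx]."""
    n = idx.shape[0]
    p = Fq.shape[1]
    s = dCq.shape[0]
    C = np.empty((n, n))
    for a in range(n):
        for b in range(n):
            C[a, b] = Cq[idx[a], idx[b]]
    # Cholesky C = L L'
    L = np.zeros((n, n))
    for i in range(n):
        acc = C[i, i]
        for k in range(i):
            acc -= L[i, k] * L[i, k]
        if acc <= 0.0:
            return -np.inf, -np.inf
        L[i, i] = np.sqrt(acc)
        for j in range(i + 1, n):
            acc = C[j, i]
            for k in range(i):
                acc -= L[j, k] * L[i, k]
            L[j, i] = acc / L[i, i]

    # G = F' C^-1 F
    F = np.empty((n, p))
    for a in range(n):
        for b in range(p):
            F[a, b] = Fq[idx[a], b]
    X = F.copy()
    for col in range(p):            # solve L L' X = F
        for i in range(n):
            acc = X[i, col]
            for k in range(i):
                acc -= L[i, k] * X[k, col]
            X[i, col] = acc / L[i, i]
        for i in range(n - 1, -1, -1):
            acc = X[i, col]
            for k in range(i + 1, n):
                acc -= L[k, i] * X[k, col]
            X[i, col] = acc / L[i, i]
    G = F.T @ X
    if p == 1:
        detG = G[0, 0]
    elif p == 2:
        detG = G[0, 0] * G[1, 1] - G[0, 1] * G[1, 0]
    else:
        detG = np.linalg.det(G)
    if detG <= 0.0:
        return -np.inf, -np.inf
    lb = np.log(detG) - p * np.log(sigma2)

    # S_k = C^-1 dC_k ; M_nu[k,l] = tr(S_k S_l)/2
    S = np.empty((s, n, n))
    for kpar in range(s):
        for a in range(n):
            for b in range(n):
                S[kpar, a, b] = dCq[kpar, idx[a], idx[b]]
        for col in range(n):
            for i in range(n):
                acc = S[kpar, i, col]
                for k in range(i):
                    acc -= L[i, k] * S[kpar, k, col]
                S[kpar, i, col] = acc / L[i, i]
            for i in range(n - 1, -1, -1):
                acc = S[kpar, i, col]
                for k in range(i + 1, n):
                    acc -= L[k, i] * S[kpar, k, col]
                S[kpar, i, col] = acc / L[i, i]
    Mnu = np.empty((s, s))
    for a in range(s):
        for b in range(a, s):
            acc = 0.0
            for i in range(n):
                for j in range(n):
                    acc += S[a, i, j] * S[b, j, i]
            Mnu[a, b] = 0.5 * acc
            Mnu[b, a] = Mnu[a, b]
    if s == 1:
        detM = Mnu[0, 0]
    elif s == 2:
        detM = Mnu[0, 0] * Mnu[1, 1] - Mnu[0, 1] * Mnu[1, 0]
    else:
        detM = np.linalg.det(Mnu)
    if detM <= 0.0:
        return lb, -np.inf
    return lb, np.log(detM)


@njit(fastmath=False)
def _pairs_batch(idx_mat, Cq, dCq, Fq, sigma2, out):
    for m in range(idx_mat.shape[0]):
        lb, ln = _pair_idx(idx_mat[m], Cq, dCq, Fq, sigma2)
        out[m, 0] = lb
        out[m, 1] = ln


@njit(fastmath=False)
def _j_idx(idx, Cq, dCq, Fq, sigma2, alpha):
    lb, ln = _pair_idx(idx, Cq, dCq, Fq, sigma2)
    return alpha * lb + (1.0 - alpha) * ln


@njit(fastmath=False)
def _local_opt_idx(idx, in_design, nbr, Cq, dCq, Fq, sigma2, alpha):
    """Rook-clique coordinate descent; mutates idx/in_design in place.
    Returns (J, number of objective evaluations)."""
    J = _j_idx(idx, Cq, dCq, Fq, sigma2, alpha)
    evals = 1
    improved = True
    while improved:
        improved = False
        for i in range(idx.shape[0]):
            for k in range(nbr.shape[1]):
                y = nbr[idx[i], k]
                if y < 0 or in_design[y]:
                    continue
                old = idx[i]
                idx[i] = y
                Jn = _j_idx(idx, Cq, dCq, Fq, sigma2, alpha)
                evals += 1
                if Jn > J:
                    in_design[old] = False
                    in_design[y] = True
                    J = Jn
                    improved = True
                else:
                    idx[i] = old
    return J, evals


class _Tableau:
    """Precomputed per-candidate-set quantities feeding the JIT kernels."""

    def __init__(self, cands: CandidateSet, model: GPModel):
        kernel = model.kernel
        D = kernel.distance_matrix(cands.points)
        self.Cq = kernel.correlation_from_distance(D)
        dCq = corr_derivatives_from_distance(D, kernel)
        for k in range(len(dCq)):
            np.fill_diagonal(dCq[k], 0.0)
        self.dCq = np.ascontiguousarray(dCq)
        self.Fq = np.ascontiguousarray(model.trend_matrix(cands.points))
        self.sigma2 = float(model.sigma2)

    def pair(self, idx: np.ndarray) -> tuple[float, float]:
        return _pair_idx(
            np.ascontiguousarray(idx, dtype=np.int64),
            self.Cq, self.dCq, self.Fq, self.sigma2,
        )

    def pairs(self, idx_mat: np.ndarray) -> np.ndarray:
        out = np.empty((len(idx_mat), 2))
        _pairs_batch(
            np.ascontiguousarray(idx_mat, dtype=np.int64),
            self.Cq, self.dCq, self.Fq, self.sigma2, out,
        )
        return out


# ---------------------------------------------------------------------------
# local search (generic, reference implementation)
# ---------------------------------------------------------------------------

def local_optimize(
    design: Design,
    objective: Callable[[Design], float],
    cands: CandidateSet,
) -> Design:
    """Greedy rook-clique improvement of an arbitrary objective (maximised).

    Scans design sites in order; each site is tentatively replaced by each of
    its rook neighbours not already in the design and any strict improvement
    is kept immediately.  Repeats until a full pass makes no improvement.
    """
    if cands.neighbors is None:
        raise ValueError("candidate set has no neighbourhood structure")
    idx = cands.index_of(design.sites)
    in_design = np.zeros(len(cands), dtype=bool)
    in_design[idx] = True
    best = objective(Design(cands.points[idx], tag=design.tag))
    improved = True
    while improved:
        improved = False
        for i in range(len(idx)):
            for y in cands.neighbors[idx[i]]:
                if y < 0 or in_design[y]:
                    continue
                old = idx[i]
                idx[i] = y
                val = objective(Design(cands.points[idx]))
                if val > best:
                    in_design[old] = False
                    in_design[y] = True
                    best = val
                    improved = True
                else:
                    idx[i] = old
    return Design(cands.points[idx], tag="optimized")


# ---------------------------------------------------------------------------
# simulated annealing over J_alpha
# ---------------------------------------------------------------------------

def sa_optimize(
    model: GPModel,
    cands: CandidateSet,
    n: int,
    alpha: float,
    config: SAConfig,
    init: Design | None = None,
    objective: Callable[[Design], float] | None = None,
) -> SearchResult:
    """Simulated annealing with embedded rook local search.

    Each iteration perturbs the current design by replacing two random sites
    with two uniform draws from the candidate set, locally optimises the
    candidate, tracks the best solution, applies Metropolis acceptance
    (worse moves accepted with probability exp(delta/T)), and cools
    geometrically (T <- r*T) whenever the state did not change.

    When ``objective`` is given it replaces J_alpha (generic, slower path);
    otherwise the JIT fast path is used.
    """
    if n >= len(cands):
        raise ValueError("design size must be smaller than the candidate set")
    if cands.neighbors is None:
        raise ValueError("candidate set has no neighbourhood structure")
    rng = np.random.default_rng(config.seed)
    fast = objective is None
    tab = _Tableau(cands, model) if fast else None
    nbr = cands.neighbors.astype(np.int64)
    Q = len(cands)
    if init is not None:
        idx = cands.index_of(init.sites)
    else:
        idx = rng.choice(Q, size=n, replace=False)
    idx = np.ascontiguousarray(idx, dtype=np.int64)
    j_evals = 0

    def local_opt(idx: np.ndarray) -> tuple[np.ndarray, float, int]:
        ind = np.zeros(Q, dtype=bool)
        ind[idx] = True
        if fast:
            J, ev = _local_opt_idx(
                idx, ind, nbr, tab.Cq, tab.dCq, tab.Fq, tab.sigma2, alpha
            )
            return idx, float(J), int(ev)
        d = local_optimize(Design(cands.points[idx]), objective, cands)
        out = cands.index_of(d.sites)
        return out, objective(d), 0

    if fast:
        lb, ln = tab.pair(idx)
        e_cur = alpha * lb + (1 - alpha) * ln
    else:
        e_cur = objective(Design(cands.points[idx]))
    j_evals += 1
    best_idx, best_e = idx.copy(), e_cur
    T = config.T0
    trace: list[tuple[int, float, bool]] = []
    for k in range(config.Nmax):
        # two-point replacement perturbation
        cand = idx.copy()
        pos = rng.choice(n, size=2, replace=False)
        keep = np.delete(cand, pos)
        pool = np.setdiff1d(np.arange(Q), keep, assume_unique=False)
        new = rng.choice(pool, size=2, replace=False)
        cand[pos] = new
        cand, e_new, ev = local_opt(np.ascontiguousarray(cand, dtype=np.int64))
        j_evals += ev
        if e_new > best_e:
            best_e, best_idx = e_new, cand.copy()
        accepted = e_new > e_cur or rng.random() < np.exp((e_new - e_cur) / T)
        if accepted:
            idx, e_cur = cand, e_new
        else:
            T *= config.r
        trace.append((k, e_new, accepted))
    return SearchResult(
        best_design=Design(cands.points[best_idx], tag="optimized"),
        best_value=float(best_e),
        counters={"iterations": config.Nmax, "j_evaluations": j_evals},
        trace=trace,
        seed=config.seed,
        config={"T0": config.T0, "r": config.r, "Nmax": config.Nmax, "alpha": alpha},
    )


def pareto_sample_sa(
    model: GPModel,
    cands: CandidateSet,
    n: int,
    alpha_grid: Sequence[float],
    config: SAConfig,
    init: Design | None = None,
    prediction_set: CandidateSet | np.ndarray | None = None,
    sigma2_known: bool = False,
    point_resolution: float = 1e-3,
) -> tuple[ParetoFront, SearchResult]:
    """Sample the Pareto front by maximising J_alpha per grid value, then pick
    the design minimising M_EK among the distinct non-dominated results.

    Distinct runs that converge to the same Pareto value scatter by the
    optimizer's terminal accuracy (~1e-4 on the log-det scale, orders of
    magnitude below the spacing of neighbouring front values), so criterion
    points are clustered at ``point_resolution`` before the expensive M_EK
    step: one evaluation per distinct Pareto value, matching the number of
    distinct values sampled from the front.
    """
    if not all(0.0 <= a <= 1.0 for a in alpha_grid):
        raise ValueError("alpha grid must lie in [0, 1]")
    pred = cands if prediction_set is None else prediction_set
    designs: dict[tuple, Design] = {}
    runs = []
    for i, alpha in enumerate(alpha_grid):
        cfg = replace(config, seed=(config.seed + 7919 * i) % 2**31)
        res = sa_optimize(model, cands, n, float(alpha), cfg, init=init)
        runs.append(res)
        designs.setdefault(res.best_design.key(cands), res.best_design)
    keys = list(designs)
    pairs = np.array([criterion_pair(designs[k], model) for k in keys])
    front = nondominated_filter(pairs, design_ids=np.arange(len(keys)))
    # cluster front points at the sampling resolution; the representative of
    # a cluster is its best balanced member (max c_beta + c_nu, then first)
    cells: dict[tuple, int] = {}
    for pos, i in enumerate(front.design_ids):
        cell = tuple(np.round(front.points[pos] / point_resolution).astype(int))
        if cell not in cells or (
            front.points[pos].sum()
            > pairs[cells[cell]].sum() + 1e-15
        ):
            cells[cell] = i
    rep_ids = sorted(cells.values())
    rep_designs = [designs[keys[i]] for i in rep_ids]
    values = [
        mek(d, model, pred, sigma2_known=sigma2_known).value for d in rep_designs
    ]
    ibest = int(np.argmin(values))
    selected = SearchResult(
        best_design=rep_designs[ibest],
        best_value=float(values[ibest]),
        counters={
            "ek_evaluations": len(rep_designs),
            "distinct_designs": len(keys),
            "distinct_pareto_points": len(cells),
            "j_evaluations": sum(r.counters["j_evaluations"] for r in runs),
        },
        seed=config.seed,
        config={
            "alpha_grid": list(map(float, alpha_grid)),
            "point_resolution": point_resolution,
        },
    )
    return front, selected


# ---------------------------------------------------------------------------
# simplified exchange algorithm
# ---------------------------------------------------------------------------

def exchange_search(
    design0: Design,
    model: GPModel,
    cands: CandidateSet,
    restrict: str = "front",
    prediction_set: CandidateSet | np.ndarray | None = None,
    sigma2_known: bool = False,
    tol: float = DEFAULT_TOL,
) -> SearchResult:
    """Iterative one-point exchange with EK evaluation confined to the
    non-dominated exchanges (``restrict="front"``) or to those on the convex
    hull of the Pareto front (``restrict="hull"``).

    Each scan enumerates all single-site exchanges — n*(Q-n) at the first
    scan, (n-1)*(Q-n) afterwards since re-exchanging the site swapped in at
    the previous scan would revisit already-enumerated designs — computes the
    two log-determinant criteria for every candidate, restricts, evaluates
    M_EK on the restricted designs only, and moves to the best candidate if
    it strictly improves; otherwise stops.  ``counters["iterations"]`` counts
    scans (including the final non-improving one) and
    ``counters["ek_evaluations"]`` every M_EK call including the initial one.
    """
    if restrict not in ("front", "hull"):
        raise ValueError("restrict must be 'front' or 'hull'")
    pred = cands if prediction_set is None else prediction_set
    tab = _Tableau(cands, model)
    Q = len(cands)
    n = len(design0)
    idx = np.ascontiguousarray(cands.index_of(design0.sites), dtype=np.int64)
    cur_val = mek(Design(cands.points[idx]), model, pred, sigma2_known).value
    ek_evals = 1
    scans = 0
    updates = 0
    trace = []
    last_in: int | None = None
    while True:
        in_design = np.zeros(Q, dtype=bool)
        in_design[idx] = True
        moves = [
            (i, q)
            for i in range(n)
            if i != last_in
            for q in range(Q)
            if not in_design[q]
        ]
        idx_mat = np.repeat(idx[None, :], len(moves), axis=0)
        for m, (i, q) in enumerate(moves):
            idx_mat[m, i] = q
        pairs = tab.pairs(idx_mat)
        front = nondominated_filter(pairs, design_ids=np.arange(len(moves)), tol=tol)
        n_front = len(front)
        if restrict == "hull":
            front = upper_convex_hull(front, tol=tol)
            sel = front.design_ids[front.hull_flags]
            n_hull_points = distinct_points(front.points[front.hull_flags], tol)
        else:
            sel = front.design_ids
            n_hull_points = None
        values = np.array(
            [
                mek(Design(cands.points[idx_mat[m]]), model, pred, sigma2_known).value
                for m in sel
            ]
        )
        ek_evals += len(sel)
        scans += 1
        m_best = sel[int(np.argmin(values))]
        trace.append(
            {
                "scan": scans,
                "n_exchanges": len(moves),
                "n_front": n_front,
                "n_front_points": distinct_points(front.points, tol),
                "n_hull_points": n_hull_points,
                "n_ek": len(sel),
                "best_candidate_mek": float(values.min()),
                "current_mek": cur_val,
            }
        )
        if values.min() >= cur_val:
            break
        i, q = moves[m_best]
        idx = idx_mat[m_best].copy()
        cur_val = float(values.min())
        last_in = i
        updates += 1
    return SearchResult(
        best_design=Design(cands.points[idx], tag="optimized"),
        best_value=cur_val,
        counters={
            "iterations": scans,
            "updates": updates,
            "ek_evaluations": ek_evals,
        },
        trace=trace,
        config={"restrict": restrict, "tol": tol, "sigma2_known": sigma2_known},
    )


# ---------------------------------------------------------------------------
# greedy sequential strategies
# ---------------------------------------------------------------------------

def greedy_augment(
    design0: Design,
    model: GPModel,
    cands: CandidateSet,
    strategy: str = "S1",
    k_max: int = 1,
    sigma2_known: bool = False,
) -> list[Design]:
    """Sequentially add the site maximising the kriging variance (S1) or the
    corrected kriging variance (S2), recomputing after each addition.
    Returns [xi_0, ..., xi_k_max]."""
    if strategy not in ("S1", "S2"):
        raise ValueError("strategy must be 'S1' or 'S2'")
    if k_max > len(cands) - len(design0):
        raise ValueError("k_max exceeds the available candidate sites")
    seq = [design0]
    cur = design0
    for _ in range(k_max):
        ek, rho2 = ek_variance_many(cands.points, cur, model, sigma2_known)
        score = rho2 if strategy == "S1" else ek
        taken = cands.index_of(cur.sites)
        score = score.copy()
        score[taken] = -np.inf
        nxt = cands.points[int(np.argmax(score))]
        cur = Design(np.vstack([cur.sites, nxt]), tag="optimized")
        seq.append(cur)
    return seq


# ---------------------------------------------------------------------------
# Latin-hypercube constructors
# ---------------------------------------------------------------------------

MAXIMIN_EXHAUSTIVE_CAP = 9


def maximin_lh(n: int, m_per_axis: int = 25) -> Design:
    """Exhaustively optimal 2-d Latin hypercube {(i, pi(i))/(n-1)}: maximin
    inter-point distance, ties broken by minimax distance to the m_per_axis
    grid, then by lexicographic permutation order.  Exact search over all n!
    permutations (n <= 9)."""
    if n > MAXIMIN_EXHAUSTIVE_CAP:
        raise ValueError(
            f"exhaustive search capped at n={MAXIMIN_EXHAUSTIVE_CAP}; "
            "use a heuristic search for larger designs"
        )
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.int64)
    # squared maximin distance in level units, vectorised over permutations
    best_min = np.full(len(perms), np.inf)
    for i in range(n):
        for j in range(i + 1, n):
            d2 = (i - j) ** 2 + (perms[:, i] - perms[:, j]) ** 2
            best_min = np.minimum(best_min, d2)
    top = np.flatnonzero(best_min == best_min.max())
    # minimax tie-break over the evaluation grid
    g = np.linspace(0, 1, m_per_axis)
    xx, yy = np.meshgrid(g, g, indexing="ij")
    grid = np.column_stack([xx.ravel(), yy.ravel()])
    lev = np.arange(n) / (n - 1)
    best = None
    for t in top:
        pts = np.column_stack([lev, lev[perms[t]]])
        dmax = cdist(grid, pts).min(axis=1).max()
        key = (dmax, tuple(perms[t]))
        if best is None or key < best[0]:
            best = (key, pts)
    return Design(best[1], tag="initial")


def perturbed_lh_sample(
    n: int, sd: float, seed: int | np.random.Generator
) -> Design:
    """Random Latin hypercube on levels i/(n-1), each coordinate perturbed by
    N(0, sd^2) and clamped to [0, 1]."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lev = np.arange(n) / (n - 1)
    pts = np.column_stack([lev, lev[rng.permutation(n)]])
    pts = np.clip(pts + rng.normal(0.0, sd, size=pts.shape), 0.0, 1.0)
    return Design(pts, tag="initial")
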