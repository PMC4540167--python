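"""Non-dominated filtering and the upper convex hull in the
(log det M_beta, log det M_nu) plane.

Both criteria are maximised.  A point p is dominated when some q is at least
as good in both coordinates and strictly better in one; exact ties in both
coordinates are mutually non-dominating and are all retained.  Because
symmetric candidate sets produce designs whose criterion values are equal in
exact arithmetic but differ at machine precision, comparisons use a small
absolute tolerance (two values within ``tol`` count as equal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: absolute tolerance under which two criterion values are treated as tied
DEFAULT_TOL = 1e-10


@dataclass
class ParetoFront:
    """A set of criterion points (c_beta, c_nu) with optional hull flags."""

    points: np.ndarray                      # (N, 2)
    design_ids: np.ndarray                  # (N,) int
    hull_flags: np.ndarray | None = None    # (N,) bool

    def __len__(self) -> int:
        return len(self.points)

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "c_beta": self.points[:, 0],
                "c_nu": self.points[:, 1],
                "on_hull": (
                    self.hull_flags
                    if self.hull_flags is not None
                    else np.zeros(len(self), dtype=bool)
                ),
                "design_id": self.design_ids,
            }
        )


def _quantise(points: np.ndarray, tol: float) -> np.ndarray:
    """Snap coordinates to a tol-grid so that exact-arithmetic ties collapse
    onto identical integer pairs."""
    return np.round(np.asarray(points, dtype=float) / tol).astype(np.int64)


def nondominated_mask(points: np.ndarray, tol: float = DEFAULT_TOL) -> np.ndarray:
    """Boolean mask of non-dominated points (maximisation, weak dominance with
    one strict inequality, ties kept).  O(N log N)."""
    P = np.atleast_2d(np.asarray(points, dtype=float))
    if P.shape[1] != 2:
        raise ValueError("criterion points must be 2-d")
    if not np.isfinite(P).all():
        raise ValueError("criterion points must be finite")
    Pq = _quantise(P, tol)
    uniq, inverse = np.unique(Pq, axis=0, return_inverse=True)
    # sweep unique points by a descending; a point survives iff its b exceeds
    # every b seen at strictly larger a, and no same-a point has larger b
    order = np.lexsort((-uniq[:, 1], -uniq[:, 0]))
    keep_u = np.zeros(len(uniq), dtype=bool)
    best_b_prev = -np.inf       # max b over strictly larger a
    i = 0
    su = uniq[order]
    while i < len(su):
        j = i
        a = su[i, 0]
        while j < len(su) and su[j, 0] == a:
            j += 1
        bmax = su[i, 1]          # b descending within the group
        for g, b in zip(order[i:j], su[i:j, 1]):
            # survives iff top of its column and strictly above everything
            # seen at larger a (same-a ties at bmax are mutually non-dominating)
            keep_u[g] = b == bmax and b > best_b_prev
        best_b_prev = max(best_b_prev, bmax)
        i = j
    return keep_u[inverse]


def nondominated_filter(
    points: np.ndarray,
    design_ids: np.ndarray | None = None,
    tol: float = DEFAULT_TOL,
) -> ParetoFront:
    """Retain the non-dominated points (criterion-space duplicates all kept)."""
    P = np.atleast_2d(np.asarray(points, dtype=float))
    if design_ids is None:
        design_ids = np.arange(len(P))
    mask = nondominated_mask(P, tol)
    return ParetoFront(points=P[mask], design_ids=np.asarray(design_ids)[mask])


def _upper_hull_of_unique(U: np.ndarray, include_collinear: bool) -> np.ndarray:
    """Indices of points of U on the upper-right (north-east) convex hull.
    U must be free of duplicates.  Monotone chain on points sorted by
    (c_beta, c_nu); both coordinate-wise maxima are always vertices."""
    order = np.lexsort((U[:, 1], U[:, 0]))
    S = U[order]
    chain: list[int] = []
    for k in range(len(S)):
        while len(chain) >= 2:
            o, a = S[chain[-2]], S[chain[-1]]
            cross = (a[0] - o[0]) * (S[k][1] - o[1]) - (a[1] - o[1]) * (S[k][0] - o[0])
            drop = cross > 0 if include_collinear else cross >= 0
            if drop:
                chain.pop()
            else:
                break
        chain.append(k)
    return order[np.asarray(chain, dtype=int)]


def upper_convex_hull(
    front: ParetoFront,
    tol: float = DEFAULT_TOL,
    include_collinear: bool = False,
) -> ParetoFront:
    """Flag the points of a non-dominated front lying on the upper convex hull
    (exactly the points attainable by maximising some J_alpha, alpha in (0,1),
    plus the two extremes).  Collinear interior points are excluded unless
    requested.  All criterion-space duplicates of a hull point are flagged."""
    P = front.points
    Pq = _quantise(P, tol)
    uniq, inverse = np.unique(Pq, axis=0, return_inverse=True)
    Uf = uniq.astype(float) * tol
    hull_u = set(_upper_hull_of_unique(Uf, include_collinear).tolist())
    flags = np.array([inv in hull_u for inv in inverse])
    return ParetoFront(points=P, design_ids=front.design_ids, hull_flags=flags)


def distinct_points(points: np.ndarray, tol: float = DEFAULT_TOL) -> int:
    """Number of distinct criterion points at the tie tolerance."""
    return len(np.unique(_quantise(np.atleast_2d(points), tol), axis=0))
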