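"""Gaussian-process primitives: covariance kernels, candidate sets, designs,
universal-kriging weights and field simulation.

The model is the universal-kriging (random field) model

    Y(x) = f(x)' beta + eps(x),    E[eps(x) eps(x')] = sigma2 * c(x, x'; nu),

with a low-order polynomial trend f, a stationary correlation kernel c with
parameter vector nu, and process variance sigma2.  All downstream design
criteria are built from the quantities computed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import gamma, kv

logger = logging.getLogger("ekdesign")

#: condition-number estimate above which diagonal jitter is added
CONDITION_LIMIT = 1e12
#: relative jitter added to an ill-conditioned correlation matrix
JITTER_SCALE = 1e-10


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovarianceKernel:
    """Stationary correlation kernel with optional geometric anisotropy.

    Parameters
    ----------
    family:
        ``"exponential"`` — c(h) = exp(-nu * h); parameter ``nu`` > 0 is an
        inverse range.
    ``"matern"`` — Matérn correlation with range ``phi`` > 0 and smoothness
        ``kappa`` > 0 (geoR parametrization):

            c(h) = (2**(kappa-1) * Gamma(kappa))**-1 * (h/phi)**kappa
                   * K_kappa(h/phi),

        where K is the modified Bessel function of the second kind.  For
        kappa = 5/2 the closed form (1 + u + u**2/3) exp(-u), u = h/phi, is
        used.
    anisotropy:
        optional (angle, ratio); coordinates are rotated by ``angle`` (radians)
        and the second rotated coordinate multiplied by ``ratio`` >= 1 before
        distances are taken (geoR ``coords.aniso`` convention).
    est_params:
        names of the correlation parameters treated as estimated (the nu vector
        of the design criteria).  Defaults: ("nu",) for exponential, ("phi",)
        for Matérn.
    """

    family: str
    params: dict = field(default_factory=dict)
    anisotropy: tuple[float, float] | None = None
    est_params: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.family not in ("exponential", "matern"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family == "exponential":
            if self.params.get("nu", 0.0) <= 0:
                raise ValueError("exponential kernel needs nu > 0")
        else:
            if self.params.get("phi", 0.0) <= 0:
                raise ValueError("matern kernel needs phi > 0")
            if self.params.get("kappa", 0.0) <= 0:
                raise ValueError("matern kernel needs kappa > 0")
        if self.anisotropy is not None and self.anisotropy[1] < 1:
            raise ValueError("anisotropy ratio must be >= 1")
        if self.est_params is None:
            default = ("nu",) if self.family == "exponential" else ("phi",)
            object.__setattr__(self, "est_params", default)
        for name in self.est_params:
            if name not in self.param_names:
                raise ValueError(f"unknown estimated parameter {name!r}")

    @property
    def param_names(self) -> tuple[str, ...]:
        return ("nu",) if self.family == "exponential" else ("phi", "kappa")

    @property
    def n_est(self) -> int:
        return len(self.est_params)

    def with_params(self, **updates: float) -> "CovarianceKernel":
        return replace(self, params={**self.params, **updates})

    # -- evaluation ---------------------------------------------------------

    def correlation_from_distance(self, h: np.ndarray) -> np.ndarray:
        """Correlation as a function of (already anisotropy-corrected)
        Euclidean distance h >= 0."""
        h = np.asarray(h, dtype=float)
        if self.family == "exponential":
            return np.exp(-self.params["nu"] * h)
        phi, kappa = self.params["phi"], self.params["kappa"]
        u = h / phi
        if abs(kappa - 2.5) < 1e-12:
            return (1.0 + u + u * u / 3.0) * np.exp(-u)
        return _matern_bessel(u, kappa)

    def __call__(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Correlation between two points (or point arrays)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        y = np.atleast_2d(np.asarray(y, dtype=float))
        if x.shape[-1] != y.shape[-1]:
            raise ValueError("points must share a dimension")
        d = np.linalg.norm(
            self.transform_coords(x) - self.transform_coords(y), axis=-1
        )
        out = self.correlation_from_distance(d)
        return out if out.size > 1 else out.item()

    def transform_coords(self, x: np.ndarray) -> np.ndarray:
        if self.anisotropy is None:
            return np.asarray(x, dtype=float)
        angle, ratio = self.anisotropy
        return anisotropy_transform(x, angle, ratio)

    def distance_matrix(self, a: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
        ta = self.transform_coords(np.atleast_2d(a))
        tb = ta if b is None else self.transform_coords(np.atleast_2d(b))
        return cdist(ta, tb)


def _matern_bessel(u: np.ndarray, kappa: float) -> np.ndarray:
    """General Matérn correlation (2**(k-1) Gamma(k))^-1 u**k K_k(u)."""
    u = np.asarray(u, dtype=float)
    out = np.ones_like(u)
    pos = u > 0
    up = u[pos]
    out[pos] = up**kappa * kv(kappa, up) / (2 ** (kappa - 1) * gamma(kappa))
    return out


def kernel_correlation(x: np.ndarray, y: np.ndarray, kernel: CovarianceKernel) -> float:
    """Correlation c(x, y; nu) between two sites."""
    return float(np.asarray(kernel(x, y)))


def anisotropy_transform(x: np.ndarray, angle: float, ratio: float) -> np.ndarray:
    """Rotate 2-d coordinates by ``angle`` and stretch the second rotated
    coordinate by ``ratio``; identity for angle=0, ratio=1."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != 2:
        raise ValueError("anisotropy is only supported in dimension 2")
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, s], [-s, c]])
    out = x @ rot.T
    out[..., 1] *= ratio
    return out


# ---------------------------------------------------------------------------
# candidate sets and designs
# ---------------------------------------------------------------------------

@dataclass
class CandidateSet:
    """Finite design space: Q candidate sites, optionally a regular grid with
    rook (N/S/E/W) neighbour cliques and an admissibility mask."""

    points: np.ndarray                      # (Q, d)
    neighbors: np.ndarray | None = None     # (Q, 2d) int, -1 padded
    grid_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if not np.isfinite(self.points).all():
            raise ValueError("candidate coordinates must be finite")
        uniq = np.unique(self.points, axis=0)
        if len(uniq) != len(self.points):
            raise ValueError("candidate sites must be distinct")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def dim(self) -> int:
        return self.points.shape[1]

    def index_of(self, sites: np.ndarray) -> np.ndarray:
        """Row indices of ``sites`` within the candidate set."""
        sites = np.atleast_2d(np.asarray(sites, dtype=float))
        d = cdist(sites, self.points)
        idx = d.argmin(axis=1)
        if (d[np.arange(len(sites)), idx] > 1e-9).any():
            raise KeyError("site not found in candidate set")
        return idx

    @classmethod
    def grid(
        cls,
        m: int,
        lo: float = 0.0,
        hi: float = 1.0,
        mask: Callable[[np.ndarray], np.ndarray] | np.ndarray | None = None,
    ) -> "CandidateSet":
        """Closed regular m x m grid {lo + i*(hi-lo)/(m-1)}^2 with rook
        neighbourhoods.  ``mask`` (boolean per site, or predicate on the
        (m*m, 2) coordinates) removes inadmissible sites."""
        g = np.linspace(lo, hi, m)
        xx, yy = np.meshgrid(g, g, indexing="ij")
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        keep = np.ones(len(pts), dtype=bool)
        if mask is not None:
            keep = np.asarray(mask(pts) if callable(mask) else mask, dtype=bool)
        # rook neighbour table on the masked grid
        full_index = -np.ones(m * m, dtype=np.int64)
        full_index[np.flatnonzero(keep)] = np.arange(int(keep.sum()))
        nbr = -np.ones((int(keep.sum()), 4), dtype=np.int64)
        for q in np.flatnonzero(keep):
            i, j = divmod(q, m)
            k = 0
            for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                ii, jj = i + di, j + dj
                if 0 <= ii < m and 0 <= jj < m and full_index[ii * m + jj] >= 0:
                    nbr[full_index[q], k] = full_index[ii * m + jj]
                    k += 1
        return cls(points=pts[keep], neighbors=nbr, grid_shape=(m, m))


@dataclass
class Design:
    """Ordered set of n distinct sites."""

    sites: np.ndarray                     # (n, d)
    tag: str = "initial"

    def __post_init__(self) -> None:
        self.sites = np.atleast_2d(np.asarray(self.sites, dtype=float))
        if len(self.sites) < 2:
            raise ValueError("a design needs at least 2 sites")
        if len(np.unique(self.sites, axis=0)) != len(self.sites):
            raise ValueError("design sites must be distinct (no replications)")

    def __len__(self) -> int:
        return len(self.sites)

    def replace_site(self, i: int, site: np.ndarray, tag: str = "perturbed") -> "Design":
        s = self.sites.copy()
        s[i] = site
        return Design(s, tag=tag)

    def key(self, cands: CandidateSet) -> tuple:
        """Order-free identity of the design within a candidate set."""
        return tuple(sorted(cands.index_of(self.sites).tolist()))


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def trend_basis(name: str) -> Callable[[np.ndarray], np.ndarray]:
    """Trend basis f: sites (N, d) -> (N, p).  'constant' or 'linear'."""
    if name == "constant":
        return lambda X: np.ones((np.atleast_2d(X).shape[0], 1))
    if name == "linear":
        def f(X: np.ndarray) -> np.ndarray:
            X = np.atleast_2d(np.asarray(X, dtype=float))
            return np.column_stack([np.ones(len(X)), X])
        return f
    raise ValueError(f"unknown trend {name!r} (use 'constant' or 'linear')")


@dataclass
class GPModel:
    """Trend + correlation kernel + process variance."""

    kernel: CovarianceKernel
    sigma2: float = 1.0
    trend: str = "constant"

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")

    def trend_matrix(self, X: np.ndarray) -> np.ndarray:
        return trend_basis(self.trend)(X)

    @property
    def n_est(self) -> int:
        return self.kernel.n_est


# ---------------------------------------------------------------------------
# correlation matrices and kriging
# ---------------------------------------------------------------------------

def correlation_matrix(design: Design | np.ndarray, kernel: CovarianceKernel) -> np.ndarray:
    """n x n correlation matrix of the design sites; adds a logged diagonal
    jitter when the condition estimate exceeds CONDITION_LIMIT."""
    X = design.sites if isinstance(design, Design) else np.atleast_2d(design)
    if len(np.unique(X, axis=0)) != len(X):
        raise ValueError("duplicate sites give a singular correlation matrix")
    D = kernel.distance_matrix(X)
    C = kernel.correlation_from_distance(D)
    cond = np.linalg.cond(C)
    if cond > CONDITION_LIMIT:
        jitter = JITTER_SCALE * float(np.mean(np.diag(C)))
        logger.warning(
            "correlation matrix condition %.3g > %.1g; adding jitter %.3g "
            "(smallest eigenvalue %.3g)",
            cond, CONDITION_LIMIT, jitter, np.linalg.eigvalsh(C)[0],
        )
        C = C + jitter * np.eye(len(C))
    return C


def _kriging_system(design: Design, model: GPModel):
    """Shared factorised pieces: C, A=C^-1, F, G=F'AF, G^-1."""
    X = design.sites
    C = correlation_matrix(design, model.kernel)
    A = np.linalg.inv(C)
    F = model.trend_matrix(X)
    G = F.T @ A @ F
    if np.linalg.matrix_rank(G) < G.shape[0]:
        raise np.linalg.LinAlgError(
            "trend basis is not identifiable on this design (rank-deficient F'C^-1F)"
        )
    return C, A, F, G, np.linalg.inv(G)


def kriging_weights_many(
    Xpred: np.ndarray, design: Design, model: GPModel
) -> tuple[np.ndarray, np.ndarray]:
    """Universal-kriging weights and normalized variance, vectorised.

    Returns (W, rho2) with W of shape (N, n) (one weight row per prediction
    site) and rho2 of shape (N,):

        w(x)    = A b + A F G^-1 h(x),      h(x) = f(x) - F' A b(x)
        rho2(x) = 1 - b' A b + h' G^-1 h,

    where A = C^-1, b(x) the cross-correlation vector, G = F' A F.
    """
    Xpred = np.atleast_2d(np.asarray(Xpred, dtype=float))
    C, A, F, G, Gi = _kriging_system(design, model)
    B = model.kernel.correlation_from_distance(
        model.kernel.distance_matrix(Xpred, design.sites)
    )                                       # (N, n)
    fX = model.trend_matrix(Xpred)          # (N, p)
    AB = B @ A                              # (N, n)
    H = fX - AB @ F                         # (N, p)
    W = AB + H @ Gi @ (A @ F).T
    rho2 = 1.0 - np.einsum("ij,ij->i", B, AB) + np.einsum("ij,ij->i", H @ Gi, H)
    return W, np.maximum(rho2, 0.0)


def kriging_weights(
    x: np.ndarray, design: Design, model: GPModel
) -> tuple[np.ndarray, float]:
    """Kriging weight vector w and normalized variance rho2 at one site."""
    W, rho2 = kriging_weights_many(np.atleast_2d(x), design, model)
    return W[0], float(rho2[0])


def simulate_field(
    cands: CandidateSet,
    model: GPModel,
    n_real: int,
    seed: int | np.random.Generator,
    beta: Sequence[float] | None = None,
) -> np.ndarray:
    """Draw ``n_real`` realisations of the field over the candidate sites.

    Returns an (n_real, Q) array of f(x)'beta + eps(x) with covariance
    sigma2 * C; beta defaults to zero.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = cands.points
    D = model.kernel.distance_matrix(X)
    C = model.kernel.correlation_from_distance(D)
    try:
        L = np.linalg.cholesky(model.sigma2 * C + 1e-12 * np.eye(len(X)))
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "model covariance is not positive definite on the candidate set"
        ) from err
    Z = rng.standard_normal((n_real, len(X)))
    fields = Z @ L.T
    if beta is not None:
        fields = fields + model.trend_matrix(X) @ np.asarray(beta, dtype=float)
    return fields
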