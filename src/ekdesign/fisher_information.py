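"""Fisher information for the universal-kriging model and the compound
D-optimality surrogate J_alpha.

For theta = (sigma2, nu) the information matrix of a design xi splits into a
trend block and a covariance block.  With A = C^-1 and S_k = A dC/dnu_k:

    M_beta = (1/sigma2) F' A F                       (p x p)
    M_nu[k, l] = tr(S_k S_l) / 2                     (s x s)
    t[k] = tr(S_k)

The asymptotic covariance of the estimator of nu is the corresponding block
of the inverse full information matrix,

    V_nu = (M_nu - t t' / (2 n))^-1,

which is free of sigma2; when sigma2 is treated as known it reduces to
M_nu^-1.  The surrogate criterion is the convex combination

    J_alpha(xi) = alpha * log det M_beta + (1 - alpha) * log det M_nu,

whose maximisers trace the convex hull of the attainable criterion set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .gp_core import CovarianceKernel, Design, GPModel, _kriging_system

logger = logging.getLogger("ekdesign")

#: relative central-difference step for parameters without analytic derivative
FD_REL_STEP = 1e-5
FD_ABS_FLOOR = 1e-8

NEG_INF = float("-inf")


# ---------------------------------------------------------------------------
# kernel derivatives
# ---------------------------------------------------------------------------

def _corr_derivative_from_distance(
    D: np.ndarray, kernel: CovarianceKernel, name: str
) -> np.ndarray | None:
    """Analytic d c(h)/d param on a distance matrix, or None if unavailable."""
    if kernel.family == "exponential" and name == "nu":
        nu = kernel.params["nu"]
        return -D * np.exp(-nu * D)
    if (
        kernel.family == "matern"
        and name == "phi"
        and abs(kernel.params["kappa"] - 2.5) < 1e-12
    ):
        phi = kernel.params["phi"]
        u = D / phi
        # d/dphi [(1 + u + u^2/3) e^-u] = u^2 (1 + u) e^-u / (3 phi)
        return u * u * (1.0 + u) * np.exp(-u) / (3.0 * phi)
    return None


def _fd_corr_derivative(D: np.ndarray, kernel: CovarianceKernel, name: str) -> np.ndarray:
    v = kernel.params[name]
    step = max(FD_REL_STEP * abs(v), FD_ABS_FLOOR)
    if v - step <= 0:       # keep the stencil inside the parameter domain
        step = v / 2.0
        logger.debug("FD step shrunk to %.3g for parameter %s", step, name)
    hi = kernel.with_params(**{name: v + step})
    lo = kernel.with_params(**{name: v - step})
    return (hi.correlation_from_distance(D) - lo.correlation_from_distance(D)) / (2 * step)


def corr_derivatives_from_distance(
    D: np.ndarray, kernel: CovarianceKernel
) -> np.ndarray:
    """Stack of d c / d nu_k over the estimated parameters, shape (s, *D.shape)."""
    out = []
    for name in kernel.est_params:
        dC = _corr_derivative_from_distance(D, kernel, name)
        if dC is None:
            dC = _fd_corr_derivative(D, kernel, name)
        out.append(dC)
    return np.stack(out)


def kernel_derivatives(design: Design | np.ndarray, kernel: CovarianceKernel) -> np.ndarray:
    """Derivative matrices dC/dnu_k on a design, shape (s, n, n); the diagonal
    is exactly zero since c(x, x) = 1 for every parameter value."""
    X = design.sites if isinstance(design, Design) else np.atleast_2d(design)
    D = kernel.distance_matrix(X)
    dC = corr_derivatives_from_distance(D, kernel)
    for k in range(len(dC)):
        np.fill_diagonal(dC[k], 0.0)
    return dC


# ---------------------------------------------------------------------------
# information bundle
# ---------------------------------------------------------------------------

@dataclass
class InformationBundle:
    """Trend and covariance-parameter information of one design."""

    M_beta: np.ndarray
    M_nu: np.ndarray
    t: np.ndarray
    V_nu: np.ndarray
    log_det_beta: float
    log_det_nu: float
    sigma2_known: bool

    def to_json(self) -> str:
        return json.dumps(
            {
                "M_beta": self.M_beta.tolist(),
                "M_nu": self.M_nu.tolist(),
                "t": self.t.tolist(),
                "V_nu": self.V_nu.tolist(),
                "log_det_beta": self.log_det_beta,
                "log_det_nu": self.log_det_nu,
                "sigma2_known": self.sigma2_known,
            }
        )


def _logdet(M: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(M)
    return ld if sign > 0 else NEG_INF


def information_bundle(
    design: Design, model: GPModel, sigma2_known: bool = False
) -> InformationBundle:
    """Compute M_beta, M_nu, t and V_nu for a design."""
    C, A, F, G, _ = _kriging_system(design, model)
    n = len(design)
    M_beta = G / model.sigma2
    dC = kernel_derivatives(design, model.kernel)
    S = np.array([A @ dC[k] for k in range(len(dC))])          # (s, n, n)
    s = len(S)
    M_nu = 0.5 * np.einsum("aij,bji->ab", S, S)
    t = np.einsum("aii->a", S)
    target = M_nu if sigma2_known else M_nu - np.outer(t, t) / (2.0 * n)
    try:
        V_nu = np.linalg.inv(target)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"covariance-parameter information is singular for this design "
            f"(n={n}, s={s}); the design cannot identify nu"
        ) from err
    return InformationBundle(
        M_beta=M_beta,
        M_nu=M_nu,
        t=t,
        V_nu=V_nu,
        log_det_beta=_logdet(M_beta),
        log_det_nu=_logdet(M_nu),
        sigma2_known=sigma2_known,
    )


def criterion_pair(design: Design, model: GPModel) -> tuple[float, float]:
    """(log det M_beta, log det M_nu) — the two D-optimality coordinates.

    Computed without inverting the covariance-parameter block, so it stays
    defined for designs whose V_nu does not exist (e.g. very small n).
    """
    _, A, _, G, _ = _kriging_system(design, model)
    dC = kernel_derivatives(design, model.kernel)
    S = np.array([A @ dC[k] for k in range(len(dC))])
    M_nu = 0.5 * np.einsum("aij,bji->ab", S, S)
    return _logdet(G / model.sigma2), _logdet(M_nu)


def j_alpha(design: Design, model: GPModel, alpha: float) -> float:
    """Compound criterion alpha*logdet M_beta + (1-alpha)*logdet M_nu.

    Any strictly monotone combination yields Pareto-front points; the
    unnormalized log-determinant form is used (immaterial when p = s = 1).
    Returns -inf (logged) for designs with singular information.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    lb, ln = criterion_pair(design, model)
    if lb == NEG_INF or ln == NEG_INF:
        logger.warning("singular information in j_alpha; returning -inf")
        return NEG_INF
    return alpha * lb + (1.0 - alpha) * ln
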