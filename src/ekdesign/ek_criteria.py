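"""The corrected (empirical-kriging) prediction variance and the M_EK design
criterion.

The plug-in kriging predictor uses an estimated covariance-parameter vector
nu; to first order, the extra prediction uncertainty caused by that estimation
adds a non-negative term to the normalized kriging variance:

    ek(x) = sigma2 * [ rho2(x) + tr( V_nu W(x) ) ],
    W(x)[k, l] = (dw/dnu_k)' C (dw/dnu_l),

with V_nu the asymptotic covariance of the estimator of nu and w(x) the
universal-kriging weight vector.  The design criterion is the maximum of
ek(x) over a finite prediction set; EK-optimal designs minimise it and are
typically not space-filling for small n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .fisher_information import corr_derivatives_from_distance, information_bundle
from .gp_core import CandidateSet, Design, GPModel, _kriging_system

logger = logging.getLogger("ekdesign")


@dataclass
class EKEvaluation:
    """Result of maximising the corrected variance over a prediction set."""

    value: float
    argmax_site: np.ndarray
    argmax_index: int
    per_site: np.ndarray | None = None   # columns: rho2, correction, total


def weight_derivatives(
    Xpred: np.ndarray, design: Design, model: GPModel
) -> np.ndarray:
    """Derivatives of the kriging weight vector w(x) w.r.t. each estimated
    covariance parameter, shape (s, N, n).

    Obtained by implicit differentiation of the closed-form universal-kriging
    weights; satisfies (dw/dnu_k)' F = 0 (differentiated unbiasedness).
    """
    Xpred = np.atleast_2d(np.asarray(Xpred, dtype=float))
    kernel = model.kernel
    C, A, F, G, Gi = _kriging_system(design, model)
    Ddes = kernel.distance_matrix(design.sites)
    Dx = kernel.distance_matrix(Xpred, design.sites)
    B = kernel.correlation_from_distance(Dx)                   # (N, n)
    dCs = corr_derivatives_from_distance(Ddes, kernel)         # (s, n, n)
    for k in range(len(dCs)):
        np.fill_diagonal(dCs[k], 0.0)
    dBs = corr_derivatives_from_distance(Dx, kernel)           # (s, N, n)

    fX = model.trend_matrix(Xpred)
    AF = A @ F
    H = fX - B @ AF                                            # (N, p)
    out = np.empty((len(dCs), len(Xpred), len(design)))
    for k, (dC, dB) in enumerate(zip(dCs, dBs)):
        dA = -A @ dC @ A
        dAF = dA @ F
        dG = F.T @ dAF
        dGi = -Gi @ dG @ Gi
        dH = -(dB @ AF + B @ dAF)
        out[k] = (
            dB @ A
            + B @ dA
            + dH @ Gi @ AF.T
            + H @ dGi @ AF.T
            + H @ Gi @ dAF.T
        )
    return out


def ek_variance_many(
    Xpred: np.ndarray,
    design: Design,
    model: GPModel,
    sigma2_known: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Corrected kriging variance at each prediction site.

    Returns (ek, rho2), both length-N arrays; ek = sigma2*(rho2 + correction)
    with correction = tr(V_nu W(x)) >= 0.
    """
    Xpred = np.atleast_2d(np.asarray(Xpred, dtype=float))
    C, A, F, G, Gi = _kriging_system(design, model)
    B = model.kernel.correlation_from_distance(
        model.kernel.distance_matrix(Xpred, design.sites)
    )
    fX = model.trend_matrix(Xpred)
    AB = B @ A
    H = fX - AB @ F
    rho2 = 1.0 - np.einsum("ij,ij->i", B, AB) + np.einsum("ij,ij->i", H @ Gi, H)
    rho2 = np.maximum(rho2, 0.0)

    bundle = information_bundle(design, model, sigma2_known=sigma2_known)
    dW = weight_derivatives(Xpred, design, model)              # (s, N, n)
    # W(x)[k,l] = dW_k C dW_l' per site; contract with V_nu
    CdW = np.einsum("ij,snj->sni", C, dW)
    Wmat = np.einsum("kni,lni->nkl", dW, CdW)
    correction = np.einsum("kl,nkl->n", bundle.V_nu, Wmat)
    correction = np.maximum(correction, 0.0)
    return model.sigma2 * (rho2 + correction), rho2


def ek_variance(
    x: np.ndarray, design: Design, model: GPModel, sigma2_known: bool = False
) -> float:
    """Corrected kriging variance at a single site."""
    ek, _ = ek_variance_many(np.atleast_2d(x), design, model, sigma2_known)
    return float(ek[0])


def mek(
    design: Design,
    model: GPModel,
    prediction_set: CandidateSet | np.ndarray,
    sigma2_known: bool = False,
    per_site: bool = False,
) -> EKEvaluation:
    """M_EK(xi): maximum corrected kriging variance over the prediction set.

    Deterministic; ties in the maximum are broken by the first site in the
    prediction-set row order.
    """
    pts = (
        prediction_set.points
        if isinstance(prediction_set, CandidateSet)
        else np.atleast_2d(np.asarray(prediction_set, dtype=float))
    )
    if len(pts) == 0:
        raise ValueError("prediction set is empty")
    ek, rho2 = ek_variance_many(pts, design, model, sigma2_known)
    i = int(np.argmax(ek))
    table = None
    if per_site:
        table = np.column_stack([rho2, ek / model.sigma2 - rho2, ek])
    return EKEvaluation(
        value=float(ek[i]), argmax_site=pts[i], argmax_index=i, per_site=table
    )


def ek_efficiency(
    design_a: Design,
    design_b: Design,
    model: GPModel,
    prediction_set: CandidateSet | np.ndarray,
    sigma2_known: bool = False,
) -> float:
    """M_EK(b) / M_EK(a): the EK efficiency of design a relative to the
    reference b (<= 1 when b is the optimum, for this minimisation problem)."""
    va = mek(design_a, model, prediction_set, sigma2_known).value
    vb = mek(design_b, model, prediction_set, sigma2_known).value
    return vb / va
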