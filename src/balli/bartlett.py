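"""Bartlett correction of the per-gene likelihood-ratio statistic.

The uncorrected statistic LR = -2 (l_null - l_alt) is referred to
chi-square with df = M - 1 (the number of tested columns); its null
distribution is biased to order 1/N in small samples.  The corrected
statistic divides by 1 + C/df, where the constant C is built from five
trace functionals of the null-fit covariance V, the nuisance design Z and
the tested design X:

    X'    = [I - Z (Z'V^-1 Z)^-1 Z'V^-1] X          (V^-1-projected X)
    Xdot' = Z (Z'V^-1 Z)^-1 Z' V^-2 X'
    D   = -1/2 tr(V^-2)
    M   = 2 tr( (X'V^-1X')^-1 (X'V^-3X' - Xdot''V^-2X') )
    P   = tr( (X'V^-2X' (X'V^-1X')^-1)^2 )
    nu  = -tr( (Z'V^-1Z)^-1 Z'V^-2Z )
    tau = -tr( (X'V^-1X')^-1 X'V^-2X' )
    C   = D^-1 (-M/2 + P/4 - nu tau / 2)

Only the diagonal V of the final model is supported, so every product with
a power of V is a column scaling and each gene costs O(N p^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .lmm import GeneFit, VarianceModel

__all__ = [
    "TestResult",
    "BartlettComponents",
    "likelihood_ratio",
    "bartlett_components",
    "bartlett_components_batch",
    "bartlett_constant",
    "balli_pvalues",
]

_LR_NEG_TOL = 1e-8


@dataclass
class BartlettComponents:
    D: float
    Mcomp: float
    P: float
    nu: float
    tau: float
    X_prime: np.ndarray
    X_dot_prime: np.ndarray


@dataclass
class TestResult:
    lr: float
    C: float
    lr_star: float
    df: int
    p_lli: float
    p_balli: float


def likelihood_ratio(fit_null: GeneFit, fit_alt: GeneFit) -> float:
    """LR = -2 (loglik_null - loglik_alt); tiny negatives are clamped to 0."""
    lr = -2.0 * (fit_null.loglik - fit_alt.loglik)
    if lr < 0.0:
        if lr < -_LR_NEG_TOL:
            raise ValueError(
                f"negative likelihood ratio {lr}: alternative fit is not "
                "at least as good as the null; optimizer failure upstream"
            )
        lr = 0.0
    return float(lr)


def bartlett_components_batch(
    v_diag: np.ndarray, Z: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """The five scalar components for G genes at once.

    v_diag is (G, N): the diagonal of each gene's null-fit covariance.
    Returns arrays (D, M, P, nu, tau), each of length G.
    """
    v = np.atleast_2d(np.asarray(v_diag, dtype=float))
    if np.any(v <= 0):
        raise ValueError("V must be positive definite")
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    w1 = 1.0 / v          # V^-1 diagonal
    w2 = w1 * w1
    w3 = w2 * w1

    ZtV1Z = np.einsum("gn,nq,nr->gqr", w1, Z, Z)
    ZtV1Z_inv = np.linalg.inv(ZtV1Z)
    ZtV1X = np.einsum("gn,nq,nk->gqk", w1, Z, X)
    B = ZtV1Z_inv @ ZtV1X
    Xp = X[None, :, :] - np.einsum("nq,gqk->gnk", Z, B)

    ZtV2Xp = np.einsum("gn,nq,gnk->gqk", w2, Z, Xp)
    Xdot = np.einsum("nq,gqk->gnk", Z, ZtV1Z_inv @ ZtV2Xp)

    S1 = np.einsum("gn,gnk,gnl->gkl", w1, Xp, Xp)  # X'' V^-1 X'
    S2 = np.einsum("gn,gnk,gnl->gkl", w2, Xp, Xp)  # X'' V^-2 X'
    S3 = np.einsum("gn,gnk,gnl->gkl", w3, Xp, Xp)  # X'' V^-3 X'
    Sdot = np.einsum("gn,gnk,gnl->gkl", w2, Xdot, Xp)  # Xdot'' V^-2 X'
    S1_inv = np.linalg.inv(S1)

    D = -0.5 * w2.sum(axis=1)
    Mc = 2.0 * np.einsum("gkl,glk->g", S1_inv, S3 - Sdot)
    T = S2 @ S1_inv
    P = np.einsum("gkl,glk->g", T, T)
    nu = -np.einsum("gqr,grq->g", ZtV1Z_inv, np.einsum("gn,nq,nr->gqr", w2, Z, Z))
    tau = -np.einsum("gkl,glk->g", S1_inv, S2)
    return D, Mc, P, nu, tau


def bartlett_components(
    vm: VarianceModel, Z: np.ndarray, X: np.ndarray
) -> BartlettComponents:
    """Components for a single gene, evaluated at its null-fit variance."""
    v = vm.V_diag[None, :]
    D, Mc, P, nu, tau = bartlett_components_batch(v, Z, X)
    w1 = 1.0 / vm.V_diag
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ZtV1Z_inv = np.linalg.inv((Z * w1[:, None]).T @ Z)
    Xp = X - Z @ ZtV1Z_inv @ ((Z * w1[:, None]).T @ X)
    Xdot = Z @ ZtV1Z_inv @ ((Z * (w1**2)[:, None]).T @ Xp)
    return BartlettComponents(
        D=float(D[0]), Mcomp=float(Mc[0]), P=float(P[0]),
        nu=float(nu[0]), tau=float(tau[0]), X_prime=Xp, X_dot_prime=Xdot,
    )


def bartlett_constant(bc: BartlettComponents) -> float:
    """C = D^-1 (-M/2 + P/4 - nu tau / 2)."""
    if bc.D == 0:
        raise ValueError("component D must be nonzero")
    return float((-0.5 * bc.Mcomp + 0.25 * bc.P - 0.5 * bc.nu * bc.tau) / bc.D)


def balli_pvalues(lr: float, C: float, df: int) -> TestResult:
    """Corrected and uncorrected chi-square p-values for one gene."""
    if lr < 0:
        raise ValueError("lr must be non-negative")
    if df < 1:
        raise ValueError("df must be at least 1")
    denom = 1.0 + C / df
    if denom <= 0:
        raise ValueError(f"pathological Bartlett correction: 1 + C/df = {denom}")
    lr_star = lr / denom
    return TestResult(
        lr=float(lr),
        C=float(C),
        lr_star=float(lr_star),
        df=int(df),
        p_lli=float(chi2.sf(lr, df)),
        p_balli=float(chi2.sf(lr_star, df)),
    )
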