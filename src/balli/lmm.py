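"""Per-gene linear mixed model with a diagonal variance decomposition.

The model for one gene's log-cpm vector Y (length N) is

    Y = Z a + X b + e',   e' ~ MVN(0, V),   V = diag(1/mu_hat) + sigma2 * I,

where diag(1/mu_hat) is the fixed technical (counting) variance and sigma2
>= 0 is the free biological variance.  Estimation maximizes the profile
log-likelihood of sigma2 (mean coefficients profiled out by GLS),

    l_P(sigma2) = -1/2 log|V| - 1/2 Y' P Y,
    P = V^-1 - V^-1 W (W' V^-1 W)^-1 W' V^-1,

with W the design under the hypothesis at hand ((Z, X) or Z alone).  The
additive constant -(N/2) log(2 pi) is dropped identically under both
hypotheses, so log-likelihood differences are exact.

Fisher scoring on sigma2 uses the analytic score and expected information
for a variance component with dV/dsigma2 = I:

    U = -1/2 sum(1/V_i) + 1/2 ||P Y||^2,    I_E = 1/2 sum(1/V_i^2),

and falls back to bounded derivative-free (Brent) maximization when scoring
leaves the feasible range or fails to settle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "VarianceModel",
    "GeneFit",
    "profile_loglik",
    "fit_sigma2",
    "fit_sigma2_batch",
    "gls_coefficients",
]

_SCORING_TOL = 1e-8
_MAX_SCORING_ITER = 50


@dataclass
class VarianceModel:
    """Diagonal variance V = diag(sigma_b_diag) + sigma2 * I for one gene."""

    sigma_b_diag: np.ndarray
    sigma2: float

    def __post_init__(self) -> None:
        self.sigma_b_diag = np.asarray(self.sigma_b_diag, dtype=float)
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")

    @property
    def V_diag(self) -> np.ndarray:
        return self.sigma_b_diag + self.sigma2


@dataclass
class GeneFit:
    """One maximized per-gene fit (null: beta_hat is empty)."""

    alpha_hat: np.ndarray
    beta_hat: np.ndarray
    sigma2_hat: float
    loglik: float
    converged: bool
    optimizer: str  # "scoring" | "brent" | "boundary" | "failed"


def _quad_terms(
    sigma2: float, Y: np.ndarray, W: np.ndarray, sb: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weights 1/V, GLS coefficients, and the GLS residual, at one sigma2."""
    v = sb + sigma2
    if np.any(v <= 0):
        raise ValueError("V must be positive definite")
    w = 1.0 / v
    Ww = W * w[:, None]
    A = W.T @ Ww
    coef = np.linalg.solve(A, Ww.T @ Y)
    resid = Y - W @ coef
    return w, coef, resid


def profile_loglik(
    sigma2: float, Y: np.ndarray, W: np.ndarray, sb: np.ndarray
) -> float:
    """Profile log-likelihood of sigma2 (constant -(N/2)log(2 pi) dropped)."""
    Y = np.asarray(Y, dtype=float)
    W = np.atleast_2d(np.asarray(W, dtype=float))
    sb = np.asarray(sb, dtype=float)
    w, _, resid = _quad_terms(sigma2, Y, W, sb)
    return float(-0.5 * np.sum(np.log(w**-1)) - 0.5 * np.sum(w * resid**2))


def _coarse_grid(upper: float, K: int = 32) -> np.ndarray:
    """0 plus K-1 log-spaced candidates up to ``upper``.

    The profile likelihood can be multimodal in sigma2, so local searches
    (scoring, Brent) are guarded by a global scan over this grid.
    """
    return np.concatenate([[0.0], np.geomspace(max(upper, 1e-12) * 1e-6, upper, K - 1)])


def _refine_around(
    Y: np.ndarray, W: np.ndarray, sb: np.ndarray, grid: np.ndarray, k: int
) -> float:
    """Brent-polish the best grid candidate within its bracketing interval."""
    lo = grid[k - 1] if k > 0 else 0.0
    hi = grid[k + 1] if k + 1 < grid.size else grid[k] * 10 + 1e-12
    res = minimize_scalar(
        lambda s: -profile_loglik(s, Y, W, sb),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-12},
    )
    cands = [grid[k], float(res.x)]
    vals = [profile_loglik(s, Y, W, sb) for s in cands]
    return cands[int(np.argmax(vals))]


def _score_info(
    sigma2: float, Y: np.ndarray, W: np.ndarray, sb: np.ndarray
) -> tuple[float, float]:
    w, _, resid = _quad_terms(sigma2, Y, W, sb)
    py = w * resid  # P Y = V^-1 (Y - W b_hat)
    U = -0.5 * np.sum(w) + 0.5 * np.sum(py**2)
    info = 0.5 * np.sum(w**2)
    return float(U), float(info)


def fit_sigma2(
    Y: np.ndarray,
    W: np.ndarray,
    sb: np.ndarray,
    s2_init: float | None = None,
    upper: float | None = None,
) -> GeneFit:
    """Maximize the profile log-likelihood over sigma2 in [0, inf).

    Fisher scoring first; if an iterate is projected to zero twice in a row
    the boundary solution is declared, and if scoring oscillates or escapes
    the bracket a bounded Brent search takes over (the bracket is widened up
    to three times when the maximum sits on its upper edge).
    """
    Y = np.asarray(Y, dtype=float)
    W = np.atleast_2d(np.asarray(W, dtype=float))
    sb = np.asarray(sb, dtype=float)
    N, p = W.shape

    # OLS residual variance seeds the iteration and scales the bracket
    coef0, _, _, _ = np.linalg.lstsq(W, Y, rcond=None)
    rss = float(np.sum((Y - W @ coef0) ** 2))
    s2_ols = rss / max(N - p, 1)
    if s2_init is None:
        s2_init = max(s2_ols - float(np.mean(sb)), 1e-8)
    if upper is None:
        upper = max(10.0 * s2_ols, 1e-6)
    upper0 = upper

    sigma2, optimizer, converged = s2_init, "scoring", False
    # a non-positive score at 0 makes the boundary a local maximizer; the
    # global grid guard below still checks for a better interior mode
    U0, _ = _score_info(0.0, Y, W, sb)
    if U0 <= 0.0:
        sigma2, optimizer, converged = 0.0, "boundary", True
    else:
        projections = 0
        for _ in range(_MAX_SCORING_ITER):
            U, info = _score_info(sigma2, Y, W, sb)
            step = U / info
            new = sigma2 + step
            if not np.isfinite(new) or new > upper:
                optimizer = "brent"
                break
            if new < 0.0:
                new = 0.0
                projections += 1
                if projections >= 2:
                    sigma2, optimizer, converged = 0.0, "boundary", True
                    break
            else:
                projections = 0
            if abs(new - sigma2) < _SCORING_TOL * (1.0 + sigma2):
                sigma2, converged = new, True
                break
            sigma2 = new
        else:
            optimizer = "brent"

    if not converged:
        optimizer = "brent"
        for _ in range(4):  # widen the bracket up to 3 times
            res = minimize_scalar(
                lambda s: -profile_loglik(s, Y, W, sb),
                bounds=(0.0, upper),
                method="bounded",
                options={"xatol": 1e-10},
            )
            sigma2 = float(res.x)
            if sigma2 < 0.999 * upper:
                converged = True
                break
            upper *= 10.0
        else:
            converged = np.isfinite(res.fun)
        # bounded search cannot reach the exact boundary; snap if better there
        if profile_loglik(0.0, Y, W, sb) >= profile_loglik(sigma2, Y, W, sb):
            sigma2 = 0.0

    # global guard: the profile likelihood can be multimodal, so the local
    # solution (scoring, boundary, or Brent) is checked against a coarse
    # global scan and replaced when an interior candidate beats it
    grid = _coarse_grid(upper0)
    grid_vals = np.array([profile_loglik(s, Y, W, sb) for s in grid])
    k = int(np.argmax(grid_vals))
    ll = profile_loglik(sigma2, Y, W, sb)
    if grid_vals[k] > ll + 1e-9:
        cand = _refine_around(Y, W, sb, grid, k)
        if profile_loglik(cand, Y, W, sb) > ll:
            sigma2 = cand
            optimizer = "boundary" if cand == 0.0 else "brent"
            converged = True

    ll = profile_loglik(sigma2, Y, W, sb)
    _, coef, _ = _quad_terms(sigma2, Y, W, sb)
    return GeneFit(
        alpha_hat=coef,
        beta_hat=np.empty(0),
        sigma2_hat=float(sigma2),
        loglik=ll,
        converged=bool(converged and np.isfinite(ll)),
        optimizer=optimizer,
    )


def gls_coefficients(
    Y: np.ndarray, Z: np.ndarray, X: np.ndarray | None, vm: VarianceModel
) -> tuple[np.ndarray, np.ndarray]:
    """GLS estimates (alpha_hat, beta_hat) at a fitted variance model.

    With X None or empty this is the null-model estimate alpha_hat =
    (Z' V^-1 Z)^-1 Z' V^-1 Y and beta_hat is empty.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    q = Z.shape[1]
    if X is None or np.size(X) == 0:
        W = Z
    else:
        W = np.hstack([Z, np.atleast_2d(np.asarray(X, dtype=float))])
    _, coef, _ = _quad_terms(vm.sigma2, np.asarray(Y, dtype=float), W, vm.sigma_b_diag)
    return coef[:q], coef[q:]


def fit_sigma2_batch(
    Y: np.ndarray, W: np.ndarray, sb: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized sigma2 fits for G genes sharing one design.

    Parameters
    ----------
    Y : (G, N) responses; W : (N, p) design; sb : (G, N) technical variances.

    Returns
    -------
    sigma2 (G,), loglik (G,), coef (G, p), ok (G,) convergence flags.

    Fisher scoring runs lock-step across genes with per-gene convergence
    masks; stragglers are finished one at a time with the scalar fitter.
    """
    Y = np.asarray(Y, dtype=float)
    sb = np.asarray(sb, dtype=float)
    W = np.atleast_2d(np.asarray(W, dtype=float))
    G, N = Y.shape
    p = W.shape[1]

    coef_ols, _, _, _ = np.linalg.lstsq(W, Y.T, rcond=None)
    rss = np.sum((Y - (W @ coef_ols).T) ** 2, axis=1)
    s2_ols = rss / max(N - p, 1)
    sigma2 = np.maximum(s2_ols - sb.mean(axis=1), 1e-8)
    upper = np.maximum(10.0 * s2_ols, 1e-6)

    def batch_score(s2: np.ndarray, active: np.ndarray):
        v = sb[active] + s2[active, None]
        w = 1.0 / v
        A = np.einsum("gn,np,nq->gpq", w, W, W)
        rhs = np.einsum("np,gn->gp", W, w * Y[active])
        coef = np.linalg.solve(A, rhs[..., None])[..., 0]
        resid = Y[active] - coef @ W.T
        py = w * resid
        U = -0.5 * w.sum(axis=1) + 0.5 * (py**2).sum(axis=1)
        info = 0.5 * (w**2).sum(axis=1)
        return U, info

    # genes whose score at 0 is non-positive sit on the boundary
    U0, _ = batch_score(np.zeros(G), np.ones(G, dtype=bool))
    done = U0 <= 0.0
    sigma2[done] = 0.0
    needs_fallback = np.zeros(G, dtype=bool)
    projections = np.zeros(G, dtype=int)
    active = ~done

    for _ in range(_MAX_SCORING_ITER):
        if not active.any():
            break
        U, info = batch_score(sigma2, active)
        idx = np.flatnonzero(active)
        new = sigma2[idx] + U / info
        bad = ~np.isfinite(new) | (new > upper[idx])
        neg = new < 0.0
        new = np.where(neg, 0.0, new)
        projections[idx] = np.where(neg, projections[idx] + 1, 0)
        boundary = projections[idx] >= 2
        conv = np.abs(new - sigma2[idx]) < _SCORING_TOL * (1.0 + sigma2[idx])
        sigma2[idx] = np.where(bad, sigma2[idx], new)
        sigma2[idx[boundary]] = 0.0
        needs_fallback[idx[bad]] = True
        done_now = bad | boundary | conv
        active[idx[done_now]] = False
    needs_fallback |= active  # scoring hit the iteration cap

    for g in np.flatnonzero(needs_fallback):
        fit = fit_sigma2(Y[g], W, sb[g])
        sigma2[g] = fit.sigma2_hat

    # global guard, vectorized: same coarse grid per gene as the scalar
    # fitter; genes where a grid candidate beats the local solution are
    # re-polished one at a time
    K = 32
    grid = np.concatenate(
        [np.zeros((G, 1)), upper[:, None] * np.geomspace(1e-6, 1.0, K - 1)[None, :]],
        axis=1,
    )
    vg = sb[:, None, :] + grid[:, :, None]
    wg = 1.0 / vg
    Ag = np.einsum("gkn,np,nq->gkpq", wg, W, W)
    rhsg = np.einsum("np,gkn->gkp", W, wg * Y[:, None, :])
    coefg = np.linalg.solve(Ag, rhsg[..., None])[..., 0]
    residg = Y[:, None, :] - coefg @ W.T
    valsg = -0.5 * np.log(vg).sum(axis=2) - 0.5 * (wg * residg**2).sum(axis=2)
    v_cur = sb + sigma2[:, None]
    w_cur = 1.0 / v_cur
    A_cur = np.einsum("gn,np,nq->gpq", w_cur, W, W)
    rhs_cur = np.einsum("np,gn->gp", W, w_cur * Y)
    coef_cur = np.linalg.solve(A_cur, rhs_cur[..., None])[..., 0]
    resid_cur = Y - coef_cur @ W.T
    ll_cur = -0.5 * np.log(v_cur).sum(axis=1) - 0.5 * (w_cur * resid_cur**2).sum(axis=1)
    best_k = valsg.argmax(axis=1)
    improvable = valsg[np.arange(G), best_k] > ll_cur + 1e-9
    for g in np.flatnonzero(improvable):
        cand = _refine_around(Y[g], W, sb[g], grid[g], int(best_k[g]))
        if profile_loglik(cand, Y[g], W, sb[g]) > ll_cur[g]:
            sigma2[g] = cand

    # final coefficients and log-likelihoods at the fitted sigma2
    v = sb + sigma2[:, None]
    w = 1.0 / v
    A = np.einsum("gn,np,nq->gpq", w, W, W)
    rhs = np.einsum("np,gn->gp", W, w * Y)
    coef = np.linalg.solve(A, rhs[..., None])[..., 0]
    resid = Y - coef @ W.T
    loglik = -0.5 * np.log(v).sum(axis=1) - 0.5 * (w * resid**2).sum(axis=1)
    ok = np.isfinite(loglik)
    return sigma2, loglik, coef, ok
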