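"""Mean-variance trend and per-observation technical means.

Per gene, an OLS fit of log-cpm on the full design gives fitted values and
a residual variance.  A LOWESS curve of the quarter-root residual variance
(s-hat^{1/2}) against average log2 count size (lambda-hat) pools information
across genes; evaluating it at per-observation fitted log2 counts and
plugging into the second-order mean approximation

    mu_hat = 2^lambda_hat * (1 + (ln 2)^2 s_hat^2 / 2)

yields the expected count mu_hat_gi whose reciprocal is the technical
(counting-noise) variance of y_gi on the log2 scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .io import DesignPair
from .normalization import LogCpmMatrix, NormalizedLibSizes

__all__ = [
    "GeneOlsSummary",
    "TrendModel",
    "TechnicalMeans",
    "fit_gene_ols",
    "gene_lambda",
    "fit_trend",
    "predict_mu",
]

_LOG2_1E6 = np.log2(1e6)
_LN2_SQ = np.log(2.0) ** 2


@dataclass
class GeneOlsSummary:
    fitted: np.ndarray     # G x N fitted log-cpm
    resid_var: np.ndarray  # length G, RSS / (N - p)
    ybar: np.ndarray       # length G row means of y


@dataclass
class TrendModel:
    """LOWESS curve of s^{1/2} = (resid_var)^{1/4} on lambda-hat."""

    lambda_hat: np.ndarray
    grid_x: np.ndarray   # sorted lambda values of the fitted curve
    grid_y: np.ndarray   # smoothed s^{1/2}, clamped at 0
    R_tilde: float
    span: float

    def __call__(self, lam: np.ndarray) -> np.ndarray:
        """Evaluate by linear interpolation, constant beyond the range."""
        return np.interp(lam, self.grid_x, self.grid_y)


@dataclass
class TechnicalMeans:
    mu_hat: np.ndarray          # G x N, > 0
    lambda_hat_obs: np.ndarray  # G x N fitted log2 counts
    s_half_obs: np.ndarray      # G x N trend values (s^{1/2} scale)


def fit_gene_ols(
    y: LogCpmMatrix | np.ndarray, dp: DesignPair | np.ndarray
) -> GeneOlsSummary:
    """Per-gene OLS of log-cpm on the stacked design (Z, X).

    Residual variance uses the unbiased divisor N - p with p the total
    number of design columns.  ``dp`` may also be a bare design matrix.
    """
    Y = y.y if isinstance(y, LogCpmMatrix) else np.asarray(y, dtype=float)
    W = np.hstack([dp.Z, dp.X]) if isinstance(dp, DesignPair) else np.asarray(dp, float)
    N, p = W.shape
    if N <= p:
        raise ValueError("need more samples than design columns for OLS")
    coef, _, _, _ = np.linalg.lstsq(W, Y.T, rcond=None)
    fitted = (W @ coef).T
    resid = Y - fitted
    s2 = (resid**2).sum(axis=1) / (N - p)
    return GeneOlsSummary(fitted=fitted, resid_var=s2, ybar=Y.mean(axis=1))


def gene_lambda(ols: GeneOlsSummary, nls: NormalizedLibSizes) -> np.ndarray:
    """Average log2 count size: lambda_hat_g = ybar_g + log2(R~) - log2(1e6),

    with R~ the geometric mean of (R*_i + 1).
    """
    R_tilde = np.exp(np.mean(np.log(nls.R_star + 1.0)))
    return ols.ybar + np.log2(R_tilde) - _LOG2_1E6


def fit_trend(
    lambda_hat: np.ndarray,
    resid_var: np.ndarray,
    nls: NormalizedLibSizes,
    span: float = 0.5,
    iterations: int = 3,
) -> TrendModel:
    """LOWESS of (resid_var)^{1/4} on lambda-hat across genes."""
    lambda_hat = np.asarray(lambda_hat, dtype=float)
    s_half = np.asarray(resid_var, dtype=float) ** 0.25
    if lambda_hat.size < 10:
        raise ValueError(
            "fewer than 10 genes: a mean-variance trend cannot be smoothed"
        )
    fitted = _sm_lowess(s_half, lambda_hat, frac=span, it=iterations, return_sorted=True)
    grid_x, grid_y = fitted[:, 0], np.clip(fitted[:, 1], 0.0, None)
    # average over tied x so interpolation is well defined
    ux, start = np.unique(grid_x, return_index=True)
    sums = np.add.reduceat(grid_y, start)
    counts = np.diff(np.append(start, grid_y.size))
    grid_x, grid_y = ux, sums / counts
    R_tilde = float(np.exp(np.mean(np.log(nls.R_star + 1.0))))
    return TrendModel(
        lambda_hat=lambda_hat, grid_x=grid_x, grid_y=grid_y, R_tilde=R_tilde, span=span
    )


def predict_mu(
    ols: GeneOlsSummary, trend: TrendModel, nls: NormalizedLibSizes
) -> TechnicalMeans:
    """Per-observation expected counts via the second-order approximation."""
    lam_obs = ols.fitted + np.log2(nls.R_star + 1.0)[None, :] - _LOG2_1E6
    s_half = trend(lam_obs)
    s2 = s_half**4
    mu = 2.0**lam_obs * (1.0 + 0.5 * _LN2_SQ * s2)
    return TechnicalMeans(mu_hat=mu, lambda_hat_obs=lam_obs, s_half_obs=s_half)
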