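"""Whole-matrix differential expression analysis.

``run_balli`` chains the stages: low-count filter, TMM normalization,
log-cpm transform, mean-variance trend, per-gene null/alternative mixed
model fits, likelihood-ratio statistics with and without the Bartlett
correction, and Benjamini-Hochberg FDR over the tested genes.  The result
is one tidy table with a row per gene that survived the filter.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .bartlett import bartlett_components_batch
from .io import CountMatrix, DesignPair, filter_low_counts
from .lmm import fit_sigma2_batch
from .normalization import log_cpm, tmm_factors
from .trend import fit_gene_ols, fit_trend, gene_lambda, predict_mu

__all__ = ["run_balli", "bh_fdr"]

logger = logging.getLogger("balli")

_COLUMNS = [
    "gene_id", "beta_hat", "sigma2_hat", "lr", "C", "lr_star",
    "p_lli", "p_balli", "fdr_lli", "fdr_balli", "status",
]


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at one.

    NaN entries are excluded from the ranking and returned as NaN.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    n = pv.size
    if n == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(n)
    res[order] = adj
    out[ok] = res
    return out


def run_balli(
    cm: CountMatrix,
    dp: DesignPair,
    span: float = 0.5,
    filter_counts: bool = True,
) -> pd.DataFrame:
    """Run the full per-gene test over a count matrix.

    Returns a DataFrame with per-gene effect estimates, the LR statistic,
    the Bartlett constant C, the corrected statistic, both p-values and
    their BH-FDR adjustments.  Genes whose fit fails carry status
    ``fit_failed``, missing p-values, and are excluded from the FDR
    denominator.  The run is deterministic.
    """
    if filter_counts:
        cm = filter_low_counts(cm)
    logger.info("testing %d genes x %d samples", cm.n_genes, cm.n_samples)
    nls = tmm_factors(cm)
    y = log_cpm(cm, nls)

    ols = fit_gene_ols(y, dp)
    lam = gene_lambda(ols, nls)
    trend = fit_trend(lam, ols.resid_var, nls, span=span)
    tech = predict_mu(ols, trend, nls)
    sb = 1.0 / tech.mu_hat  # per-observation technical variance

    Z, X = dp.Z, dp.X
    W = np.hstack([Z, X])
    q, df = Z.shape[1], dp.df

    s2_null, ll_null, coef_null, ok_null = fit_sigma2_batch(y.y, Z, sb)
    s2_alt, ll_alt, coef_alt, ok_alt = fit_sigma2_batch(y.y, W, sb)
    ok = ok_null & ok_alt

    lr = -2.0 * (ll_null - ll_alt)
    bad_lr = lr < -1e-8
    if bad_lr.any():
        logger.warning("%d genes with negative LR marked as fit failures", bad_lr.sum())
    ok &= ~bad_lr
    lr = np.clip(lr, 0.0, None)

    v_null = sb + s2_null[:, None]
    D, Mc, P, nu, tau = bartlett_components_batch(v_null, Z, X)
    C = (-0.5 * Mc + 0.25 * P - 0.5 * nu * tau) / D
    denom = 1.0 + C / df
    ok &= np.isfinite(C) & (denom > 0)

    lr_star = np.where(ok, lr / denom, np.nan)
    p_lli = np.where(ok, chi2.sf(lr, df), np.nan)
    p_balli = np.where(ok, chi2.sf(lr_star, df), np.nan)

    table = pd.DataFrame(
        {
            "gene_id": cm.gene_ids,
            "beta_hat": [row[q:] if df > 1 else float(row[q]) for row in coef_alt],
            "sigma2_hat": s2_alt,
            "lr": np.where(ok, lr, np.nan),
            "C": C,
            "lr_star": lr_star,
            "p_lli": p_lli,
            "p_balli": p_balli,
            "fdr_lli": bh_fdr(p_lli),
            "fdr_balli": bh_fdr(p_balli),
            "status": np.where(ok, "ok", "fit_failed"),
        },
        columns=_COLUMNS,
    )
    n_failed = int((~ok).sum())
    if n_failed:
        logger.warning("%d of %d genes failed to fit", n_failed, cm.n_genes)
    if n_failed == cm.n_genes:
        raise RuntimeError("all genes failed to fit")
    return table
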