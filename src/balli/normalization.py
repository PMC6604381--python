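"""Between-sample normalization and the log-cpm transform.

TMM (trimmed mean of M-values) scaling factors are computed against a
reference sample and rescaled to geometric mean one; effective library
sizes R*_i = R_i * factor_i then enter the log-cpm transform

    y_gi = log2( (r_gi + d_i) / (R*_i + 2 d_i) * 1e6 ),
    d_i  = R*_i / mean(R*) * 0.25,

i.e. a pseudo-count proportional to the sample's effective depth, averaging
0.25 across samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .io import CountMatrix

__all__ = ["NormalizedLibSizes", "LogCpmMatrix", "tmm_factors", "log_cpm"]

# edgeR-conventional TMM tuning: symmetric trim fractions on the log ratios
# (M) and mean log abundances (A), and precision weighting by the asymptotic
# binomial variance of M.
_M_TRIM = 0.30
_A_TRIM = 0.05


@dataclass
class NormalizedLibSizes:
    """TMM factors, effective library sizes and the per-sample offsets d_i."""

    factors: np.ndarray
    R_star: np.ndarray
    d: np.ndarray


@dataclass
class LogCpmMatrix:
    """log2 counts-per-million with depth-proportional pseudo-counts."""

    y: np.ndarray
    cm: CountMatrix
    nls: NormalizedLibSizes


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float) -> float:
    """TMM factor of one sample against the reference (log2 scale -> 2**)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p_obs = obs / n_obs
        p_ref = ref / n_ref
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
        # asymptotic variance of M under binomial sampling
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    ok = np.isfinite(m) & np.isfinite(a) & (a > -1e10)
    m, a, v = m[ok], a[ok], v[ok]
    if m.size == 0:
        warnings.warn("no genes usable for TMM; factor set to 1", stacklevel=3)
        return 1.0
    if np.max(np.abs(m)) < 1e-6:  # identical composition
        return 1.0
    n = m.size
    lo_m, hi_m = np.floor(n * _M_TRIM) + 1, n - np.floor(n * _M_TRIM)
    lo_a, hi_a = np.floor(n * _A_TRIM) + 1, n - np.floor(n * _A_TRIM)
    # average ranks so tied log-ratios are kept or trimmed together
    rank_m = rankdata(m, method="average")
    rank_a = rankdata(a, method="average")
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        warnings.warn("all genes trimmed in TMM; factor set to 1", stacklevel=3)
        return 1.0
    w = 1.0 / v[keep]
    f = np.sum(w * m[keep]) / np.sum(w)
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(cm: CountMatrix) -> NormalizedLibSizes:
    """Trimmed-mean-of-M-values scaling factors, rescaled to geometric mean 1.

    The reference sample is the one whose 75th percentile of count
    proportions is closest to the mean of those percentiles across samples.
    """
    counts = cm.counts.astype(float)
    lib = cm.lib_sizes.astype(float)
    if cm.n_samples < 2:
        factors = np.ones(cm.n_samples)
    else:
        if np.any(lib <= 0):
            raise ValueError("every sample needs a positive library size")
        q75 = np.quantile(counts / lib, 0.75, axis=0)
        ref = int(np.argmin(np.abs(q75 - q75.mean())))
        factors = np.array(
            [
                1.0
                if i == ref
                else _tmm_pair(counts[:, i], counts[:, ref], lib[i], lib[ref])
                for i in range(cm.n_samples)
            ]
        )
        factors = factors / np.exp(np.mean(np.log(factors)))
    R_star = lib * factors
    d = R_star / R_star.mean() * 0.25
    return NormalizedLibSizes(factors=factors, R_star=R_star, d=d)


def log_cpm(cm: CountMatrix, nls: NormalizedLibSizes) -> LogCpmMatrix:
    """Transform counts to log2 counts per million with the d_i offset."""
    if cm.n_samples != nls.R_star.size:
        raise ValueError("count matrix and normalized library sizes disagree")
    r = cm.counts.astype(float)
    d = nls.d
    y = np.log2((r + d) / (nls.R_star + 2.0 * d) * 1e6)
    return LogCpmMatrix(y=y, cm=cm, nls=nls)
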