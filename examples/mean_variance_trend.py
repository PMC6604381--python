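"""Step through the model-building stages on one dataset.

Shows the intermediate objects the pipeline produces: TMM scaling factors,
log-cpm values, the lowess mean-variance trend, the per-gene technical
variances it implies, and a single gene's biological variance fit.
"""

import numpy as np

from balli import (
    SimConfig,
    filter_low_counts,
    fit_gene_ols,
    fit_sigma2,
    fit_trend,
    gene_lambda,
    group_design,
    log_cpm,
    predict_mu,
    simulate_counts,
    tmm_factors,
)

truth = simulate_counts(SimConfig(G=800, N=8, u=0.5, de_fraction=0.0, seed=3))
cm = filter_low_counts(truth.counts)
dp = group_design(8)

# normalization: TMM factors average out compositional differences; the
# effective library sizes R* and pseudo-counts d feed the log-cpm transform
nls = tmm_factors(cm)
print("TMM factors:", np.round(nls.factors, 4))
print("effective library sizes:", np.round(nls.R_star).astype(int))

y = log_cpm(cm, nls)
print("log-cpm range: [%.2f, %.2f]" % (y.y.min(), y.y.max()))

# trend: residual standard deviations (to the 1/2 power of the variance)
# follow a smooth decreasing function of log2 expected expression
ols = fit_gene_ols(y, dp)
lam = gene_lambda(ols, nls)
trend = fit_trend(lam, ols.resid_var, nls)
for q in (0.1, 0.5, 0.9):
    lq = np.quantile(lam, q)
    print(f"lambda = {lq:5.2f}  ->  trend sd^(1/2) = {trend(np.array([lq]))[0]:.3f}")

# technical variances: 1 / mu_hat per gene and sample
tech = predict_mu(ols, trend, nls)
sb = 1.0 / tech.mu_hat
print("median technical variance:", float(np.median(sb)))

# one gene's biological variance on top of its technical variance
g = 0
W = np.hstack([dp.Z, dp.X])
fit = fit_sigma2(y.y[g], W, sb[g])
print(f"gene {cm.gene_ids[g]}: sigma2_hat = {fit.sigma2_hat:.4f} "
      f"({fit.optimizer}, converged = {fit.converged})")
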