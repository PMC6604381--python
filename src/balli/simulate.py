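"""Negative-binomial RNA-seq simulation and the calibration study.

Counts for gene g, sample i are drawn from a negative binomial with mean
a_gi and variance a_gi + a_gi^2 phi_gi.  Baseline gene means a_g come from
a log-normal spanning realistic sequencing depth; per-sample means multiply
a_g by a library-size factor drawn from U(u, 2 - u) (u = 1 gives equal
libraries; smaller u more depth variation).  Per-observation dispersions
follow

    phi_gi = (0.2 + a_gi^{-1/2})^2 * delta_g,   40 / delta_g ~ chi2(40),

so that dispersion falls with expression and carries gene-level noise.
Differentially expressed genes have their second-group means multiplied by
2^{+-delta} with delta = c * sigma_g, where sigma_g is the gene's null
log2-scale standard deviation sqrt(1/a_g + mean(phi_g)) / ln 2 — an effect
expressed in units of the gene's own biological spread.

Each random quantity draws from its own named substream of the master seed,
so changing e.g. the effect size does not perturb the simulated baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix, DesignPair

__all__ = [
    "SimConfig",
    "SimTruth",
    "draw_dispersions",
    "draw_library_factors",
    "simulate_counts",
    "group_design",
    "evaluate_performance",
    "run_study",
]

_STREAMS = ("means", "dispersions", "factors", "de", "counts")


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults give two equal groups, equal library sizes, a 10% DE fraction
    and baseline means log-normal with central 99% range [5, 5000] counts
    (log-mean at the geometric midpoint, log-sd = ln(5000/5)/(2 * 2.576)).
    """

    G: int = 2000
    N: int = 12
    u: float = 1.0
    de_fraction: float = 0.1
    effect: float = 0.0  # c in delta = c * sigma_g
    mean_log: float = float(0.5 * (np.log(5.0) + np.log(5000.0)))
    mean_sdlog: float = float(np.log(5000.0 / 5.0) / (2.0 * 2.5758293035489004))
    seed: int = 0
    replicates: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.u <= 1.0:
            raise ValueError("u must lie in (0, 1]")
        if not 0.0 <= self.de_fraction < 1.0:
            raise ValueError("de_fraction must lie in [0, 1)")
        if self.effect < 0:
            raise ValueError("effect multiplier must be non-negative")
        if self.N % 2:
            raise ValueError("N must split into two equal groups")


@dataclass
class SimTruth:
    counts: CountMatrix
    is_de: np.ndarray
    true_delta: np.ndarray
    lib_factors: np.ndarray
    gene_dispersion_scale: np.ndarray


def _streams(seed: int | np.random.SeedSequence) -> dict[str, np.random.Generator]:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return {
        name: np.random.default_rng(np.random.SeedSequence(
            entropy=ss.entropy, spawn_key=ss.spawn_key + (k,)
        ))
        for k, name in enumerate(_STREAMS)
    }


def draw_dispersions(
    G: int, a: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Gene dispersion scales delta_g = 40/chi2(40) and per-cell phi_gi."""
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0):
        raise ValueError("means must be positive")
    delta = 40.0 / rng.chisquare(40.0, size=G)
    phi = (0.2 + a ** (-0.5)) ** 2 * delta.reshape(-1, *([1] * (a.ndim - 1)))
    return delta, phi


def draw_library_factors(N: int, u: float, rng: np.random.Generator) -> np.ndarray:
    """Library-size factors, i.i.d. uniform on [u, 2 - u]."""
    if not 0.0 < u <= 1.0:
        raise ValueError("u must lie in (0, 1]")
    if u == 1.0:
        return np.ones(N)
    return rng.uniform(u, 2.0 - u, size=N)


def group_design(N: int) -> DesignPair:
    """Two equal groups: intercept-only Z and a single 0/1 dummy X.

    The first N/2 samples form group 1 (dummy = 1); the second group is the
    reference.
    """
    x = np.zeros((N, 1))
    x[: N // 2, 0] = 1.0
    return DesignPair(Z=np.ones((N, 1)), X=x, M=2)


def simulate_counts(cfg: SimConfig, seed: int | np.random.SeedSequence | None = None) -> SimTruth:
    """Draw one genes x samples negative-binomial count matrix."""
    rng = _streams(cfg.seed if seed is None else seed)
    G, N = cfg.G, cfg.N

    a_g = rng["means"].lognormal(cfg.mean_log, cfg.mean_sdlog, size=G)
    lib = draw_library_factors(N, cfg.u, rng["factors"])
    a_null = a_g[:, None] * lib[None, :]

    delta_g, phi_null = draw_dispersions(G, a_null, rng["dispersions"])

    n_de = int(round(G * cfg.de_fraction))
    is_de = np.zeros(G, dtype=bool)
    true_delta = np.zeros(G)
    a = a_null.copy()
    if n_de > 0 and cfg.effect > 0:
        de_rng = rng["de"]
        de_idx = de_rng.choice(G, size=n_de, replace=False)
        is_de[de_idx] = True
        sigma_g = np.sqrt(1.0 / a_g + phi_null.mean(axis=1)) / np.log(2.0)
        sign = de_rng.choice([-1.0, 1.0], size=n_de)
        true_delta[de_idx] = sign * cfg.effect * sigma_g[de_idx]
        group2 = np.arange(N // 2, N)
        a[np.ix_(de_idx, group2)] *= 2.0 ** true_delta[de_idx][:, None]
        # dispersions respond to the shifted means through the same delta_g
        phi = (0.2 + a ** (-0.5)) ** 2 * delta_g[:, None]
    else:
        phi = phi_null

    size = 1.0 / phi  # NB "number of failures" parameter
    p = size / (size + a)
    counts = rng["counts"].negative_binomial(size, p)

    cm = CountMatrix(
        gene_ids=[f"gene{j}" for j in range(G)],
        sample_ids=[f"s{i}_g{1 if i < N // 2 else 2}" for i in range(N)],
        counts=counts.astype(np.int64),
    )
    return SimTruth(
        counts=cm,
        is_de=is_de,
        true_delta=true_delta,
        lib_factors=lib,
        gene_dispersion_scale=delta_g,
    )


def _wald_ci(k: int, n: int) -> tuple[float, float]:
    if n == 0:
        return (float("nan"), float("nan"))
    p = k / n
    half = 1.959963984540054 * np.sqrt(p * (1 - p) / n)
    return (max(p - half, 0.0), min(p + half, 1.0))


def evaluate_performance(
    table: pd.DataFrame,
    truth: SimTruth,
    alpha: float = 0.05,
    fdr_level: float = 0.1,
    method: str = "balli",
) -> dict:
    """Type-1 error, power and precision of one method on one replicate.

    Type-1 error is the proportion of truly-null genes with raw p < alpha;
    power the proportion of truly-DE genes called at FDR < fdr_level;
    precision the proportion of those calls that are truly DE (NaN with no
    calls).  Counts are returned so replicates can be pooled exactly.
    """
    if method not in ("balli", "lli"):
        raise ValueError("method must be 'balli' or 'lli'")
    p_col, fdr_col = f"p_{method}", f"fdr_{method}"
    truth_de = pd.Series(truth.is_de, index=truth.counts.gene_ids)
    tab = table[table["status"] == "ok"]
    is_de = truth_de.loc[tab["gene_id"]].to_numpy()

    p = tab[p_col].to_numpy()
    fdr = tab[fdr_col].to_numpy()
    null_mask = ~is_de
    n_null = int(null_mask.sum())
    n_de = int(is_de.sum())
    k_type1 = int((p[null_mask] < alpha).sum())
    calls = fdr < fdr_level
    k_power = int(calls[is_de].sum())
    n_calls = int(calls.sum())
    lo, hi = _wald_ci(k_type1, n_null)
    return {
        "method": method,
        "alpha": alpha,
        "fdr_level": fdr_level,
        "type1": k_type1 / n_null if n_null else float("nan"),
        "type1_ci_low": lo,
        "type1_ci_high": hi,
        "power": k_power / n_de if n_de else 0.0,
        "precision": k_power / n_calls if n_calls else float("nan"),
        "n_null": n_null,
        "n_de": n_de,
        "k_type1": k_type1,
        "k_power": k_power,
        "n_calls": n_calls,
    }


def run_study(
    cfg: SimConfig,
    methods: tuple[str, ...] = ("balli", "lli"),
    alphas: tuple[float, ...] = (0.1, 0.05, 0.01, 0.005),
    fdr_level: float = 0.1,
    span: float = 0.5,
) -> pd.DataFrame:
    """Replicate the simulation and pool metrics across replicates.

    Each replicate draws a fresh dataset from its own substream of
    ``cfg.seed``, runs the full testing pipeline once, and contributes its
    rejection counts; pooled rates and Wald 95% confidence intervals are
    returned per (method, alpha) cell.
    """
    from .pipeline import run_balli  # local import to avoid a cycle

    dp = group_design(cfg.N)
    master = np.random.SeedSequence(cfg.seed)
    rows: list[dict] = []
    for rep in range(cfg.replicates):
        rep_seed = np.random.SeedSequence(entropy=master.entropy, spawn_key=(rep,))
        truth = simulate_counts(cfg, seed=rep_seed)
        table = run_balli(truth.counts, dp, span=span)
        for method in methods:
            for alpha in alphas:
                row = evaluate_performance(table, truth, alpha, fdr_level, method)
                row["replicate"] = rep
                rows.append(row)

    per_rep = pd.DataFrame(rows)
    pooled = []
    for (method, alpha), grp in per_rep.groupby(["method", "alpha"], sort=False):
        n_null, k_type1 = int(grp["n_null"].sum()), int(grp["k_type1"].sum())
        n_de, k_power = int(grp["n_de"].sum()), int(grp["k_power"].sum())
        n_calls = int(grp["n_calls"].sum())
        lo, hi = _wald_ci(k_type1, n_null)
        pooled.append(
            {
                "N": cfg.N,
                "u": cfg.u,
                "effect": cfg.effect,
                "de_fraction": cfg.de_fraction,
                "method": method,
                "alpha": alpha,
                "fdr_level": fdr_level,
                "type1": k_type1 / n_null if n_null else float("nan"),
                "type1_ci_low": lo,
                "type1_ci_high": hi,
                "power": k_power / n_de if n_de else float("nan"),
                "precision": k_power / n_calls if n_calls else float("nan"),
                "replicates": cfg.replicates,
            }
        )
    return pd.DataFrame(pooled)
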