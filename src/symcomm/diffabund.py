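"""Bayesian Poisson-lognormal differential abundance between pools.

Raw counts (not rarefied or normalized) are modeled per compartment or
coral species as

    y[s, t] ~ Poisson(lambda[s, t])
    log lambda[s, t] = alpha[t] + beta[t] * x[s] + u[s] + eps[s, t]

where ``x[s]`` indicates the non-reference pool, ``u[s]`` is a
sample-level lognormal random effect absorbing sequencing-depth
differences, and ``eps[s, t]`` is a per-cell overdispersion effect. An
artificial "sum" taxon whose count is each sample's total is modeled
alongside the real taxa; relative abundances and between-pool
fold-changes are computed against it, which cancels the depth effects.

Inference is by adaptive Metropolis-within-Gibbs: every parameter block
is updated elementwise with Gaussian random-walk proposals whose scales
adapt toward a 0.44 acceptance rate during burn-in. Significance uses
Bayesian z-scores (posterior mean/sd of the between-pool log contrast)
with two-sided normal p-values and Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, norm

from .table import CountTable

logger = logging.getLogger(__name__)

SUM_TAXON = "sum"


# ---------------------------------------------------------------------------
# taxon filtering and the sum taxon


def filter_taxa(counts: CountTable, min_fraction: float = 0.001) -> CountTable:
    """Keep taxa whose total count strictly exceeds ``min_fraction`` of
    the grand total within the subset (default >0.1% of all sequences).

    Rare taxa are dropped from differential-abundance testing only; the
    beta-diversity analyses keep the full table.
    """
    grand = counts.counts.values.sum()
    if grand == 0:
        raise ValueError("empty count table")
    keep = counts.counts.sum(axis=0) > min_fraction * grand
    if not keep.any():
        logger.warning("no taxa exceed %.3g of the grand total", min_fraction)
    return CountTable(counts.counts.loc[:, keep], counts.metadata)


def add_sum_taxon(counts: CountTable,
                  totals: pd.Series | None = None) -> CountTable:
    """Append the artificial "sum" taxon: each sample's total count.

    ``totals`` should be the *pre-filter* per-sample totals so the
    normalizer reflects true sequencing depth; by default the table's
    own row sums are used. Zero-total samples are excluded with a
    warning.
    """
    mat = counts.counts.copy()
    if totals is None:
        totals = mat.sum(axis=1)
    mat[SUM_TAXON] = totals.loc[mat.index].astype(int)
    keep = mat[SUM_TAXON] > 0
    if (~keep).any():
        logger.warning("excluding %d zero-total samples from the model",
                       int((~keep).sum()))
        mat = mat.loc[keep]
    return CountTable(mat, counts.metadata.loc[mat.index])


# ---------------------------------------------------------------------------
# model specification and posterior containers


@dataclass
class PlnModelSpec:
    """MCMC controls and priors for the Poisson-lognormal model.

    Fixed effects get Normal(0, ``prior_sd_fixed``^2) priors on the log
    scale; the random-effect standard deviations get half-Cauchy priors
    with scale ``prior_scale_sd``.
    """

    iterations: int = 15_000
    burn_in: int = 5_000
    thin: int = 10
    seed: int | None = None
    prior_sd_fixed: float = 10.0
    prior_scale_sd: float = 2.5
    reference_pool: int = 400

    def __post_init__(self):
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_draws(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class PlnPosterior:
    """Thinned post-burn-in draws and chain diagnostics."""

    taxa: list[str]
    pools: tuple[int, int]  # (reference, contrast)
    alpha: np.ndarray  # draws x taxa
    beta: np.ndarray  # draws x taxa
    sigma_u: np.ndarray
    sigma_eps: np.ndarray
    acceptance: dict[str, float]
    spec: PlnModelSpec

    def diagnostics(self) -> pd.DataFrame:
        """Split-Rhat and autocorrelation-based effective sample size of
        each taxon's between-pool contrast (beta_t - beta_sum)."""
        k = self.taxa.index(SUM_TAXON)
        delta = self.beta - self.beta[:, [k]]
        rows = []
        for i, taxon in enumerate(self.taxa):
            x = delta[:, i]
            rows.append({"taxon": taxon,
                         "ess": _effective_size(x),
                         "split_rhat": _split_rhat(x)})
        return pd.DataFrame(rows).set_index("taxon")


def _split_rhat(x: np.ndarray) -> float:
    half = len(x) // 2
    a, b = x[:half], x[half:2 * half]
    w = (a.var(ddof=1) + b.var(ddof=1)) / 2
    if w == 0:
        return 1.0
    mean_all = np.concatenate([a, b]).mean()
    bvar = half * ((a.mean() - mean_all) ** 2 + (b.mean() - mean_all) ** 2)
    var_hat = (half - 1) / half * w + bvar / half
    return float(math.sqrt(var_hat / w))


def _effective_size(x: np.ndarray) -> float:
    n = len(x)
    x = x - x.mean()
    v = np.dot(x, x) / n
    if v == 0:
        return float(n)
    rho_sum = 0.0
    for lag in range(1, n // 2):
        rho = np.dot(x[:-lag], x[lag:]) / ((n - lag) * v)
        if rho < 0.05:
            break
        rho_sum += rho
    return float(n / (1 + 2 * rho_sum))


# ---------------------------------------------------------------------------
# sampler


def fit_pln(counts: CountTable, spec: PlnModelSpec | None = None) -> PlnPosterior:
    """Fit the Poisson-lognormal model to a count table that includes
    the "sum" taxon, with pool as the only fixed factor.

    Deterministic given ``spec.seed``. Raises on non-integer counts or
    when a pool has fewer than two samples.
    """
    spec = spec or PlnModelSpec()
    if SUM_TAXON not in counts.taxa:
        raise ValueError('count table must include the "sum" taxon '
                         "(see add_sum_taxon)")
    y_df = counts.counts
    if not np.issubdtype(y_df.values.dtype, np.integer):
        raise ValueError("counts must be integers")
    pools = sorted(counts.metadata["pool"].unique())
    if len(pools) != 2:
        raise ValueError(f"need exactly two pools, got {pools}")
    ref = spec.reference_pool if spec.reference_pool in pools else pools[0]
    other = [p for p in pools if p != ref][0]
    x = (counts.metadata["pool"] == other).to_numpy(float)
    for p in pools:
        if (counts.metadata["pool"] == p).sum() < 2:
            raise ValueError(f"pool {p} has fewer than 2 samples")

    y = y_df.to_numpy(float)
    S, T = y.shape
    rng = np.random.default_rng(spec.seed)

    # initial values from crude moment estimates
    col_mean = np.maximum(y.mean(axis=0), 0.5)
    alpha = np.log(col_mean)
    beta = np.zeros(T)
    row_factor = np.maximum(y.sum(axis=1), 1.0)
    u = np.log(row_factor / row_factor.mean())
    eps = np.zeros((S, T))
    log_su, log_se = math.log(max(u.std(), 0.1)), math.log(0.3)

    # proposal scales (log), adapted during burn-in
    s_alpha = np.full(T, -1.5)
    s_beta = np.full(T, -1.5)
    s_u = np.full(S, -1.5)
    s_eps = np.full(T, -1.5)  # shared per taxon across samples
    s_su = s_se = -1.0
    post_acc = {k: 0.0 for k in ("alpha", "beta", "u", "eps")}
    n_post = 0

    prior_var = spec.prior_sd_fixed ** 2
    hc = spec.prior_scale_sd
    xcol = x[:, None]
    eta = alpha[None, :] + beta[None, :] * xcol + u[:, None] + eps

    def pois_delta(eta_new, eta_old, ysub):
        return ysub * (eta_new - eta_old) - (
            np.exp(np.clip(eta_new, -50, 50)) -
            np.exp(np.clip(eta_old, -50, 50)))

    n_keep = spec.n_draws
    alpha_draws = np.empty((n_keep, T))
    beta_draws = np.empty((n_keep, T))
    su_draws = np.empty(n_keep)
    se_draws = np.empty(n_keep)
    kept = 0
    adapt_every = 50
    batch_acc = {k: np.zeros_like(v) for k, v in
                 (("alpha", s_alpha), ("beta", s_beta), ("u", s_u),
                  ("eps", s_eps))}
    batch_sigma = np.zeros(2)

    for it in range(spec.iterations):
        se2 = math.exp(2 * log_se)
        su2 = math.exp(2 * log_su)

        # eps: elementwise, proposal scale shared within taxon
        step = np.exp(s_eps)[None, :]
        prop = eps + step * rng.standard_normal((S, T))
        eta_p = eta + (prop - eps)
        dlog = pois_delta(eta_p, eta, y) - (prop ** 2 - eps ** 2) / (2 * se2)
        take = np.log(rng.random((S, T))) < dlog
        eps = np.where(take, prop, eps)
        eta = np.where(take, eta_p, eta)
        batch_acc["eps"] += take.mean(axis=0)
        if it >= spec.burn_in:
            post_acc["eps"] += take.mean()

        # u: per sample
        du = np.exp(s_u) * rng.standard_normal(S)
        eta_p = eta + du[:, None]
        dlog = pois_delta(eta_p, eta, y).sum(axis=1) - (
            (u + du) ** 2 - u ** 2) / (2 * su2)
        take = np.log(rng.random(S)) < dlog
        u = np.where(take, u + du, u)
        eta = np.where(take[:, None], eta_p, eta)
        batch_acc["u"] += take
        if it >= spec.burn_in:
            post_acc["u"] += take.mean()

        # alpha: per taxon
        da = np.exp(s_alpha) * rng.standard_normal(T)
        eta_p = eta + da[None, :]
        dlog = pois_delta(eta_p, eta, y).sum(axis=0) - (
            (alpha + da) ** 2 - alpha ** 2) / (2 * prior_var)
        take = np.log(rng.random(T)) < dlog
        alpha = np.where(take, alpha + da, alpha)
        eta = np.where(take[None, :], eta_p, eta)
        batch_acc["alpha"] += take
        if it >= spec.burn_in:
            post_acc["alpha"] += take.mean()

        # beta: per taxon, only contrast-pool rows contribute
        db = np.exp(s_beta) * rng.standard_normal(T)
        eta_p = eta + db[None, :] * xcol
        dlog = pois_delta(eta_p, eta, y).sum(axis=0) - (
            (beta + db) ** 2 - beta ** 2) / (2 * prior_var)
        take = np.log(rng.random(T)) < dlog
        beta = np.where(take, beta + db, beta)
        eta = np.where(take[None, :], eta_p, eta)
        batch_acc["beta"] += take
        if it >= spec.burn_in:
            post_acc["beta"] += take.mean()
            n_post += 1

        # variance components: random walk on log sd, half-Cauchy prior
        def sd_logpost(lam, ssq, count):
            sd = math.exp(lam)
            return (-count * lam - ssq / (2 * sd * sd)
                    - math.log1p((sd / hc) ** 2) + lam)

        ssq_u = float(np.dot(u, u))
        prop_lam = log_su + math.exp(s_su) * rng.standard_normal()
        if math.log(rng.random()) < (sd_logpost(prop_lam, ssq_u, S)
                                     - sd_logpost(log_su, ssq_u, S)):
            log_su = prop_lam
            batch_sigma[0] += 1
        ssq_e = float(np.sum(eps * eps))
        prop_lam = log_se + math.exp(s_se) * rng.standard_normal()
        if math.log(rng.random()) < (sd_logpost(prop_lam, ssq_e, S * T)
                                     - sd_logpost(log_se, ssq_e, S * T)):
            log_se = prop_lam
            batch_sigma[1] += 1

        # adapt proposal scales during burn-in
        if it < spec.burn_in and (it + 1) % adapt_every == 0:
            gain = min(0.1, 10.0 / math.sqrt(it + 1))
            for key, scale in (("alpha", s_alpha), ("beta", s_beta),
                               ("u", s_u), ("eps", s_eps)):
                rate = batch_acc[key] / adapt_every
                scale += np.where(rate > 0.44, gain, -gain)
                batch_acc[key][:] = 0
            rate = batch_sigma / adapt_every
            s_su += gain if rate[0] > 0.44 else -gain
            s_se += gain if rate[1] > 0.44 else -gain
            batch_sigma[:] = 0

        if it >= spec.burn_in:
            if (it - spec.burn_in) % spec.thin == 0 and kept < n_keep:
                alpha_draws[kept] = alpha
                beta_draws[kept] = beta
                su_draws[kept] = math.exp(log_su)
                se_draws[kept] = math.exp(log_se)
                kept += 1

    return PlnPosterior(
        taxa=list(y_df.columns),
        pools=(ref, other),
        alpha=alpha_draws[:kept],
        beta=beta_draws[:kept],
        sigma_u=su_draws[:kept],
        sigma_eps=se_draws[:kept],
        acceptance={k: v / max(n_post, 1) for k, v in post_acc.items()},
        spec=spec,
    )


# ---------------------------------------------------------------------------
# summaries


@dataclass
class DiffAbundResult:
    """Per-taxon posterior summaries and significance flags."""

    table: pd.DataFrame
    q: float
    pools: tuple[int, int]

    @property
    def significant_taxa(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def summarize_diff(posterior: PlnPosterior, q: float = 0.1) -> DiffAbundResult:
    """Summarize a fitted model into per-taxon relative abundances,
    fold-changes, z-scores, and BH-adjusted significance at FDR ``q``.

    Relative abundance in a pool is exp(eta_taxon - eta_sum) at that
    pool's fixed effects; the fold-change is the contrast pool's
    abundance over the reference pool's. Point estimates are posterior
    means on the log scale (geometric means), with 2.5/97.5 percentile
    credible limits. The Bayesian z-score is |mean|/sd of the log
    fold-change draws, with two-sided normal p-values.
    """
    if posterior.alpha.shape[0] < 200:
        raise ValueError("need at least 200 retained draws to summarize")
    taxa = posterior.taxa
    k = taxa.index(SUM_TAXON)
    ref, other = posterior.pools
    log_rel_ref = posterior.alpha - posterior.alpha[:, [k]]
    log_rel_other = log_rel_ref + posterior.beta - posterior.beta[:, [k]]
    delta = posterior.beta - posterior.beta[:, [k]]  # log fold (other/ref)

    rows = []
    for i, taxon in enumerate(taxa):
        if taxon == SUM_TAXON:
            continue
        d = delta[:, i]
        sd = d.std(ddof=1)
        if sd == 0:
            logger.warning("degenerate posterior for %s; p set to 1", taxon)
            z, p = 0.0, 1.0
        else:
            z = abs(d.mean()) / sd
            p = 2 * (1 - norm.cdf(z))
        rows.append({
            "taxon": taxon,
            f"relabund_{other}": math.exp(log_rel_other[:, i].mean()),
            f"relabund_{other}_lo": math.exp(
                np.percentile(log_rel_other[:, i], 2.5)),
            f"relabund_{other}_hi": math.exp(
                np.percentile(log_rel_other[:, i], 97.5)),
            f"relabund_{ref}": math.exp(log_rel_ref[:, i].mean()),
            f"relabund_{ref}_lo": math.exp(np.percentile(log_rel_ref[:, i], 2.5)),
            f"relabund_{ref}_hi": math.exp(np.percentile(log_rel_ref[:, i], 97.5)),
            "fold_change": math.exp(d.mean()),
            "fold_change_lo": math.exp(np.percentile(d, 2.5)),
            "fold_change_hi": math.exp(np.percentile(d, 97.5)),
            "z": z,
            "p": p,
        })
    table = pd.DataFrame(rows).set_index("taxon")
    table["p_adj"] = false_discovery_control(table["p"].to_numpy(), method="bh")
    table["significant"] = table["p_adj"] <= q
    return DiffAbundResult(table, q, posterior.pools)
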