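"""Hypothesis testing on calibrated abundances and yield-coefficient
modelling.

All count models here are negative binomial with mean scaled by the
per-library calibration: a transcript's expected count in library j is
``nu_j * delta_j * mu``, with mu the nominal abundance the model predicts
for that library's condition.  Because nu_j anchors counts to absolute
spike-in amounts, tests on these means detect genuine changes in RNA per
cell — including global amplification that size-factor normalisations
assuming a fixed transcriptome silently remove.

Growth-rate designs model the mean nominal abundance as
``exp(phi0 + phi1 * (gamma - mean gamma))``; phi1 is the exponential rate
constant per unit growth rate, so the fold change between growth rates is
``exp(phi1 * (gamma_hi - gamma_lo))``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._nbglm import nb_glm_fit, nb_logpmf, nb_ml_mean
from .calibration import EstimationError
from .data_model import ValidationError

logger = logging.getLogger("spikecal")


# ----------------------------------------------------------------------
# exponential growth-rate response
# ----------------------------------------------------------------------
@dataclass
class GrowthFit:
    """Per-transcript exponential growth-rate fits.

    ``phi0`` is log mean nominal abundance at the centred growth rate;
    ``phi1`` the exponential rate constant (h per unit growth rate).
    ``lrt`` is the likelihood-ratio statistic against phi1 = 0 and
    ``p_chi2`` its chi-squared(1) asymptotic p-value.  Empirical
    (parametric-bootstrap) p-values are added by
    :func:`empirical_pvalues`.
    """

    phi0: np.ndarray
    phi1: np.ndarray
    loglik: np.ndarray
    loglik_null: np.ndarray
    lrt: np.ndarray
    p_chi2: np.ndarray
    gamma: np.ndarray
    gamma_bar: float
    p_empirical: np.ndarray | None = None
    q_values: np.ndarray | None = None


def _growth_design(gamma: np.ndarray) -> tuple[np.ndarray, float]:
    gamma = np.asarray(gamma, dtype=float)
    if np.unique(gamma).size < 2:
        raise ValidationError("growth-rate fit needs >= 2 distinct growth rates")
    gbar = float(gamma.mean())
    x = np.column_stack([np.ones_like(gamma), gamma - gbar])
    return x, gbar


def fit_growth_model(
    counts: np.ndarray, gamma: np.ndarray, scales: np.ndarray, a: float
) -> GrowthFit:
    """ML fit of NB counts with mean ``scale_j * exp(phi0 + phi1 (gamma_j -
    gamma_bar))`` and known shape, per transcript (rows of ``counts``).

    The likelihood-ratio statistic against the flat model (phi1 = 0) is
    computed for every transcript; both models are fitted by Fisher
    scoring on the NB log-likelihood.
    """
    y = np.atleast_2d(np.asarray(counts, dtype=float))
    scales = np.asarray(scales, dtype=float)
    if np.any(scales <= 0):
        raise ValidationError("library scales (nu*delta) must be positive")
    if a <= 0:
        raise ValidationError("shape a must be positive")
    x, gbar = _growth_design(gamma)
    offset = np.log(scales)
    beta, ll = nb_glm_fit(y, x, offset, a)
    mu0 = nb_ml_mean(y, scales, a)  # null (flat) model, closed profile
    ll0 = nb_logpmf(y, mu0[:, None] * scales, a).sum(axis=1)
    lrt = np.maximum(2.0 * (ll - ll0), 0.0)
    return GrowthFit(
        phi0=beta[:, 0],
        phi1=beta[:, 1],
        loglik=ll,
        loglik_null=ll0,
        lrt=lrt,
        p_chi2=stats.chi2.sf(lrt, df=1),
        gamma=np.asarray(gamma, dtype=float),
        gamma_bar=gbar,
    )


def fold_change_from_phi(phi1: float, gamma_lo: float, gamma_hi: float) -> float:
    """Fold change in mean abundance between two growth rates implied by
    the exponential model: ``exp(phi1 * (gamma_hi - gamma_lo))``."""
    if gamma_hi <= gamma_lo:
        raise ValidationError("gamma_hi must exceed gamma_lo")
    return float(np.exp(np.asarray(phi1, dtype=float) * (gamma_hi - gamma_lo)))


def empirical_pvalues(
    counts: np.ndarray,
    gamma: np.ndarray,
    scales: np.ndarray,
    a: float,
    null_sims: int = 1000,
    seed: int | None = None,
    fit: GrowthFit | None = None,
) -> GrowthFit:
    """Parametric-bootstrap p-values for the growth-rate dependence.

    For each transcript, counts are regenerated ``null_sims`` times from
    the fitted flat model (NB, same scales and shape); both models are
    refitted on each replicate and
    ``p = (1 + #{LRT_sim >= LRT_obs}) / (null_sims + 1)``.
    The chi-squared(1) asymptotic p-value remains available as
    ``p_chi2``.
    """
    if null_sims < 1:
        raise ValidationError("null_sims must be >= 1")
    y = np.atleast_2d(np.asarray(counts, dtype=float))
    scales = np.asarray(scales, dtype=float)
    if fit is None:
        fit = fit_growth_model(y, gamma, scales, a)
    x, _ = _growth_design(gamma)
    offset = np.log(scales)
    rng = np.random.default_rng(seed)
    mu0 = nb_ml_mean(y, scales, a)
    p_emp = np.empty(y.shape[0])
    for i in range(y.shape[0]):
        m0 = np.maximum(mu0[i] * scales, 1e-12)
        lam = rng.gamma(a, np.broadcast_to(m0 / a, (null_sims, m0.size)))
        ysim = rng.poisson(lam).astype(float)
        _, ll_full = nb_glm_fit(ysim, x, offset, a)
        mu0_sim = nb_ml_mean(ysim, scales, a)
        ll_null = nb_logpmf(ysim, mu0_sim[:, None] * scales, a).sum(axis=1)
        lrt_sim = np.maximum(2.0 * (ll_full - ll_null), 0.0)
        p_emp[i] = (1.0 + np.sum(lrt_sim >= fit.lrt[i])) / (null_sims + 1.0)
    fit.p_empirical = p_emp
    return fit


# ----------------------------------------------------------------------
# multiple testing
# ----------------------------------------------------------------------
def bh_fdr(pvals: np.ndarray, q: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and significance calls at
    FDR level ``q``."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    reject, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, reject


# ----------------------------------------------------------------------
# pairwise differential abundance
# ----------------------------------------------------------------------
@dataclass
class DEResult:
    """Per-transcript NB likelihood-ratio test of equal scaled means
    between two conditions.  ``fold_change`` is fitted mean of group 2
    over group 1 (on the calibrated, per-cell scale); excluded transcripts
    (all-zero in both groups) carry NaN."""

    groups: tuple[str, str]
    mean1: np.ndarray
    mean2: np.ndarray
    fold_change: np.ndarray
    log2_fold_change: np.ndarray
    lrt: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray
    significant: np.ndarray
    direction: np.ndarray  # +1 up in group 2, -1 down, 0 excluded/flat
    excluded: np.ndarray


def nb_pairwise_test(
    counts: np.ndarray,
    scales: np.ndarray,
    groups,
    a,
    q: float = 0.01,
    group_order: tuple[str, str] | None = None,
) -> DEResult:
    """Two-condition differential-abundance test on calibrated counts.

    ``scales`` are the per-library size factors (nu_j * delta_j, or the
    median size factors for the comparison mode); ``a`` is a scalar shape
    or a mapping condition -> shape.  Per transcript, the NB likelihood
    ratio compares a common scaled mean against group-specific means;
    p-values are chi-squared(1), q-values Benjamini-Hochberg.
    """
    y = np.atleast_2d(np.asarray(counts, dtype=float))
    scales = np.asarray(scales, dtype=float)
    groups = np.asarray(groups)
    labels = (
        list(group_order) if group_order is not None else list(dict.fromkeys(groups))
    )
    if len(labels) != 2 or set(labels) != set(np.unique(groups)):
        raise ValidationError("exactly two conditions required")
    g1 = groups == labels[0]
    g2 = groups == labels[1]
    if g1.sum() < 2 or g2.sum() < 2:
        raise ValidationError("need >= 2 libraries per condition")
    if isinstance(a, dict):
        a_vec = np.where(g1, a[labels[0]], a[labels[1]]).astype(float)
    else:
        a_vec = np.full(y.shape[1], float(a))
    if np.any(a_vec <= 0):
        raise ValidationError("shape a must be positive")

    mu1 = nb_ml_mean(y[:, g1], scales[g1], a_vec[g1])
    mu2 = nb_ml_mean(y[:, g2], scales[g2], a_vec[g2])
    mu_null = nb_ml_mean(y, scales, a_vec)
    ll_alt = nb_logpmf(y[:, g1], mu1[:, None] * scales[g1], a_vec[g1]).sum(
        axis=1
    ) + nb_logpmf(y[:, g2], mu2[:, None] * scales[g2], a_vec[g2]).sum(axis=1)
    ll_null = nb_logpmf(y, mu_null[:, None] * scales, a_vec).sum(axis=1)
    lrt = np.maximum(2.0 * (ll_alt - ll_null), 0.0)

    excluded = y.sum(axis=1) == 0
    pvals = np.where(excluded, np.nan, stats.chi2.sf(lrt, df=1))
    qvals = np.full_like(pvals, np.nan)
    sig = np.zeros(pvals.shape, dtype=bool)
    if np.any(~excluded):
        qvals[~excluded], sig[~excluded] = bh_fdr(pvals[~excluded], q=q)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(excluded, np.nan, mu2 / mu1)
        l2fc = np.log2(fc)
    direction = np.zeros(pvals.shape)
    direction[~excluded & (mu2 > mu1)] = 1.0
    direction[~excluded & (mu2 < mu1)] = -1.0
    return DEResult(
        groups=(labels[0], labels[1]),
        mean1=mu1,
        mean2=mu2,
        fold_change=fc,
        log2_fold_change=l2fc,
        lrt=lrt,
        p_values=pvals,
        q_values=qvals,
        significant=sig,
        direction=direction,
        excluded=excluded,
    )


def median_size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors: ``s_j = median_i y_ij / (prod_k
    y_ik)^{1/r}`` over transcripts with all-positive counts.

    These dimensionless factors implicitly assume a fixed total
    transcriptome; they are provided only for comparison with the
    spike-in anchored calibration.
    """
    y = np.atleast_2d(np.asarray(counts, dtype=float))
    pos = np.all(y > 0, axis=1)
    if not np.any(pos):
        raise EstimationError("no transcript has all-positive counts")
    logy = np.log(y[pos])
    log_gm = logy.mean(axis=1, keepdims=True)
    return np.exp(np.median(logy - log_gm, axis=0))


# ----------------------------------------------------------------------
# relative-yield model
# ----------------------------------------------------------------------
@dataclass
class YieldFit:
    """Log-linear model of relative yields on physical covariates.

    ``beta`` is (intercept, length, GC, folding energy); ``nrmse_range``
    and ``nrmse_sd`` are the RMSE of fitted vs observed alpha normalised
    by range(alpha) and sd(alpha) respectively."""

    beta: np.ndarray
    fitted_alpha: np.ndarray
    nrmse_range: float
    nrmse_sd: float
    condition_number: float


def fit_yield_model(
    alpha: np.ndarray,
    length_nt: np.ndarray,
    gc_fraction: np.ndarray,
    folding_energy: np.ndarray,
    weights: np.ndarray | None = None,
    scale_covariates: bool = False,
) -> YieldFit:
    """Fit ``ln alpha = b0 + b1*length + b2*GC + b3*energy`` by (weighted)
    least squares.

    Under the multinomial model Var(ln alpha_i) is approximately the
    reciprocal of spike-in i's total count, so passing row count totals as
    ``weights`` gives the ML weighting.  ``scale_covariates`` standardises
    the covariates (coefficients then per sd).  A large design condition
    number is reported and warned about, not fatal.
    """
    alpha = np.asarray(alpha, dtype=float)
    if alpha.size < 10:
        raise ValidationError("need >= 10 spike-ins to fit the yield model")
    if np.any(alpha <= 0):
        raise ValidationError("alpha values must be positive")
    cov = np.column_stack(
        [np.asarray(v, dtype=float) for v in (length_nt, gc_fraction, folding_energy)]
    )
    if scale_covariates:
        cov = (cov - cov.mean(axis=0)) / cov.std(axis=0)
    x = np.column_stack([np.ones(alpha.size), cov])
    cond = float(np.linalg.cond(x))
    if cond > 1e8:
        logger.warning("yield-model design is ill-conditioned (cond=%.3g)", cond)
    import statsmodels.api as sm

    w = np.ones(alpha.size) if weights is None else np.asarray(weights, dtype=float)
    model = sm.WLS(np.log(alpha), x, weights=w).fit()
    fitted = np.exp(model.fittedvalues)
    rmse = float(np.sqrt(np.mean((fitted - alpha) ** 2)))
    rng_ = float(alpha.max() - alpha.min())
    sd = float(alpha.std())
    return YieldFit(
        beta=np.asarray(model.params),
        fitted_alpha=fitted,
        nrmse_range=rmse / rng_ if rng_ > 0 else 0.0,
        nrmse_sd=rmse / sd if sd > 0 else 0.0,
        condition_number=cond,
    )
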