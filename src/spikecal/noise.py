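"""Count-noise models and the synthetic-data generator.

Spike-in counts within a library are one multinomial draw with proportions
shared across libraries (so the marginal count of each spike-in is
binomial).  Native-RNA counts compound gamma-distributed biological
variation in abundance with Poisson sampling, giving negative-binomial
counts with variance mu + mu^2/a.  This module provides the model-predicted
counts and quantile bands, closed-form CV^2 curves for both models, shape
estimation by profile likelihood, and a generator that emulates a full
study: an ERCC-like annotation (92 molecules at 22 abundance levels
spanning ~10^6-fold), multinomial spike-in counts with known relative
yields, NB native counts with condition-dependent means, and injected
per-library preparation errors delta.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from ._nbglm import nb_logpmf, nb_ml_mean
from .data_model import (
    NATIVE,
    SPIKEIN,
    CountMatrix,
    LibraryMeta,
    SpikeInAnnotation,
    ValidationError,
)

logger = logging.getLogger("spikecal")

#: Shape values at or above this cap are reported as Poisson-like.
SHAPE_CAP = 1e4
_SHAPE_FLOOR = 1e-2


class ShapeEstimationError(ValidationError):
    pass


# ----------------------------------------------------------------------
# multinomial model predictions and bands
# ----------------------------------------------------------------------
def predict_spikein_counts(f: np.ndarray, l_si) -> np.ndarray:
    """Model-expected spike-in counts ``yhat_ij = f_i * L_j^SI``."""
    f = np.asarray(f, dtype=float)
    l_si = np.atleast_1d(np.asarray(l_si, dtype=float))
    return np.outer(f, l_si)


def binomial_band(p: float, total: int, coverage: float = 0.99) -> tuple[int, int]:
    """Mid-``coverage`` quantile band of a Binomial(total, p) count.

    Returns the largest L with P(Y < L) < (1-coverage)/2 and the smallest U
    with P(Y > U) < (1-coverage)/2 — the marginal band of one spike-in's
    count under the multinomial model.
    """
    if not 0 < p <= 1:
        raise ValidationError("p must lie in (0, 1]")
    if total < 1:
        raise ValidationError("total must be >= 1")
    tail = (1.0 - coverage) / 2.0
    if p == 1.0:
        return total, total
    dist = stats.binom(total, p)
    lo = int(dist.ppf(tail))  # smallest k with cdf(k) >= tail => P(Y<k) < tail
    hi = int(dist.ppf(1.0 - tail))
    while hi < total and dist.sf(hi) >= tail:
        hi += 1
    return lo, hi


def cv2_multinomial(p: float, l_vec) -> float:
    """Population CV^2 of normalised counts y_ij / L_j under the
    multinomial model: ``(1-p)/p * mean_j(1/L_j)``."""
    if not 0 < p <= 1:
        raise ValidationError("p must lie in (0, 1]")
    l_vec = np.asarray(l_vec, dtype=float)
    return (1.0 - p) / p * np.mean(1.0 / l_vec)


def cv2_negbin(p: float, l_vec, a: float) -> float:
    """CV^2 under the gamma-Poisson model: the multinomial sampling term
    plus the 1/a overdispersion floor."""
    if a <= 0:
        raise ValidationError("shape a must be positive")
    return cv2_multinomial(p, l_vec) + 1.0 / a


# ----------------------------------------------------------------------
# shape (dispersion) estimation
# ----------------------------------------------------------------------
def estimate_shape(
    counts: np.ndarray,
    scales: np.ndarray,
    cap: float = SHAPE_CAP,
) -> float:
    """Single shared NB shape for one condition by adjusted profile
    likelihood.

    ``counts``: transcripts x replicate-libraries (detection-filtered);
    ``scales``: per-library nu_j * delta_j.  For each candidate a the
    transcript means are profiled at their ML values given the scales; the
    summed log-likelihood carries a Cox-Reid adjustment (-1/2 log Fisher
    information of each profiled mean) that removes the overdispersion
    bias incurred by estimating one mean per transcript from few
    replicates.  The result is maximised over log a by 1-D bounded search.
    Estimates at the cap indicate Poisson-like (zero biological
    overdispersion) data and are returned as ``cap``.
    """
    y = np.atleast_2d(np.asarray(counts, dtype=float))
    c = np.asarray(scales, dtype=float)
    if y.shape[1] != c.size:
        raise ValidationError("one scale per library required")
    if y.shape[1] < 2:
        raise ValidationError("shape estimation needs >= 2 replicate libraries")
    if np.any(c <= 0):
        raise ValidationError("scales must be positive")

    def neg_profile_ll(log_a: float) -> float:
        a = np.exp(log_a)
        mu = nb_ml_mean(y, c, a)
        m = np.maximum(mu[:, None] * c, 1e-12)
        ll = float(nb_logpmf(y, m, a).sum())
        # Cox-Reid: -1/2 log I(log mu_hat) per transcript with a fitted mean
        info = (a * m / (m + a)).sum(axis=1)
        ll -= 0.5 * float(np.log(np.maximum(info, 1e-300))[mu > 0].sum())
        return -ll

    res = optimize.minimize_scalar(
        neg_profile_ll,
        bounds=(np.log(_SHAPE_FLOOR), np.log(cap)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    if not res.success:
        raise ShapeEstimationError(f"shape optimisation failed: {res}")
    a_hat = float(np.exp(res.x))
    if a_hat >= cap * (1.0 - 1e-3):
        return cap
    return a_hat


# ----------------------------------------------------------------------
# ERCC-like spike-in mixes
# ----------------------------------------------------------------------
def ercc_like_annotation(
    rng: np.random.Generator,
    n_molecules: int = 92,
    n_levels: int = 22,
    max_amol: float = 3000.0,
    span: float = 3.0e6,
) -> SpikeInAnnotation:
    """Annotation emulating ERCC mix 1: ``n_molecules`` synthetic RNAs at
    ``n_levels`` abundance levels on a geometric ladder spanning ``span``-
    fold (mix concentrations 30,000 down to 0.01 amol/uL; ``max_amol`` is
    the amount of the top level actually added per sample).

    Covariates mimic the real mix: lengths 250-2000 nt, GC 0.3-0.7,
    folding energies roughly proportional to length and negative.
    """
    levels = max_amol * span ** (-np.arange(n_levels) / (n_levels - 1))
    level_of = np.arange(n_molecules) % n_levels
    n_amol = levels[level_of]
    length = rng.integers(250, 2001, size=n_molecules).astype(float)
    gc = rng.uniform(0.30, 0.70, size=n_molecules)
    energy = -length * (0.15 + 0.35 * gc) + rng.normal(0.0, 10.0, n_molecules)
    energy = np.minimum(energy, -1.0)
    return SpikeInAnnotation(
        molecule_ids=[f"SYN-{i:05d}" for i in range(1, n_molecules + 1)],
        n_amol=n_amol,
        length_nt=length,
        gc_fraction=gc,
        folding_energy=energy,
    )


# ----------------------------------------------------------------------
# synthetic study generator
# ----------------------------------------------------------------------
@dataclass
class SimulationConfig:
    """Design of a synthetic spike-in calibration study.

    Defaults emulate the yeast chemostat growth-rate study: three
    conditions in biological triplicate, 10^7 cells per sample, 92
    spike-ins at 22 levels, spike-in libraries of ~5x10^5 reads,
    log-normal relative yields, library-preparation errors with
    log-sd 0.15, and NB biological noise with shape 25.
    """

    conditions: tuple[str, ...] = ("c1", "c2", "c3")
    replicates: int = 3
    n_spikeins: int = 92
    n_levels: int = 22
    n_transcripts: int = 3000
    l_si: float = 5.0e5
    l_si_jitter: float = 0.15  # log-sd of per-library spike-in library size
    alpha_log_sd: float = 0.5
    delta_log_sd: float = 0.15
    shape: float = 25.0
    cells: float = 1.0e7
    #: log-normal distribution of per-transcript mean molecules per cell
    mean_log_mpc: float = np.log(10.0)
    sd_log_mpc: float = 1.5
    #: optional growth-rate design: gamma (1/h) per condition; when set,
    #: per-transcript means scale as exp(phi1 * (gamma - mean gamma))
    gamma: dict[str, float] | None = None
    phi1_sd: float = 0.0  # sd of per-transcript phi1 when gamma is set
    phi1_mean: float = 0.0
    #: optional global per-condition fold change applied to every transcript
    condition_fold: dict[str, float] | None = None


@dataclass
class SyntheticDataset:
    """A realised synthetic study plus its generating truth."""

    config: SimulationConfig
    seed: int
    spikein_counts: CountMatrix
    native_counts: CountMatrix
    annotation: SpikeInAnnotation
    library_meta: dict[str, LibraryMeta]
    alpha_true: np.ndarray
    delta_true: np.ndarray
    mu_true: np.ndarray  # transcripts x conditions, mean nominal amol
    nu_true: np.ndarray
    phi1_true: np.ndarray | None = None
    truth_extra: dict = field(default_factory=dict)


def simulate_dataset(config: SimulationConfig, seed: int) -> SyntheticDataset:
    """Generate one synthetic study under the full statistical model.

    Draw order (fixed for reproducibility): annotation covariates, relative
    yields alpha, library sizes, per-library spike-in multinomials
    (library by library), transcript means, per-transcript phi1 (if a
    growth design), delta errors, then native NB counts via the
    gamma-Poisson concatenation, library by library.
    """
    rng = np.random.default_rng(seed)
    cfg = config
    n_lib = len(cfg.conditions) * cfg.replicates
    if n_lib == 0 or cfg.n_spikeins == 0:
        raise ValidationError("design must have at least one library and spike-in")
    lib_ids = [
        f"{cond}_r{r + 1}" for cond in cfg.conditions for r in range(cfg.replicates)
    ]
    cond_of = np.repeat(np.arange(len(cfg.conditions)), cfg.replicates)

    annotation = ercc_like_annotation(rng, cfg.n_spikeins, cfg.n_levels)
    alpha = rng.lognormal(0.0, cfg.alpha_log_sd, cfg.n_spikeins)
    p = alpha * annotation.n_amol
    p /= p.sum()

    l_si = np.round(
        cfg.l_si * rng.lognormal(0.0, cfg.l_si_jitter, n_lib)
    ).astype(np.int64)
    si_counts = np.empty((cfg.n_spikeins, n_lib), dtype=np.int64)
    for j in range(n_lib):
        si_counts[:, j] = rng.multinomial(l_si[j], p)

    # per-transcript baseline abundance, molecules per cell -> amol/sample
    mpc = rng.lognormal(cfg.mean_log_mpc, cfg.sd_log_mpc, cfg.n_transcripts)
    from .data_model import molecules_per_cell_to_amol

    base_amol = np.asarray(molecules_per_cell_to_amol(mpc, cfg.cells), dtype=float)

    gammas = None
    phi1 = None
    mu_cond = np.tile(base_amol[:, None], (1, len(cfg.conditions)))
    if cfg.gamma is not None:
        gammas = np.array([cfg.gamma[c] for c in cfg.conditions], dtype=float)
        phi1 = rng.normal(cfg.phi1_mean, cfg.phi1_sd, cfg.n_transcripts)
        mu_cond = base_amol[:, None] * np.exp(
            phi1[:, None] * (gammas - gammas.mean())[None, :]
        )
    if cfg.condition_fold is not None:
        folds = np.array([cfg.condition_fold.get(c, 1.0) for c in cfg.conditions])
        mu_cond = mu_cond * folds[None, :]

    delta = rng.lognormal(0.0, cfg.delta_log_sd, n_lib)

    # true calibration constants implied by the spike-in model
    ref = int(np.argmax(p))
    nu = p[ref] * l_si.astype(float) / annotation.n_amol[ref]

    native = np.empty((cfg.n_transcripts, n_lib), dtype=np.int64)
    a = cfg.shape
    for j in range(n_lib):
        mean_j = mu_cond[:, cond_of[j]] * nu[j] * delta[j]
        lam = rng.gamma(a, mean_j / a)  # biological abundance noise
        native[:, j] = rng.poisson(lam)  # sequencing sampling noise

    meta = {}
    for j, lib in enumerate(lib_ids):
        cond = cfg.conditions[cond_of[j]]
        meta[lib] = LibraryMeta(
            condition=cond,
            growth_rate=None if gammas is None else float(gammas[cond_of[j]]),
            cells=cfg.cells,
        )

    si_cm = CountMatrix(
        molecule_ids=list(annotation.molecule_ids),
        library_ids=lib_ids,
        counts=si_counts,
        molecule_class=np.full(cfg.n_spikeins, SPIKEIN, dtype=object),
        library_meta=meta,
    )
    rna_cm = CountMatrix(
        molecule_ids=[f"gene-{i:05d}" for i in range(1, cfg.n_transcripts + 1)],
        library_ids=lib_ids,
        counts=native,
        molecule_class=np.full(cfg.n_transcripts, NATIVE, dtype=object),
        library_meta=meta,
    )
    return SyntheticDataset(
        config=cfg,
        seed=seed,
        spikein_counts=si_cm,
        native_counts=rna_cm,
        annotation=annotation,
        library_meta=meta,
        alpha_true=alpha,
        delta_true=delta,
        mu_true=mu_cond,
        nu_true=nu,
        phi1_true=phi1,
        truth_extra={"p": p, "l_si": l_si, "reference_index": ref},
    )
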