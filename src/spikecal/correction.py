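"""Library-preparation error correction (delta) and diagnostics (RLE, MA).

Within a condition the expected abundance of every transcript is constant,
so residual per-library scale differences in calibrated abundances reflect
library-preparation errors: pipetting and dilution of the spike-in aliquot,
cell-count error, RNA-extraction efficiency.  A per-library multiplicative
factor delta_j absorbs them: corrected abundances are z_ij / delta_j.
delta_j is a median-of-ratios within the library's condition, rescaled so
the within-condition geometric mean of delta is exactly 1 (a condition with
a single library gets delta = 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_model import ValidationError

logger = logging.getLogger("spikecal")


@dataclass
class DiagnosticsTables:
    """RLE matrix (natural-log scale, per-row median removed), per-library
    RLE medians, and an (A, M) table for a two-group comparison."""

    rle: np.ndarray | None = None
    rle_medians: np.ndarray | None = None
    ma: np.ndarray | None = None  # columns (A, M)
    n_excluded: int = 0


def compute_delta(z_tilde: np.ndarray, conditions) -> np.ndarray:
    """Per-library correction factors from pseudocounted abundances.

    For each condition: g_i = geometric mean of z~_i over the condition's
    libraries; delta_j = median_i (z~_ij / g_i); then delta is rescaled so
    its geometric mean over the condition's libraries is 1.

    ``z_tilde`` must be strictly positive (apply the +1 pseudocount and the
    detection filter first); ``conditions`` is one label per column.
    """
    z_tilde = np.asarray(z_tilde, dtype=float)
    if np.any(z_tilde <= 0) or not np.all(np.isfinite(z_tilde)):
        raise ValidationError("delta estimation needs strictly positive abundances")
    conditions = np.asarray(conditions)
    if conditions.shape != (z_tilde.shape[1],):
        raise ValidationError("one condition label per library required")
    delta = np.ones(z_tilde.shape[1])
    logz = np.log(z_tilde)
    for cond in np.unique(conditions):
        cols = np.nonzero(conditions == cond)[0]
        if cols.size < 2:
            logger.warning(
                "condition %r has a single library; delta fixed at 1", cond
            )
            continue
        log_g = logz[:, cols].mean(axis=1)  # log geometric mean per transcript
        log_ratio = logz[:, cols] - log_g[:, None]
        log_d = np.median(log_ratio, axis=0)
        log_d -= log_d.mean()  # within-condition geometric mean of delta = 1
        delta[cols] = np.exp(log_d)
    return delta


def apply_delta(z: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """Corrected abundances ``z_ij / delta_j``."""
    delta = np.asarray(delta, dtype=float)
    if np.any(delta <= 0):
        raise ValidationError("delta factors must be positive")
    return np.asarray(z, dtype=float) / delta


def rle_table(z_tilde: np.ndarray) -> DiagnosticsTables:
    """Relative log expression: ``ln z~_ij - median_j' ln z~_ij'``.

    Rows must be strictly positive (pseudocounted, detection-filtered).
    Each row has median 0 across libraries by construction; the per-library
    medians of the resulting columns are the usual RLE summary.
    """
    z_tilde = np.asarray(z_tilde, dtype=float)
    if np.any(z_tilde <= 0):
        raise ValidationError("RLE needs strictly positive abundances")
    logz = np.log(z_tilde)
    rle = logz - np.median(logz, axis=1, keepdims=True)
    return DiagnosticsTables(rle=rle, rle_medians=np.median(rle, axis=0))


def ma_table(mean_high: np.ndarray, mean_low: np.ndarray) -> DiagnosticsTables:
    """MA summary for two group means on the base-2 log scale.

    ``M = log2(mean_high / mean_low)``, ``A = (1/2) log2(mean_high *
    mean_low)``.  Transcripts with a zero mean in either group are excluded
    and counted in ``n_excluded``.
    """
    hi = np.asarray(mean_high, dtype=float)
    lo = np.asarray(mean_low, dtype=float)
    if hi.shape != lo.shape:
        raise ValidationError("group-mean vectors must have equal length")
    ok = (hi > 0) & (lo > 0)
    m = np.log2(hi[ok] / lo[ok])
    a = 0.5 * np.log2(hi[ok] * lo[ok])
    return DiagnosticsTables(ma=np.column_stack([a, m]), n_excluded=int((~ok).sum()))
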