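"""Maximum-likelihood spike-in calibration of RNA-seq counts.

Counts within each library are modelled as one multinomial draw whose
expected proportions are shared across libraries.  For the spike-in block
the proportions are proportional to alpha_i * n_i, the product of each
molecule's relative yield and its known abundance.  Maximising the joint
multinomial likelihood gives closed forms:

* pooled proportions       f_i = sum_j y_ij / sum_{i,j} y_ij
* calibration constant     nu_j = f_1 * L_j^SI / n_1
* nominal abundance        z_ij = y_ij / nu_j         (native RNA)
* spike-in abundance       z_i  = (n_1 / f_1) * f_i
* relative yield           alpha_i = z_i / n_i

where index 1 is the reference spike-in (the one contributing the largest
share of pooled spike-in counts; alpha_1 = 1 by convention) and n_1 its
known amount, in attomoles or molecules per cell.  1/nu_j is then on an
absolute scale — attomoles (or molecules) per count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_model import (
    SPIKEIN,
    CountMatrix,
    SpikeInAnnotation,
    SpikecalError,
    ValidationError,
)

logger = logging.getLogger("spikecal")


class EstimationError(SpikecalError):
    """Estimation impossible on the given data."""


@dataclass
class CalibrationResult:
    """Fitted calibration for one study.

    ``nu`` is in counts per unit of ``units`` ('amol' or
    'molecules_per_cell'); ``alpha`` is dimensionless with
    ``alpha[reference_index] == 1``.  ``dropped`` lists spike-ins with zero
    total counts, excluded from ``f`` rather than silently given f=0.
    """

    molecule_ids: list[str]
    library_ids: list[str]
    f: np.ndarray
    reference_index: int
    nu: np.ndarray
    alpha: np.ndarray
    z_spikein: np.ndarray
    units: str = "amol"
    dropped: list[str] | None = None

    @property
    def reference_id(self) -> str:
        return self.molecule_ids[self.reference_index]


@dataclass
class AbundanceMatrix:
    """Nominal abundances z_ij (units of the reference spike-in amount) with
    optional per-library correction factors delta_j."""

    molecule_ids: list[str]
    library_ids: list[str]
    z: np.ndarray
    units: str = "amol"
    delta: np.ndarray | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.z, index=self.molecule_ids, columns=self.library_ids)


# ----------------------------------------------------------------------
# closed-form ML estimators
# ----------------------------------------------------------------------
def pooled_proportions(counts: np.ndarray) -> np.ndarray:
    """ML multinomial proportions pooled across libraries.

    ``f_i = (sum_j y_ij) / (sum_ij y_ij)``.  Raises on an all-zero matrix.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim == 1:
        counts = counts[:, None]
    total = counts.sum()
    if total <= 0:
        raise EstimationError("cannot estimate proportions: all counts are zero")
    return counts.sum(axis=1) / total


def select_reference(f: np.ndarray) -> int:
    """Index of the reference spike-in: argmax of f, ties to lowest index."""
    f = np.asarray(f, dtype=float)
    if f.size == 0:
        raise EstimationError("empty proportion vector")
    return int(np.argmax(f))


def calibration_constants(f1: float, l_si, n1) -> np.ndarray:
    """Per-library calibration constants ``nu_j = f1 * L_j^SI / n1``.

    ``n1`` may be a scalar (same spike-in amount in every sample) or a
    per-library vector (dilution designs, where the reference amount
    carries a library subscript).
    """
    n1 = np.asarray(n1, dtype=float)
    if np.any(n1 <= 0):
        raise ValidationError("reference spike-in amount n1 must be positive")
    if not 0 < f1 <= 1:
        raise ValidationError("reference proportion f1 must lie in (0, 1]")
    l_si = np.asarray(l_si, dtype=float)
    nu = f1 * l_si / n1
    if np.any(nu == 0):
        zero = np.nonzero(nu == 0)[0]
        logger.warning(
            "libraries with zero spike-in counts are unusable: indices %s",
            zero.tolist(),
        )
    return nu


def counts_to_abundance(counts: np.ndarray, nu: np.ndarray, pseudocount: float = 0.0):
    """Nominal abundances ``z_ij = (y_ij + pseudocount) / nu_j``.

    The pseudocount (+1) is used only ahead of log-scale diagnostics,
    never for estimating nu or alpha.
    """
    nu = np.asarray(nu, dtype=float)
    if np.any(nu <= 0):
        bad = np.nonzero(nu <= 0)[0].tolist()
        raise ValidationError(f"non-positive calibration constant for libraries {bad}")
    return (np.asarray(counts, dtype=float) + pseudocount) / nu


def spikein_nominal_abundance(f: np.ndarray, f1: float, n1: float) -> np.ndarray:
    """Spike-in nominal abundances ``z_i = (n1 / f1) * f_i``."""
    if f1 <= 0:
        raise ValidationError("reference proportion f1 must be positive")
    return (n1 / f1) * np.asarray(f, dtype=float)


def relative_yields(z: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Relative yield coefficients ``alpha_i = z_i / n_i``."""
    n = np.asarray(n, dtype=float)
    if np.any(n <= 0):
        raise ValidationError("known spike-in amounts must be positive")
    return np.asarray(z, dtype=float) / n


# ----------------------------------------------------------------------
# end-to-end calibration
# ----------------------------------------------------------------------
def calibrate(
    spikein_counts: CountMatrix,
    annotation: SpikeInAnnotation,
    units: str = "amol",
    cells: float | None = None,
    n1_per_library: np.ndarray | None = None,
) -> CalibrationResult:
    """Fit the full spike-in calibration for one study.

    Pools spike-in counts across all libraries sharing the same spike-in
    composition, picks the reference spike-in, and returns f, nu, alpha and
    the spike-in nominal abundances.  Spike-ins absent from all libraries
    are dropped from the fit and reported in ``dropped``.

    With ``units='molecules_per_cell'`` the known amounts are converted via
    ``cells`` before anchoring nu, so 1/nu is molecules per cell per count.
    ``n1_per_library`` overrides the reference amount per library for
    dilution-style designs.
    """
    if units not in ("amol", "molecules_per_cell"):
        raise ValidationError(f"unknown units {units!r}")
    si_rows = spikein_counts.molecule_class == SPIKEIN
    if not si_rows.all():
        spikein_counts = spikein_counts.subset_molecules(
            [m for m, s in zip(spikein_counts.molecule_ids, si_rows) if s]
        )
    row_tot = spikein_counts.counts.sum(axis=1)
    dropped = [m for m, t in zip(spikein_counts.molecule_ids, row_tot) if t == 0]
    if dropped:
        logger.info("dropping %d undetected spike-ins: %s", len(dropped), dropped[:5])
        keep = [m for m in spikein_counts.molecule_ids if m not in set(dropped)]
        spikein_counts = spikein_counts.subset_molecules(keep)

    ann = annotation.reindex(spikein_counts.molecule_ids)
    n = ann.n_amol
    if units == "molecules_per_cell":
        if cells is None:
            raise ValidationError("units='molecules_per_cell' requires cells")
        n = ann.molecules_per_cell(cells)

    f = pooled_proportions(spikein_counts.counts)
    ref = select_reference(f)
    n1 = n[ref] if n1_per_library is None else np.asarray(n1_per_library, float)
    nu = calibration_constants(f[ref], spikein_counts.l_si, n1)
    z_si = spikein_nominal_abundance(f, f[ref], n[ref])
    alpha = relative_yields(z_si, n)
    return CalibrationResult(
        molecule_ids=list(spikein_counts.molecule_ids),
        library_ids=list(spikein_counts.library_ids),
        f=f,
        reference_index=ref,
        nu=nu,
        alpha=alpha,
        z_spikein=z_si,
        units=units,
        dropped=dropped,
    )


def abundance_matrix(
    counts: CountMatrix, calib: CalibrationResult, pseudocount: float = 0.0
) -> AbundanceMatrix:
    """Convert a (native) count matrix to nominal abundances with the fitted
    per-library calibration constants."""
    if counts.library_ids != calib.library_ids:
        raise ValidationError("library ids of counts and calibration differ")
    z = counts_to_abundance(counts.counts, calib.nu, pseudocount=pseudocount)
    return AbundanceMatrix(
        molecule_ids=list(counts.molecule_ids),
        library_ids=list(counts.library_ids),
        z=z,
        units=calib.units,
    )
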