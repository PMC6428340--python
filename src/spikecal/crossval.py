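"""Leave-one-condition-out cross-validation of the calibration.

Spike-in abundances are known and identical across samples, so the
calibration can be audited by training the multinomial model (pooled
proportions, reference choice, relative yields) on all but one condition
and inferring the spike-ins' molecules per cell in the left-out
condition's libraries as if they were native RNA.  Mean Fold Error (MFE)
summarises the discrepancy; comparing it with MFE on counts regenerated
from the fitted multinomial model (MFE_syn, Monte Carlo) separates
model-misfit error from pure sampling error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import calibration
from .data_model import (
    CountMatrix,
    SpikeInAnnotation,
    ValidationError,
    amol_to_molecules_per_cell,
)

logger = logging.getLogger("spikecal")


@dataclass
class LocoResult:
    """Inference for one leave-out condition."""

    leave_out: str
    molecule_ids: list[str]
    inferred_mpc: np.ndarray  # mean over leave-out libraries, molecules/cell
    actual_mpc: np.ndarray
    mean_l_si: float
    excluded: list[str]  # spike-ins undetected in training


@dataclass
class MfeRatioResult:
    """Monte-Carlo MFE ratio summary for one leave-out condition."""

    leave_out: str
    mfe_lab: float
    ratios: np.ndarray  # MFE_lab / MFE_syn per trial
    mean_ratio: float
    quantile_range: tuple[float, float]  # mid-0.95 range of the ratios
    mean_l_si: float


def _train_model(train: CountMatrix, annotation: SpikeInAnnotation):
    """Pooled proportions, reference and relative yields on the retained
    libraries; spike-ins undetected in training are excluded."""
    row_tot = train.counts.sum(axis=1)
    excluded = [m for m, t in zip(train.molecule_ids, row_tot) if t == 0]
    if excluded:
        train = train.subset_molecules(
            [m for m in train.molecule_ids if m not in set(excluded)]
        )
    ann = annotation.reindex(train.molecule_ids)
    f = calibration.pooled_proportions(train.counts)
    ref = calibration.select_reference(f)
    alpha = calibration.relative_yields(
        calibration.spikein_nominal_abundance(f, f[ref], ann.n_amol[ref]), ann.n_amol
    )
    return train.molecule_ids, f, ref, alpha, ann, excluded


def loco_infer(
    spikein_counts: CountMatrix,
    annotation: SpikeInAnnotation,
    leave_out: str,
    cells: float,
) -> LocoResult:
    """Treat the left-out condition's spike-ins as unknowns and infer their
    molecules per cell from the model trained on the other conditions.

    For each leave-out library j, nu_j = f1_train * L_j^SI / n1; the
    inferred abundance of spike-in i is y_ij / (nu_j * alpha_i_train),
    averaged over the leave-out libraries.
    """
    cond = spikein_counts.conditions()
    if leave_out not in cond:
        raise ValidationError(f"unknown condition {leave_out!r}")
    if len(cond) < 2:
        raise ValidationError("leave-one-condition-out needs >= 2 conditions")
    test_cols = cond[leave_out]
    train_libs = [
        lib
        for j, lib in enumerate(spikein_counts.library_ids)
        if j not in set(test_cols)
    ]
    train = spikein_counts.subset_libraries(train_libs)
    ids, f, ref, alpha, ann, excluded = _train_model(train, annotation)

    test = spikein_counts.subset_molecules(ids).counts[:, test_cols]
    l_si_test = test.sum(axis=0).astype(float)
    nu_test = calibration.calibration_constants(f[ref], l_si_test, ann.n_amol[ref])
    inferred_amol = (test / nu_test[None, :]) / alpha[:, None]
    inferred_amol = inferred_amol.mean(axis=1)
    return LocoResult(
        leave_out=leave_out,
        molecule_ids=list(ids),
        inferred_mpc=np.asarray(amol_to_molecules_per_cell(inferred_amol, cells)),
        actual_mpc=np.asarray(amol_to_molecules_per_cell(ann.n_amol, cells)),
        mean_l_si=float(l_si_test.mean()),
        excluded=excluded,
    )


def mean_fold_error(
    inferred: np.ndarray, actual: np.ndarray, geometric: bool = False
) -> float:
    """Mean over spike-ins of the fold discrepancy max(r, 1/r) with
    r = inferred/actual; >= 1 by construction.  Zero or non-finite inferred
    values are excluded (and logged).  ``geometric=True`` averages on the
    log scale instead of arithmetically."""
    inferred = np.asarray(inferred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if inferred.shape != actual.shape:
        raise ValidationError("inferred and actual must have equal length")
    if np.any(actual <= 0):
        raise ValidationError("actual abundances must be positive")
    ok = np.isfinite(inferred) & (inferred > 0)
    if (~ok).sum():
        logger.info("MFE: excluding %d undetected spike-ins", int((~ok).sum()))
    if not np.any(ok):
        raise ValidationError("no usable spike-ins for MFE")
    r = inferred[ok] / actual[ok]
    fold = np.maximum(r, 1.0 / r)
    if geometric:
        return float(np.exp(np.mean(np.log(fold))))
    return float(np.mean(fold))


def mfe_ratio_mc(
    spikein_counts: CountMatrix,
    annotation: SpikeInAnnotation,
    leave_out: str,
    cells: float,
    trials: int = 10_000,
    seed: int | None = None,
    geometric: bool = False,
) -> MfeRatioResult:
    """Monte-Carlo distribution of MFE_lab / MFE_syn for one leave-out
    condition.

    Each trial regenerates *all* spike-in libraries at once from the
    multinomial model fitted to the full data (library column totals kept
    fixed), reruns the leave-one-condition-out inference on the synthetic
    counts and recomputes the MFE.  Ratios near 1 mean the laboratory
    error is explained by multinomial sampling alone.
    """
    if trials < 1:
        raise ValidationError("trials must be >= 1")
    rng = np.random.default_rng(seed)
    lab = loco_infer(spikein_counts, annotation, leave_out, cells)
    mfe_lab = mean_fold_error(lab.inferred_mpc, lab.actual_mpc, geometric=geometric)

    # full-data multinomial fit used as the generative model
    f_all = calibration.pooled_proportions(spikein_counts.counts)
    l_si = spikein_counts.l_si
    ratios = np.empty(trials)
    syn = spikein_counts  # reuse structure; counts replaced per trial
    for t in range(trials):
        counts = np.column_stack(
            [rng.multinomial(int(l), f_all) for l in l_si]
        )
        syn_cm = CountMatrix(
            molecule_ids=list(syn.molecule_ids),
            library_ids=list(syn.library_ids),
            counts=counts,
            molecule_class=syn.molecule_class.copy(),
            library_meta=dict(syn.library_meta),
        )
        res = loco_infer(syn_cm, annotation, leave_out, cells)
        mfe_syn = mean_fold_error(res.inferred_mpc, res.actual_mpc, geometric=geometric)
        ratios[t] = mfe_lab / mfe_syn
    lo, hi = np.quantile(ratios, [0.025, 0.975])
    return MfeRatioResult(
        leave_out=leave_out,
        mfe_lab=mfe_lab,
        ratios=ratios,
        mean_ratio=float(ratios.mean()),
        quantile_range=(float(lo), float(hi)),
        mean_l_si=lab.mean_l_si,
    )
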