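"""Shared data model and tab-delimited I/O for spike-in calibrated RNA-seq.

Count tables are genes-by-libraries (or spike-ins-by-libraries) TSV files
with a header row of library identifiers and a first column of molecule
identifiers.  Spike-in annotations carry, per synthetic molecule, the known
amount added to each sample (attomoles), its length (nt), GC content and
predicted folding energy (kcal/mol).  Library metadata (condition label,
growth rate, cells per sample, spike-in aliquot) lives in a small separate
YAML or TSV config because the count tables themselves carry none.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.constants import Avogadro

logger = logging.getLogger("spikecal")

SPIKEIN = "spike-in"
NATIVE = "native"

#: Default cells per sample by study design: ten million yeast cells per
#: chemostat sample; 800 FACS-sorted cells per Ciona lineage sample.
DEFAULT_CELLS_YEAST = 10_000_000
DEFAULT_CELLS_CIONA = 800


class SpikecalError(Exception):
    """Base class for all spikecal errors."""


class ParseError(SpikecalError):
    """A cell of an input table could not be parsed."""


class ValidationError(SpikecalError):
    """An input violated a model invariant."""


@dataclass(frozen=True)
class LibraryMeta:
    """Per-library experimental metadata.

    Parameters
    ----------
    condition
        Condition / cell-type label; conditions partition libraries.
    growth_rate
        Steady-state exponential growth rate constant (1/h), for
        growth-rate designs.
    cells
        Number of cells in the sample the library derives from.
    aliquot
        Spike-in aliquot label, for designs where the spike-in amount
        differs between libraries (dilution studies).
    """

    condition: str
    growth_rate: float | None = None
    cells: float | None = None
    aliquot: str | None = None


@dataclass
class CountMatrix:
    """Observed counts for molecules (rows) across libraries (columns).

    ``counts`` is a non-negative integer array of shape
    ``(len(molecule_ids), len(library_ids))``.  ``molecule_class`` flags
    every row as spike-in or native RNA.
    """

    molecule_ids: list[str]
    library_ids: list[str]
    counts: np.ndarray
    molecule_class: np.ndarray  # per-row flag, values in {SPIKEIN, NATIVE}
    library_meta: dict[str, LibraryMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.molecule_ids), len(self.library_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.molecule_ids)} molecules x {len(self.library_ids)} libraries"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        if len(set(self.molecule_ids)) != len(self.molecule_ids):
            dups = pd.Index(self.molecule_ids)
            dups = sorted(set(dups[dups.duplicated()]))
            raise ValidationError(f"duplicate molecule ids: {dups[:5]}")
        self.molecule_class = np.asarray(self.molecule_class, dtype=object)
        if self.molecule_class.shape != (len(self.molecule_ids),):
            raise ValidationError("molecule_class must be per-molecule")
        bad = set(self.molecule_class) - {SPIKEIN, NATIVE}
        if bad:
            raise ValidationError(f"unknown molecule class: {sorted(bad)}")

    # ------------------------------------------------------------------
    # derived library totals
    # ------------------------------------------------------------------
    @property
    def n_molecules(self) -> int:
        return len(self.molecule_ids)

    @property
    def n_libraries(self) -> int:
        return len(self.library_ids)

    @property
    def l_si(self) -> np.ndarray:
        """Per-library total spike-in counts."""
        return self.counts[self.molecule_class == SPIKEIN].sum(axis=0)

    @property
    def l_rna(self) -> np.ndarray:
        """Per-library total native-RNA counts."""
        return self.counts[self.molecule_class == NATIVE].sum(axis=0)

    @property
    def l_tot(self) -> np.ndarray:
        """Per-library total counts over all molecules."""
        return self.counts.sum(axis=0)

    def conditions(self) -> dict[str, list[int]]:
        """Map condition label -> column indices (the index sets of the
        condition partition).  Requires metadata for every library."""
        out: dict[str, list[int]] = {}
        for j, lib in enumerate(self.library_ids):
            meta = self.library_meta.get(lib)
            if meta is None:
                raise ValidationError(f"library {lib!r} has no metadata")
            out.setdefault(meta.condition, []).append(j)
        return out

    def with_meta(self, meta: Mapping[str, LibraryMeta]) -> "CountMatrix":
        missing = [lib for lib in self.library_ids if lib not in meta]
        if missing:
            raise ValidationError(f"metadata missing for libraries: {missing}")
        return replace(self, library_meta={lib: meta[lib] for lib in self.library_ids})

    def subset_libraries(self, library_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.library_ids.index(lib) for lib in library_ids]
        return CountMatrix(
            molecule_ids=list(self.molecule_ids),
            library_ids=list(library_ids),
            counts=self.counts[:, idx],
            molecule_class=self.molecule_class.copy(),
            library_meta={
                lib: self.library_meta[lib]
                for lib in library_ids
                if lib in self.library_meta
            },
        )

    def subset_molecules(self, molecule_ids: Sequence[str]) -> "CountMatrix":
        pos = {m: i for i, m in enumerate(self.molecule_ids)}
        idx = [pos[m] for m in molecule_ids]
        return CountMatrix(
            molecule_ids=list(molecule_ids),
            library_ids=list(self.library_ids),
            counts=self.counts[idx, :],
            molecule_class=self.molecule_class[idx],
            library_meta=dict(self.library_meta),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.molecule_ids, columns=self.library_ids
        )


@dataclass
class SpikeInAnnotation:
    """Known composition of the spike-in mixture.

    One row per spike-in molecule: amount added per sample in attomoles
    (``n_amol``; strictly positive), molecule length in nt, GC fraction in
    [0, 1] and folding free energy in kcal/mol.  For dilution-style designs
    ``n_amol`` may be a DataFrame column per aliquot; here it is a single
    vector and per-aliquot amounts are handled via :meth:`scaled`.
    """

    molecule_ids: list[str]
    n_amol: np.ndarray
    length_nt: np.ndarray | None = None
    gc_fraction: np.ndarray | None = None
    folding_energy: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.n_amol = np.asarray(self.n_amol, dtype=float)
        if self.n_amol.shape != (len(self.molecule_ids),):
            raise ValidationError("n_amol must be per-molecule")
        if np.any(~np.isfinite(self.n_amol)) or np.any(self.n_amol <= 0):
            raise ValidationError("spike-in amounts (amol) must be positive")
        for name in ("length_nt", "gc_fraction", "folding_energy"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (len(self.molecule_ids),):
                    raise ValidationError(f"{name} must be per-molecule")
                setattr(self, name, v)
        if self.gc_fraction is not None and np.any(self.gc_fraction > 1.0):
            warnings.warn(
                "GC content > 1 interpreted as percent; dividing by 100",
                stacklevel=2,
            )
            self.gc_fraction = np.where(
                self.gc_fraction > 1.0, self.gc_fraction / 100.0, self.gc_fraction
            )
        if self.gc_fraction is not None and (
            np.any(self.gc_fraction < 0) or np.any(self.gc_fraction > 1)
        ):
            raise ValidationError("GC fraction must lie in [0, 1]")

    def molecules_per_cell(self, cells: float) -> np.ndarray:
        """Spike-in abundance in molecules per cell for ``cells`` per sample."""
        return amol_to_molecules_per_cell(self.n_amol, cells)

    def reindex(self, molecule_ids: Sequence[str]) -> "SpikeInAnnotation":
        pos = {m: i for i, m in enumerate(self.molecule_ids)}
        missing = [m for m in molecule_ids if m not in pos]
        if missing:
            raise ValidationError(f"spike-ins missing from annotation: {missing[:5]}")
        idx = [pos[m] for m in molecule_ids]

        def take(v):
            return None if v is None else np.asarray(v)[idx]

        return SpikeInAnnotation(
            molecule_ids=list(molecule_ids),
            n_amol=self.n_amol[idx],
            length_nt=take(self.length_nt),
            gc_fraction=take(self.gc_fraction),
            folding_energy=take(self.folding_energy),
        )

    def scaled(self, factor: float) -> "SpikeInAnnotation":
        """Annotation with every amount multiplied by ``factor`` (aliquot
        volume scaling in dilution designs)."""
        return SpikeInAnnotation(
            molecule_ids=list(self.molecule_ids),
            n_amol=self.n_amol * factor,
            length_nt=self.length_nt,
            gc_fraction=self.gc_fraction,
            folding_energy=self.folding_energy,
        )


# ----------------------------------------------------------------------
# unit conversion
# ----------------------------------------------------------------------
def amol_to_molecules_per_cell(n_amol, cells) -> np.ndarray | float:
    """Convert attomoles per sample to molecules per cell.

    ``molecules/cell = n_amol * 1e-18 * N_A / cells`` with Avogadro's
    constant N_A.  ``cells`` must be positive.
    """
    cells = np.asarray(cells, dtype=float)
    if np.any(cells <= 0):
        raise ValidationError("cells per sample must be positive")
    return np.asarray(n_amol, dtype=float) * 1e-18 * Avogadro / cells


def molecules_per_cell_to_amol(n_molecules, cells) -> np.ndarray | float:
    """Inverse of :func:`amol_to_molecules_per_cell`."""
    cells = np.asarray(cells, dtype=float)
    if np.any(cells <= 0):
        raise ValidationError("cells per sample must be positive")
    return np.asarray(n_molecules, dtype=float) * cells / (1e-18 * Avogadro)


# ----------------------------------------------------------------------
# readers / writers
# ----------------------------------------------------------------------
def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=0, index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"{path}: table has no data rows/columns")
    return df


def read_count_matrix(
    path,
    molecule_class: str = NATIVE,
    library_meta: Mapping[str, LibraryMeta] | None = None,
) -> CountMatrix:
    """Read a genes-by-libraries (or spike-ins-by-libraries) count TSV.

    The file is strictly tab-delimited with one header line of library ids;
    the molecule-id column is the first column (unnamed or named ``id``).
    All cells must be non-negative integers.
    """
    if molecule_class not in (SPIKEIN, NATIVE):
        raise ValidationError(f"unknown molecule class {molecule_class!r}")
    df = _read_tsv(path)
    arr = np.empty(df.shape, dtype=np.int64)
    for cj, col in enumerate(df.columns):
        try:
            numeric = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ParseError(
                f"{path}: non-numeric count at row {bad!r}, column {col!r}"
            ) from None
        vals = np.asarray(numeric, dtype=float)
        if np.any(np.mod(vals, 1) != 0):
            bad = df.index[np.mod(vals, 1) != 0][0]
            raise ParseError(
                f"{path}: non-integer count at row {bad!r}, column {col!r}"
            )
        arr[:, cj] = vals.astype(np.int64)
    cm = CountMatrix(
        molecule_ids=[str(m) for m in df.index],
        library_ids=[str(c) for c in df.columns],
        counts=arr,
        molecule_class=np.full(df.shape[0], molecule_class, dtype=object),
    )
    if library_meta is not None:
        cm = cm.with_meta(library_meta)
    return cm


def write_count_matrix(cm: CountMatrix, path) -> None:
    cm.to_frame().to_csv(path, sep="\t", index_label="id")


def combine(spikein: CountMatrix, native: CountMatrix) -> CountMatrix:
    """Stack a spike-in and a native count matrix sharing library columns."""
    if spikein.library_ids != native.library_ids:
        raise ValidationError("library ids differ between spike-in and native tables")
    return CountMatrix(
        molecule_ids=list(spikein.molecule_ids) + list(native.molecule_ids),
        library_ids=list(spikein.library_ids),
        counts=np.vstack([spikein.counts, native.counts]),
        molecule_class=np.concatenate([spikein.molecule_class, native.molecule_class]),
        library_meta={**native.library_meta, **spikein.library_meta},
    )


# accepted header spellings, lowercased, for the annotation columns
_ANNOT_ALIASES = {
    "n_amol": {"n_amol", "amol", "attomoles", "amount", "amol_per_sample"},
    "length_nt": {"length_nt", "length", "len", "nt"},
    "gc_fraction": {"gc_fraction", "gc", "gc_content", "gc_percent", "gccontent"},
    "folding_energy": {
        "folding_energy",
        "energy",
        "dg",
        "foldingenergy",
        "folding_energy_kcal_mol",
    },
}


def read_spikein_annotation(path) -> SpikeInAnnotation:
    """Read a spike-in annotation TSV (id, amol, length, GC, folding energy).

    Minor header variants are tolerated; GC given as percent is normalised
    to a fraction.  Length, GC and folding energy are optional columns.
    """
    df = _read_tsv(path)
    lower = {str(c).strip().lower(): c for c in df.columns}
    resolved: dict[str, str] = {}
    for canon, aliases in _ANNOT_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                resolved[canon] = lower[alias]
                break
    if "n_amol" not in resolved:
        raise ValidationError(
            f"{path}: no attomole-amount column found (columns: {list(df.columns)})"
        )

    def col(canon):
        if canon not in resolved:
            return None
        return np.asarray(pd.to_numeric(df[resolved[canon]], errors="raise"), float)

    return SpikeInAnnotation(
        molecule_ids=[str(m) for m in df.index],
        n_amol=col("n_amol"),
        length_nt=col("length_nt"),
        gc_fraction=col("gc_fraction"),
        folding_energy=col("folding_energy"),
    )


def write_spikein_annotation(ann: SpikeInAnnotation, path) -> None:
    data = {"amol": ann.n_amol}
    if ann.length_nt is not None:
        data["length_nt"] = ann.length_nt
    if ann.gc_fraction is not None:
        data["gc_fraction"] = ann.gc_fraction
    if ann.folding_energy is not None:
        data["folding_energy"] = ann.folding_energy
    pd.DataFrame(data, index=ann.molecule_ids).to_csv(path, sep="\t", index_label="id")


def read_library_metadata(path) -> dict[str, LibraryMeta]:
    """Read library metadata from YAML (mapping library -> fields) or TSV
    (columns: library, condition, [growth_rate], [cells], [aliquot])."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: expected a mapping of library -> fields")
        out = {}
        for lib, rec in raw.items():
            if isinstance(rec, str):
                rec = {"condition": rec}
            def num(v):
                return None if v is None else float(v)

            out[str(lib)] = LibraryMeta(
                condition=str(rec["condition"]),
                growth_rate=num(rec.get("growth_rate")),
                cells=num(rec.get("cells")),
                aliquot=rec.get("aliquot"),
            )
        return out
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "library" not in cols or "condition" not in cols:
        raise ValidationError(f"{path}: need 'library' and 'condition' columns")
    out = {}
    for _, row in df.iterrows():
        out[str(row[cols["library"]])] = LibraryMeta(
            condition=str(row[cols["condition"]]),
            growth_rate=(
                float(row[cols["growth_rate"]]) if "growth_rate" in cols else None
            ),
            cells=float(row[cols["cells"]]) if "cells" in cols else None,
            aliquot=str(row[cols["aliquot"]]) if "aliquot" in cols else None,
        )
    return out


def detection_filter(cm: CountMatrix, min_fraction: float = 2.0 / 3.0) -> np.ndarray:
    """Boolean row mask: detected (nonzero) in more than ``min_fraction`` of
    libraries.  Generalises the more-than-4-of-6 / more-than-6-of-9 rules
    used before log-scale diagnostics."""
    detected = (cm.counts > 0).sum(axis=1)
    return detected > min_fraction * cm.n_libraries
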