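"""Spectral dataset container and row/column operations.

The :class:`SpectralDataset` is the currency passed between every stage of
the aquagram pipeline: a strictly increasing wavelength grid (nm), one
absorbance spectrum (logT^-1) per row, and a per-row metadata table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpectralDataset",
    "ValidationError",
    "METADATA_COLUMNS",
    "subset_wavelengths",
    "average_consecutive_scans",
]

#: Recognized metadata columns, in canonical order.
METADATA_COLUMNS = (
    "sample_id",
    "group_label",
    "temperature_C",
    "concentration_mM",
    "replicate_id",
    "scan_index",
)

#: Absolute tolerance (nm) for matching a requested wavelength to the grid.
WAVELENGTH_ATOL = 1e-6


class ValidationError(ValueError):
    """A dataset violated one of its structural invariants."""


@dataclass
class SpectralDataset:
    """Wavelength grid, absorbance matrix and per-spectrum metadata.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing 1-D grid in nanometres.
    absorbance
        2-D array, shape ``(n_spectra, n_wavelengths)``, absorbance units.
    meta
        DataFrame with one row per spectrum.  Missing metadata columns are
        allowed; operations that need one (e.g. ``temperature_C``) fail fast.
    """

    wavelengths_nm: np.ndarray
    absorbance: np.ndarray
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float).ravel()
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.meta is None or len(self.meta) == 0:
            self.meta = pd.DataFrame(index=range(self.absorbance.shape[0]))
        self.meta = self.meta.reset_index(drop=True)
        self.validate()

    # -- invariants -------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`ValidationError` on any broken invariant."""
        wl, ab = self.wavelengths_nm, self.absorbance
        if ab.ndim != 2 or ab.shape[1] != wl.size:
            raise ValidationError(
                f"absorbance shape {ab.shape} does not match {wl.size} wavelengths"
            )
        if wl.size > 1 and not np.all(np.diff(wl) > 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(ab)):
            bad = np.argwhere(~np.isfinite(ab))[0]
            raise ValidationError(
                f"non-finite absorbance at row {bad[0]}, wavelength index {bad[1]}"
            )
        if len(self.meta) != ab.shape[0]:
            raise ValidationError(
                f"{len(self.meta)} metadata rows for {ab.shape[0]} spectra"
            )

    def declare_step(self, step_nm: float) -> None:
        """Assert the grid is uniform at ``step_nm`` (max deviation < 1e-9 nm)."""
        diffs = np.diff(self.wavelengths_nm)
        if diffs.size and np.max(np.abs(diffs - step_nm)) >= 1e-9:
            raise ValidationError(
                f"grid is not uniform at the declared step {step_nm} nm"
            )

    # -- conveniences -----------------------------------------------------

    @property
    def n_spectra(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths_nm.size

    def copy(self) -> "SpectralDataset":
        return SpectralDataset(
            self.wavelengths_nm.copy(), self.absorbance.copy(), self.meta.copy()
        )

    def with_absorbance(self, absorbance: np.ndarray) -> "SpectralDataset":
        """New dataset sharing grid and metadata, replacing the matrix."""
        return SpectralDataset(self.wavelengths_nm, np.asarray(absorbance), self.meta.copy())

    def take(self, rows) -> "SpectralDataset":
        """Row subset by positional index."""
        rows = np.asarray(rows)
        return SpectralDataset(
            self.wavelengths_nm,
            self.absorbance[rows],
            self.meta.iloc[rows].reset_index(drop=True),
        )

    def wavelength_index(self, target_nm: float, atol: float = WAVELENGTH_ATOL) -> int:
        """Index of the grid point matching ``target_nm`` within ``atol``."""
        i = int(np.argmin(np.abs(self.wavelengths_nm - target_nm)))
        if abs(self.wavelengths_nm[i] - target_nm) > atol:
            raise ValidationError(
                f"no grid wavelength within {atol} nm of {target_nm} nm"
            )
        return i


def subset_wavelengths(ds: SpectralDataset, lo: float, hi: float) -> SpectralDataset:
    """Keep columns with ``lo <= wavelength <= hi`` (inclusive); rows untouched.

    Raises
    ------
    ValidationError
        If ``lo > hi`` or the interval misses the grid entirely.
    """
    if lo > hi:
        raise ValidationError(f"lo ({lo}) must not exceed hi ({hi})")
    mask = (ds.wavelengths_nm >= lo - WAVELENGTH_ATOL) & (
        ds.wavelengths_nm <= hi + WAVELENGTH_ATOL
    )
    if not mask.any():
        raise ValidationError(
            f"[{lo}, {hi}] nm does not intersect the grid "
            f"[{ds.wavelengths_nm[0]}, {ds.wavelengths_nm[-1]}] nm"
        )
    return SpectralDataset(
        ds.wavelengths_nm[mask], ds.absorbance[:, mask], ds.meta.copy()
    )


def average_consecutive_scans(
    ds: SpectralDataset, by: str | list[str] = "group_label"
) -> SpectralDataset:
    """Average spectra within each metadata group (consecutive-scan collapse).

    One output row per distinct value combination of ``by``; the absorbance is
    the arithmetic mean over the group's rows, ``scan_index`` is dropped and
    the group size is recorded in an ``n_scans`` column.
    """
    keys = [by] if isinstance(by, str) else list(by)
    for k in keys:
        if k not in ds.meta.columns:
            raise ValidationError(f"metadata column {k!r} required for averaging")
    frames, rows = [], []
    grouped = ds.meta.groupby(keys, sort=True, dropna=False)
    for name, idx in grouped.groups.items():
        pos = ds.meta.index.get_indexer(idx)
        rows.append(ds.absorbance[pos].mean(axis=0))
        rec = dict(zip(keys, name if isinstance(name, tuple) else (name,)))
        # carry metadata that is constant within the group
        for col in ds.meta.columns:
            if col in keys or col == "scan_index":
                continue
            vals = ds.meta[col].iloc[pos].unique()
            if len(vals) == 1:
                rec[col] = vals[0]
        rec["n_scans"] = len(pos)
        frames.append(rec)
    return SpectralDataset(
        ds.wavelengths_nm.copy(), np.vstack(rows), pd.DataFrame(frames)
    )
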