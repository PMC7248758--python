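"""CSV readers/writers for spectral datasets.

Two dialects are supported.  The canonical *wide* layout mirrors how
spectrometer exports are usually shared: leading metadata columns followed by
one column per wavelength, named by the wavelength in nm with a ``.`` decimal
separator::

    sample_id,group_label,temperature_C,scan_index,1300.0,1300.5,...,1600.0
    s1,w20,20.0,1,0.1234,...

A *long* layout (one row per (spectrum, wavelength) pair) is accepted on
read and produces an identical dataset to its wide twin.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataset import METADATA_COLUMNS, SpectralDataset, ValidationError

__all__ = ["read_spectra", "write_spectra", "FormatError"]


class FormatError(ValueError):
    """The file does not conform to a recognized spectral CSV dialect."""


def _is_wavelength_name(name: str) -> bool:
    try:
        float(name)
        return True
    except (TypeError, ValueError):
        return False


def read_spectra(
    path,
    dialect: str = "wide",
    *,
    column_map: dict[str, str] | None = None,
) -> SpectralDataset:
    """Read a spectral CSV file.

    Parameters
    ----------
    path
        CSV file path.
    dialect
        ``"wide"`` (default) or ``"long"``.
    column_map
        Optional mapping from file column names to canonical metadata names
        (``sample_id``, ``group_label``, ``temperature_C``,
        ``concentration_mM``, ``replicate_id``, ``scan_index``), for files
        whose headers use different labels.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    if dialect == "wide":
        return _from_wide(df)
    if dialect == "long":
        return _from_long(df)
    raise FormatError(f"unknown dialect {dialect!r}")


def _from_wide(df: pd.DataFrame) -> SpectralDataset:
    wl_cols = [c for c in df.columns if _is_wavelength_name(c)]
    if not wl_cols:
        raise FormatError("no wavelength columns found in header")
    meta_cols = [c for c in df.columns if c not in wl_cols]
    wl = np.array([float(c) for c in wl_cols])
    order = np.argsort(wl)
    wl = wl[order]
    block = df[wl_cols].to_numpy()
    try:
        ab = block.astype(float)[:, order]
    except (TypeError, ValueError):
        for i in range(block.shape[0]):
            try:
                block[i].astype(float)
            except (TypeError, ValueError):
                raise FormatError(f"non-numeric absorbance in data row {i}") from None
        raise
    if np.size(wl) != np.unique(wl).size:
        raise ValidationError("duplicate wavelength columns")
    meta = df[meta_cols].copy() if meta_cols else pd.DataFrame(index=df.index)
    return SpectralDataset(wl, ab, meta)


def _from_long(df: pd.DataFrame) -> SpectralDataset:
    for col in ("wavelength_nm", "absorbance"):
        if col not in df.columns:
            raise FormatError(f"long dialect requires a {col!r} column")
    id_cols = [c for c in df.columns if c not in ("wavelength_nm", "absorbance")]
    if not id_cols:
        df = df.assign(sample_id=0)
        id_cols = ["sample_id"]
    if not np.issubdtype(df["absorbance"].dtype, np.number):
        bad = df.index[pd.to_numeric(df["absorbance"], errors="coerce").isna()][0]
        raise FormatError(f"non-numeric absorbance in data row {bad}")
    wide = df.pivot_table(
        index=id_cols, columns="wavelength_nm", values="absorbance", sort=False
    )
    wide = wide.sort_index(axis=1)
    wl = wide.columns.to_numpy(dtype=float)
    meta = wide.index.to_frame(index=False)
    # preserve first-appearance row order of the long file
    first_seen = df.drop_duplicates(id_cols)[id_cols]
    key = pd.MultiIndex.from_frame(meta)
    want = pd.MultiIndex.from_frame(first_seen)
    pos = key.get_indexer(want)
    return SpectralDataset(wl, wide.to_numpy()[pos], meta.iloc[pos])


def write_spectra(ds: SpectralDataset, path, dialect: str = "wide") -> None:
    """Write a dataset as CSV; ``read_spectra`` inverts this losslessly.

    Absorbance is printed with ``repr`` round-trip precision so the
    write/read cycle reproduces values to better than 1e-12.
    """
    if dialect != "wide":
        raise FormatError("only the wide dialect is written")
    meta_cols = [c for c in METADATA_COLUMNS if c in ds.meta.columns]
    meta_cols += [c for c in ds.meta.columns if c not in meta_cols]
    meta = ds.meta[meta_cols].reset_index(drop=True) if meta_cols else pd.DataFrame(
        index=range(ds.n_spectra)
    )
    block = pd.DataFrame(
        ds.absorbance, columns=[format(w, ".10g") for w in ds.wavelengths_nm]
    )
    out = pd.concat([meta, block], axis=1)
    out.to_csv(path, index=False, float_format="%.17g")
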