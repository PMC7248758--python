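"""Spectral pretreatments: MSC, SNV, Savitzky-Golay derivatives, PCA.

MSC (multiplicative scatter correction) removes per-spectrum affine
scatter/pathlength distortions by regressing each spectrum on a reference
spectrum and back-transforming.  SNV centers and scales each spectrum by its
own statistics.  Savitzky-Golay derivatives are taken with respect to
wavelength in nm, so a 2nd derivative has units of absorbance per nm^2
regardless of grid density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from sklearn.decomposition import PCA

from .dataset import SpectralDataset

__all__ = ["msc", "snv", "sg_derivative", "pca_explained", "DegenerateSpectrumError"]


class DegenerateSpectrumError(ValueError):
    """A spectrum (or reference) has no variance where variance is required."""


@dataclass
class MscResult:
    dataset: SpectralDataset
    slope: np.ndarray      # per-spectrum OLS slope a
    intercept: np.ndarray  # per-spectrum OLS intercept b


def msc(ds: SpectralDataset, reference: np.ndarray | None = None) -> MscResult:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum ``x`` is fitted as ``x ~ a * reference + b`` by ordinary
    least squares over all wavelengths and replaced by ``(x - b) / a``.  The
    default reference is the mean spectrum of ``ds``.

    Returns the corrected dataset together with the per-spectrum ``(a, b)``.
    """
    X = ds.absorbance
    if reference is None:
        if ds.n_spectra < 2:
            raise DegenerateSpectrumError(
                "MSC needs >= 2 spectra when no reference is supplied"
            )
        reference = X.mean(axis=0)
    ref = np.asarray(reference, dtype=float).ravel()
    if ref.size != ds.n_wavelengths:
        raise ValueError("reference length does not match the wavelength grid")
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom <= 0:
        raise DegenerateSpectrumError("MSC reference has zero variance")
    Xc = X - X.mean(axis=1, keepdims=True)
    a = (Xc @ ref_c) / denom
    if np.any(a == 0):
        raise DegenerateSpectrumError("MSC fit produced a zero slope")
    b = X.mean(axis=1) - a * ref.mean()
    corrected = (X - b[:, None]) / a[:, None]
    return MscResult(ds.with_absorbance(corrected), a, b)


def snv(ds: SpectralDataset) -> SpectralDataset:
    """Standard normal variate: per-spectrum center and scale (sample SD, n-1)."""
    X = ds.absorbance
    sd = X.std(axis=1, ddof=1)
    if np.any(sd == 0):
        row = int(np.flatnonzero(sd == 0)[0])
        raise DegenerateSpectrumError(f"spectrum {row} is constant; SNV undefined")
    return ds.with_absorbance((X - X.mean(axis=1, keepdims=True)) / sd[:, None])


def sg_derivative(
    ds: SpectralDataset, window: int = 21, polyorder: int = 2, deriv: int = 2
) -> tuple[SpectralDataset, np.ndarray]:
    """Savitzky-Golay smoothed derivative with respect to wavelength.

    The interior is the standard least-squares local polynomial derivative;
    the first and last ``(window - 1) // 2`` points come from the polynomial
    fitted to the first/last window and are flagged in the returned edge
    mask (True = edge-filled value).

    Returns ``(derivative dataset, edge_mask)``.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if not (window > polyorder >= deriv >= 0):
        raise ValueError("need window > polyorder >= deriv >= 0")
    if ds.n_wavelengths < window:
        raise ValueError("spectrum shorter than the filter window")
    steps = np.diff(ds.wavelengths_nm)
    delta = float(steps[0]) if steps.size else 1.0
    if steps.size and np.max(np.abs(steps - delta)) > 1e-9:
        raise ValueError("Savitzky-Golay derivative requires a uniform grid")
    out = savgol_filter(
        ds.absorbance, window, polyorder, deriv=deriv, delta=delta,
        axis=1, mode="interp",
    )
    half = (window - 1) // 2
    edge = np.zeros(ds.n_wavelengths, dtype=bool)
    edge[:half] = True
    edge[ds.n_wavelengths - half:] = True
    return ds.with_absorbance(out), edge


def pca_explained(ds: SpectralDataset, ncomp: int = 2):
    """Mean-centered PCA of the absorbance matrix.

    Returns ``(scores, loadings, explained_variance_fractions)`` where
    ``scores`` is ``(n_spectra, ncomp)``, ``loadings`` is
    ``(ncomp, n_wavelengths)`` and the fractions are sorted non-increasing
    and sum to at most 1.
    """
    n, p = ds.absorbance.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 spectra")
    if ncomp > min(n - 1, p):
        raise ValueError(f"ncomp={ncomp} exceeds min(n-1, p)={min(n - 1, p)}")
    model = PCA(n_components=ncomp, svd_solver="full")
    scores = model.fit_transform(ds.absorbance)
    return scores, model.components_, model.explained_variance_ratio_
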