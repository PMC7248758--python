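"""Temperature-based aquagram: perturbations expressed in degrees Celsius.

The method compares the water spectral pattern of a sample group with the
patterns pure water shows across a 20-70 degC temperature ramp, and reports
for each water matrix coordinate the temperature change that would have
produced the same relative-band-area change in pure water:

1. Average consecutive scans per reference temperature and per sample group.
2. Remove a linear baseline fitted on the two edges of the first overtone
   region (1300 and 1600 nm).
3. Integrate the corrected spectrum over each coordinate's range and divide
   by the full 1300-1600 nm area (relative areas; insensitive to scatter
   and pathlength).
4. Smooth each coordinate's relative area against reference temperature
   with local polynomial regression onto a fine temperature grid.
5. Fit a local line r = alpha + beta * T inside a +/- 2 degC window around
   the experiment temperature.
6. Map a group's relative area r* to its temperature equivalent
   (r* - alpha) / beta; coordinates with |beta| below a conditioning
   threshold are flagged instead of reported.
7. Bootstrap the group's spectra through the whole chain for percentile
   95% confidence intervals (the reference is treated as a fixed
   calibration and is not resampled).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import SpectralDataset, average_consecutive_scans, subset_wavelengths
from .results import AquagramResult
from .wamacs import WamacScheme, default_scheme

__all__ = [
    "baseline_correct",
    "relative_areas",
    "build_reference_curves",
    "local_calibration",
    "temperature_equivalent",
    "temp_aquagram",
    "ReferenceCurves",
    "TemperatureCalibration",
    "RangeError",
    "ConditioningError",
    "DegenerateSpectrumError",
]

FIRST_OVERTONE = (1300.0, 1600.0)


class RangeError(ValueError):
    """Required wavelengths or temperatures fall outside the available span."""


class ConditioningError(ValueError):
    """A coordinate's calibration slope is too flat to invert."""


class DegenerateSpectrumError(ValueError):
    """Total area under the corrected spectrum is not positive."""


# ---------------------------------------------------------------------------
# local polynomial regression (tricube-weighted, LOESS-style)
# ---------------------------------------------------------------------------

def loess_smooth(
    x: np.ndarray, y: np.ndarray, x_out: np.ndarray,
    span: float = 0.5, degree: int = 2,
) -> np.ndarray:
    """Locally weighted polynomial regression evaluated at ``x_out``.

    For each output point the nearest ``ceil(span * n)`` observations are
    fitted with a degree-``degree`` polynomial under tricube weights.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    k = max(degree + 2, int(np.ceil(span * n)))
    if k > n:
        raise RangeError(
            f"span {span} needs {k} points but only {n} temperatures available"
        )
    out = np.empty(np.asarray(x_out).size)
    for j, x0 in enumerate(np.asarray(x_out, float)):
        d = np.abs(x - x0)
        h = np.partition(d, k - 1)[k - 1]
        if h == 0:
            h = np.finfo(float).tiny
        w = (1.0 - np.clip(d / h, 0.0, 1.0) ** 3) ** 3
        V = np.vander(x - x0, degree + 1, increasing=True)
        beta, *_ = np.linalg.lstsq(V * w[:, None], y * w, rcond=None)
        out[j] = beta[0]
    return out


# ---------------------------------------------------------------------------
# baseline and areas
# ---------------------------------------------------------------------------

def _edge_mask(wl: np.ndarray, edge_halfwidth_nm: float) -> np.ndarray:
    lo, hi = wl[0], wl[-1]
    if edge_halfwidth_nm <= 0:
        mask = np.zeros(wl.size, dtype=bool)
        mask[0] = mask[-1] = True
        return mask
    return (wl <= lo + edge_halfwidth_nm) | (wl >= hi - edge_halfwidth_nm)


def baseline_correct(
    spectra: np.ndarray,
    wavelengths_nm: np.ndarray,
    edge_halfwidth_nm: float = 5.0,
) -> np.ndarray:
    """Subtract a straight line fitted to the two edges of the region.

    The line is the ordinary least-squares fit to the points within
    ``edge_halfwidth_nm`` of both ends of the grid (with halfwidth 0 this
    degenerates to the exact line through the two endpoint samples).  A
    spectrum that is exactly linear over the region maps to zeros.
    """
    wl = np.asarray(wavelengths_nm, float)
    lo, hi = FIRST_OVERTONE
    if abs(wl[0] - lo) > 1e-6 or abs(wl[-1] - hi) > 1e-6:
        raise RangeError(
            f"baseline correction needs the grid to span exactly "
            f"[{lo}, {hi}] nm, got [{wl[0]}, {wl[-1]}]"
        )
    Y = np.atleast_2d(np.asarray(spectra, float))
    mask = _edge_mask(wl, edge_halfwidth_nm)
    A = np.column_stack([np.ones(mask.sum()), wl[mask]])
    coef = Y[:, mask] @ np.linalg.pinv(A).T          # (n, 2): intercept, slope
    lines = coef[:, [0]] + coef[:, [1]] * wl[None, :]
    out = Y - lines
    return out[0] if np.ndim(spectra) == 1 else out


@dataclass
class RelativeAreaVector:
    """Coordinate areas divided by the full first-overtone area."""

    coordinate_ids: list[str]
    auc: np.ndarray        # nm * absorbance, per coordinate
    total_auc: float
    rel_area: np.ndarray = field(init=False)

    def __post_init__(self):
        if self.total_auc <= 0:
            raise DegenerateSpectrumError(
                f"total first-overtone area {self.total_auc:.4g} is not positive"
            )
        self.rel_area = self.auc / self.total_auc


def _area_matrix(
    spectra: np.ndarray, wl: np.ndarray, scheme: WamacScheme
) -> tuple[np.ndarray, np.ndarray]:
    """Trapezoidal AUC per coordinate range and total AUC, row-wise."""
    Y = np.atleast_2d(spectra)
    total = np.trapezoid(Y, wl, axis=1)
    per = np.empty((Y.shape[0], len(scheme)))
    for j, c in enumerate(scheme):
        m = (wl >= c.lo_nm - 1e-9) & (wl <= c.hi_nm + 1e-9)
        per[:, j] = np.trapezoid(Y[:, m], wl[m], axis=1)
    return per, total


def relative_areas(
    spectrum: np.ndarray,
    wavelengths_nm: np.ndarray,
    scheme: WamacScheme | None = None,
) -> RelativeAreaVector:
    """Relative coordinate areas of one baseline-corrected spectrum.

    Scaling the spectrum by any k > 0 leaves every relative area unchanged,
    which is what makes the temperature aquagram scatter/pathlength proof.
    """
    scheme = scheme or default_scheme()
    per, total = _area_matrix(spectrum, np.asarray(wavelengths_nm, float), scheme)
    return RelativeAreaVector(scheme.ids, per[0], float(total[0]))


# ---------------------------------------------------------------------------
# reference curves and local calibration
# ---------------------------------------------------------------------------

@dataclass
class ReferenceCurves:
    """Smoothed relative-area-vs-temperature curves, one per coordinate."""

    coordinate_ids: list[str]
    T_grid: np.ndarray           # fine temperature grid, degC
    curves: np.ndarray           # (n_coordinates, len(T_grid))
    raw_temps: np.ndarray
    raw_rel_areas: np.ndarray    # (n_temps, n_coordinates)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.T_grid[0]), float(self.T_grid[-1])


@dataclass
class TemperatureCalibration:
    """Per-coordinate local line r = alpha + beta * T around experiment_T."""

    coordinate_ids: list[str]
    experiment_T: float
    window: tuple[float, float]
    alpha: np.ndarray
    beta: np.ndarray
    conditioned: np.ndarray      # bool per coordinate
    beta_min: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coordinate": self.coordinate_ids,
                "alpha": self.alpha,
                "beta": self.beta,
                "conditioned": self.conditioned,
                "window_lo": self.window[0],
                "window_hi": self.window[1],
            }
        )


def build_reference_curves(
    reference: SpectralDataset,
    scheme: WamacScheme | None = None,
    span: float = 0.5,
    degree: int = 2,
    fine_step: float = 0.1,
    edge_halfwidth_nm: float = 5.0,
) -> ReferenceCurves:
    """Relative-area-vs-temperature curves from a pure-water reference ramp.

    Consecutive scans are averaged per temperature before the baseline and
    area steps; each coordinate's relative area is then smoothed against
    temperature by tricube-weighted local polynomial regression onto a
    uniform fine grid spanning the reference temperatures.
    """
    scheme = scheme or default_scheme()
    if "temperature_C" not in reference.meta.columns:
        raise RangeError("reference dataset must carry temperature_C metadata")
    ref = subset_wavelengths(reference, *FIRST_OVERTONE)
    ref = average_consecutive_scans(ref, by="temperature_C")
    temps = ref.meta["temperature_C"].to_numpy(dtype=float)
    order = np.argsort(temps)
    temps = temps[order]
    if np.unique(temps).size < 5:
        raise RangeError("reference needs at least 5 distinct temperatures")
    corrected = baseline_correct(
        ref.absorbance[order], ref.wavelengths_nm, edge_halfwidth_nm
    )
    per, total = _area_matrix(corrected, ref.wavelengths_nm, scheme)
    if np.any(total <= 0):
        raise DegenerateSpectrumError("non-positive total area in reference")
    R = per / total[:, None]
    n_fine = int(round((temps[-1] - temps[0]) / fine_step))
    T_grid = temps[0] + fine_step * np.arange(n_fine + 1)
    curves = np.vstack(
        [loess_smooth(temps, R[:, j], T_grid, span=span, degree=degree)
         for j in range(len(scheme))]
    )
    return ReferenceCurves(scheme.ids, T_grid, curves, temps, R)


def local_calibration(
    curves: ReferenceCurves,
    experiment_T: float,
    halfwidth: float = 2.0,
    beta_min_fraction: float = 1e-3,
) -> TemperatureCalibration:
    """OLS line per coordinate over the smoothed curve inside the window.

    The window is ``experiment_T +/- halfwidth`` intersected with the curve
    span (a window partly outside the span is clipped; one entirely outside
    raises :class:`RangeError`).  A coordinate is conditioned when |beta|
    is at least ``beta_min_fraction`` times its curve's full range per degC.
    """
    lo = max(experiment_T - halfwidth, curves.span[0])
    hi = min(experiment_T + halfwidth, curves.span[1])
    mask = (curves.T_grid >= lo - 1e-9) & (curves.T_grid <= hi + 1e-9)
    if lo >= hi or mask.sum() < 2:
        raise RangeError(
            f"window [{experiment_T - halfwidth}, {experiment_T + halfwidth}] degC "
            f"is outside the curve span {curves.span}"
        )
    t = curves.T_grid[mask]
    alphas, betas, cond, bmin = [], [], [], []
    for j in range(curves.curves.shape[0]):
        beta, alpha = np.polyfit(t, curves.curves[j, mask], 1)
        rng_r = float(curves.curves[j].max() - curves.curves[j].min())
        threshold = beta_min_fraction * rng_r
        alphas.append(alpha)
        betas.append(beta)
        bmin.append(threshold)
        cond.append(bool(threshold > 0 and abs(beta) >= threshold))
    return TemperatureCalibration(
        curves.coordinate_ids,
        float(experiment_T),
        (float(lo), float(hi)),
        np.array(alphas),
        np.array(betas),
        np.array(cond, dtype=bool),
        np.array(bmin),
    )


def temperature_equivalent(
    r_star: float, calibration: TemperatureCalibration, coordinate: str
) -> float:
    """Invert the local line: the degC at which pure water shows ``r_star``."""
    j = calibration.coordinate_ids.index(coordinate)
    if not calibration.conditioned[j]:
        raise ConditioningError(
            f"{coordinate}: |beta| = {abs(calibration.beta[j]):.3g} below the "
            f"conditioning threshold {calibration.beta_min[j]:.3g}; "
            "temperature equivalent suppressed"
        )
    return float((r_star - calibration.alpha[j]) / calibration.beta[j])


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def _group_chain(
    X: np.ndarray, wl: np.ndarray, scheme: WamacScheme, edge_halfwidth_nm: float
) -> np.ndarray:
    """Mean spectrum -> baseline -> relative areas, for a stack of rows."""
    mean = X.mean(axis=0)
    corrected = baseline_correct(mean, wl, edge_halfwidth_nm)
    per, total = _area_matrix(corrected, wl, scheme)
    if total[0] <= 0:
        raise DegenerateSpectrumError("non-positive total area in group mean")
    return per[0] / total[0]


def _bootstrap_rel_areas(
    X: np.ndarray, wl: np.ndarray, scheme: WamacScheme,
    edge_halfwidth_nm: float, n_boot: int, rng: np.random.Generator,
) -> np.ndarray:
    """Relative areas of ``n_boot`` within-group resampled mean spectra."""
    n = X.shape[0]
    counts = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot)
    means = (counts @ X) / n
    corrected = baseline_correct(means, wl, edge_halfwidth_nm)
    per, total = _area_matrix(corrected, wl, scheme)
    return per / total[:, None]


def temp_aquagram(
    experimental: SpectralDataset,
    reference: SpectralDataset,
    group_key: str = "group_label",
    scheme: WamacScheme | None = None,
    experiment_T: float | None = 28.0,
    control_group=None,
    n_boot: int = 1000,
    seed: int = 0,
    halfwidth: float = 2.0,
    span: float = 0.5,
    degree: int = 2,
    fine_step: float = 0.1,
    beta_min_fraction: float = 1e-3,
    edge_halfwidth_nm: float = 5.0,
) -> AquagramResult:
    """Temperature-based aquagram of ``experimental`` against a water ramp.

    ``experiment_T=None`` selects per-group calibration windows centered on
    each group's own mean ``temperature_C`` (for runs where the reference
    ramp itself is the experiment, so the whole 20-70 degC span is
    representable).  Each group's value depends only on its own spectra and
    the reference, so adding or removing unrelated groups never changes it.

    When ``control_group`` is given, delta rows (group degC minus control
    degC, confidence limits shifted by the control's point value) are
    appended with ``mode='delta'``.
    """
    scheme = scheme or default_scheme()
    if group_key not in experimental.meta.columns:
        raise RangeError(f"experimental metadata lacks {group_key!r}")
    exp = subset_wavelengths(experimental, *FIRST_OVERTONE)
    curves = build_reference_curves(
        reference, scheme, span=span, degree=degree,
        fine_step=fine_step, edge_halfwidth_nm=edge_halfwidth_nm,
    )
    rng = np.random.default_rng(seed)
    labels = list(pd.unique(exp.meta[group_key]))
    rows = []
    per_group: dict = {}
    for label in labels:
        idx = np.flatnonzero((exp.meta[group_key] == label).to_numpy())
        X = exp.absorbance[idx]
        if experiment_T is None:
            temps = exp.meta["temperature_C"].iloc[idx].to_numpy(dtype=float)
            center_T = float(np.mean(temps))
        else:
            center_T = float(experiment_T)
        calib = local_calibration(
            curves, center_T, halfwidth=halfwidth,
            beta_min_fraction=beta_min_fraction,
        )
        r = _group_chain(X, exp.wavelengths_nm, scheme, edge_halfwidth_nm)
        boot_r = _bootstrap_rel_areas(
            X, exp.wavelengths_nm, scheme, edge_halfwidth_nm, n_boot, rng
        )
        values = np.full(len(scheme), np.nan)
        lcl = np.full(len(scheme), np.nan)
        ucl = np.full(len(scheme), np.nan)
        for j, cid in enumerate(scheme.ids):
            if not calib.conditioned[j]:
                continue
            values[j] = (r[j] - calib.alpha[j]) / calib.beta[j]
            boot_T = (boot_r[:, j] - calib.alpha[j]) / calib.beta[j]
            lo_q, hi_q = np.percentile(boot_T, [2.5, 97.5])
            lcl[j] = min(lo_q, values[j])
            ucl[j] = max(hi_q, values[j])
        per_group[label] = (values, lcl, ucl, len(idx), calib)
        for j, cid in enumerate(scheme.ids):
            rows.append(
                {
                    "group": label, "coordinate": cid, "value": values[j],
                    "lcl95": lcl[j], "ucl95": ucl[j], "n": len(idx),
                    "conditioned": bool(calib.conditioned[j]), "mode": "absolute",
                }
            )
    if control_group is not None:
        if control_group not in per_group:
            raise RangeError(f"control group {control_group!r} not in experimental data")
        cv = per_group[control_group][0]
        for label in labels:
            v, lo_, hi_, n, calib = per_group[label]
            for j, cid in enumerate(scheme.ids):
                rows.append(
                    {
                        "group": label, "coordinate": cid,
                        "value": v[j] - cv[j],
                        "lcl95": lo_[j] - cv[j], "ucl95": hi_[j] - cv[j],
                        "n": n, "conditioned": bool(calib.conditioned[j]),
                        "mode": "delta",
                    }
                )
    table = pd.DataFrame(rows)
    result = AquagramResult(
        table=table,
        mode="temperature",
        reference_info={
            "n_reference_spectra": reference.n_spectra,
            "reference_span_C": curves.span,
            "experiment_T": experiment_T,
            "halfwidth_C": halfwidth,
        },
    )
    result.validate()
    return result
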