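"""Synthetic water-like NIR spectra with temperature and solute effects.

The generator emulates the qualitative phenomenology of the water first
overtone (1300-1600 nm): a broad composite band near 1450 nm built from
overlapping Gaussian species bands, a blue shift of the band maximum with
increasing temperature, an isosbestic (temperature-invariant) wavelength,
consecutive-scan replication, per-spectrum affine scatter and photometric
noise.

Two stock models are provided:

* :func:`two_band_model` - the minimal mechanism: bands at 1412 nm (weakly
  hydrogen-bonded water, grows with temperature) and 1462 nm (strongly
  hydrogen-bonded water, shrinks), with amplitude rates chosen so the total
  band area is conserved, which guarantees an isosbestic crossing.
* :func:`rich_water_model` - five components (1342, 1412, 1460, 1462,
  1484 nm) giving every WAMAC a usable temperature response, plus a solute
  difference-spectrum mechanism: a structure-breaker depletes the bulk
  hydrogen-bonded components (a narrow species at 1460 nm and the broad
  1462 nm band) and feeds both wings - more free OH on the short side, an
  ion-hydration species near 1484 nm on the long side - which blue-shifts
  the composite band maximum and raises the far long-wavelength
  coordinates relative to an equivalent pure-water temperature change.

Amplitudes are linear in temperature around ``T_ref``; the model refuses to
produce spectra whose band amplitudes would go negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .dataset import SpectralDataset

__all__ = [
    "Band",
    "SyntheticWaterModel",
    "SoluteEffect",
    "two_band_model",
    "rich_water_model",
    "simulate_temperature_series",
    "simulate_solute_series",
    "isosbestic_wavelength",
    "ModelError",
]


class ModelError(ValueError):
    """The model parameters produce unphysical (negative-amplitude) spectra."""


@dataclass(frozen=True)
class Band:
    center_nm: float
    sigma_nm: float
    base_amplitude: float      # absorbance at T_ref
    dAmplitude_per_C: float = 0.0

    def __post_init__(self):
        if self.sigma_nm <= 0:
            raise ModelError(f"sigma must be positive, got {self.sigma_nm}")
        if self.base_amplitude < 0:
            raise ModelError(f"base amplitude must be >= 0, got {self.base_amplitude}")


@dataclass(frozen=True)
class SyntheticWaterModel:
    """Band mixture + baseline + scatter/noise settings."""

    bands: tuple[Band, ...]
    T_ref: float = 45.0
    baseline_offset: float = 0.02
    baseline_slope_per_nm: float = 1e-4     # relative to 1300 nm
    scatter_multiplicative_sd: float = 0.01
    scatter_additive_sd: float = 0.002
    noise_sd: float = 0.001                 # absorbance units
    seed: int = 0

    def amplitudes(self, temperature_C: float, solute_shift=None) -> np.ndarray:
        amps = np.array(
            [b.base_amplitude + b.dAmplitude_per_C * (temperature_C - self.T_ref)
             for b in self.bands]
        )
        if solute_shift is not None:
            amps = amps + np.asarray(solute_shift, dtype=float)
        if np.any(amps < 0):
            bad = int(np.flatnonzero(amps < 0)[0])
            raise ModelError(
                f"band at {self.bands[bad].center_nm} nm has negative amplitude "
                f"{amps[bad]:.4g} at {temperature_C} degC"
            )
        return amps

    def clean_spectrum(
        self, wavelengths_nm: np.ndarray, temperature_C: float, solute_shift=None
    ) -> np.ndarray:
        """Noise- and scatter-free spectrum at one temperature."""
        wl = np.asarray(wavelengths_nm, dtype=float)
        y = self.baseline_offset + self.baseline_slope_per_nm * (wl - 1300.0)
        for band, a in zip(self.bands, self.amplitudes(temperature_C, solute_shift)):
            y = y + a * np.exp(-0.5 * ((wl - band.center_nm) / band.sigma_nm) ** 2)
        return y

    def peak_amplitude(self) -> float:
        """Approximate clean-spectrum maximum at the hottest typical state."""
        wl = np.arange(1300.0, 1600.01, 0.5)
        return float(max(self.clean_spectrum(wl, t).max() for t in (20.0, 45.0, 70.0)))

    def to_yaml(self, path) -> None:
        payload = {
            "bands": [vars(b).copy() for b in self.bands],
            "T_ref": self.T_ref,
            "baseline_offset": self.baseline_offset,
            "baseline_slope_per_nm": self.baseline_slope_per_nm,
            "scatter_multiplicative_sd": self.scatter_multiplicative_sd,
            "scatter_additive_sd": self.scatter_additive_sd,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticWaterModel":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        bands = tuple(Band(**b) for b in payload.pop("bands"))
        return cls(bands=bands, **payload)


def two_band_model(**overrides) -> SyntheticWaterModel:
    """Minimal two-band mechanism (1412 grows, 1462 shrinks, area conserved)."""
    d1 = 0.0045
    bands = (
        Band(1412.0, 22.0, 0.55, +d1),
        Band(1462.0, 30.0, 0.75, -d1 * 22.0 / 30.0),
    )
    return SyntheticWaterModel(bands=bands, **overrides)


def rich_water_model(**overrides) -> SyntheticWaterModel:
    """Five-component model with a usable temperature slope at all 12 WAMACs.

    The amplitude rates conserve total band area (sum of sigma * dA/dT = 0),
    preserving the isosbestic crossing, and are deliberately strong so that
    relative band areas sweep a wide dynamic range over 20-70 degC.
    """
    rates = {1342.0: +0.0070, 1412.0: +0.0090, 1460.0: -0.0020, 1484.0: -0.0035}
    sigmas = {1342.0: 16.0, 1412.0: 22.0, 1460.0: 6.0, 1462.0: 30.0, 1484.0: 18.0}
    d1462 = -sum(sigmas[c] * r for c, r in rates.items()) / sigmas[1462.0]
    bands = (
        Band(1342.0, 16.0, 0.20, rates[1342.0]),
        Band(1412.0, 22.0, 0.85, rates[1412.0]),
        Band(1460.0, 6.0, 0.08, rates[1460.0]),
        Band(1462.0, 30.0, 0.60, d1462),
        Band(1484.0, 18.0, 0.10, rates[1484.0]),
    )
    return SyntheticWaterModel(bands=bands, **overrides)


@dataclass(frozen=True)
class SoluteEffect:
    """Per-band amplitude shift per unit effect, plus a concentration map.

    ``shifts_per_effect`` aligns with the model's band tuple.  The default
    concentration map is linear in log10: effect = log10(1 + c_mM), so high
    concentrations dominate.  Positive ``sign`` is a structure breaker
    (central bulk components feed the wings); ``sign=-1`` flips every shift,
    giving a structure maker.
    """

    shifts_per_effect: tuple[float, ...]
    sign: int = +1

    def effect_of_concentration(self, concentration_mM: float) -> float:
        return float(np.log10(1.0 + concentration_mM))

    def shift(self, concentration_mM: float) -> np.ndarray:
        e = self.effect_of_concentration(concentration_mM)
        return self.sign * e * np.asarray(self.shifts_per_effect, dtype=float)


def default_solute_effect(model: SyntheticWaterModel, sign: int = +1) -> SoluteEffect:
    """Structure-breaker difference spectrum for :func:`rich_water_model`.

    Depletes the 1460/1462 bulk components and feeds the 1342/1412 free-OH
    side and the 1484 ion-hydration band.
    """
    shifts = {1342.0: +0.002, 1412.0: +0.006, 1460.0: -0.014,
              1462.0: -0.007, 1484.0: +0.010}
    per_band = tuple(shifts.get(b.center_nm, 0.0) for b in model.bands)
    if not any(per_band):
        raise ModelError("model has no bands matching the stock solute effect")
    return SoluteEffect(per_band, sign=sign)


def _default_grid(grid) -> np.ndarray:
    if grid is None:
        grid = (1300.0, 1600.0, 0.5)
    lo, hi, step = grid
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def _measure(model, rng, clean, n_scans, records, rows, base_record):
    """Append n_scans noisy measurements of one clean spectrum."""
    for scan in range(1, n_scans + 1):
        a = 1.0 + model.scatter_multiplicative_sd * rng.standard_normal()
        b = model.scatter_additive_sd * rng.standard_normal()
        noise = model.noise_sd * rng.standard_normal(clean.size)
        rows.append(a * clean + b + noise)
        records.append({**base_record, "scan_index": scan})


def simulate_temperature_series(
    model: SyntheticWaterModel,
    temps_C=None,
    n_scans: int = 3,
    grid=None,
    seed: int | None = None,
) -> SpectralDataset:
    """Milli-Q-water-like temperature series.

    Defaults emulate a 20-70 degC ramp in 2 degC increments (26 steps) with
    3 consecutive scans per step, i.e. 78 spectra on the 1300-1600 nm grid
    at 0.5 nm steps.
    """
    if temps_C is None:
        temps_C = np.arange(20.0, 70.01, 2.0)
    wl = _default_grid(grid)
    rng = np.random.default_rng(model.seed if seed is None else seed)
    rows, records = [], []
    for t in temps_C:
        clean = model.clean_spectrum(wl, t)
        base = {
            "sample_id": f"T{t:g}",
            "group_label": f"T{t:g}",
            "temperature_C": float(t),
            "replicate_id": 1,
        }
        _measure(model, rng, clean, n_scans, records, rows, base)
    return SpectralDataset(wl, np.vstack(rows), pd.DataFrame(records))


def simulate_solute_series(
    model: SyntheticWaterModel,
    concentrations_mM=None,
    effect: SoluteEffect | None = None,
    experiment_T: float = 28.0,
    n_reps: int = 2,
    n_scans: int = 3,
    n_control_scans: int = 150,
    grid=None,
    seed: int | None = None,
) -> SpectralDataset:
    """Salt-solution-like series at fixed temperature, with interleaved controls.

    Defaults emulate 30 concentrations (1-1000 mM, log-spaced) x 2 repeats
    x 3 consecutive scans plus 150 zero-concentration control scans, i.e.
    330 spectra.  Control rows carry ``group_label='control'``.
    """
    if concentrations_mM is None:
        concentrations_mM = np.round(np.logspace(0, 3, 30), 3)
    if effect is None:
        effect = default_solute_effect(model)
    wl = _default_grid(grid)
    rng = np.random.default_rng(model.seed if seed is None else seed)
    rows, records = [], []
    n_groups = len(concentrations_mM) * n_reps
    controls_per_slot = n_control_scans // max(n_groups, 1)
    remainder = n_control_scans - controls_per_slot * n_groups
    control_clean = model.clean_spectrum(wl, experiment_T)
    slot = 0
    for c in concentrations_mM:
        shift = effect.shift(c)
        clean = model.clean_spectrum(wl, experiment_T, solute_shift=shift)
        for rep in range(1, n_reps + 1):
            base = {
                "sample_id": f"c{c:g}_r{rep}",
                "group_label": f"c{c:g}",
                "temperature_C": float(experiment_T),
                "concentration_mM": float(c),
                "replicate_id": rep,
            }
            _measure(model, rng, clean, n_scans, records, rows, base)
            slot += 1
            n_ctrl = controls_per_slot + (1 if slot <= remainder else 0)
            ctrl_base = {
                "sample_id": f"control_{slot}",
                "group_label": "control",
                "temperature_C": float(experiment_T),
                "concentration_mM": 0.0,
                "replicate_id": slot,
            }
            _measure(model, rng, control_clean, n_ctrl, records, rows, ctrl_base)
    return SpectralDataset(wl, np.vstack(rows), pd.DataFrame(records))


def isosbestic_wavelength(
    model: SyntheticWaterModel,
    temps_C=None,
    grid=None,
    search_between_main_bands: bool = True,
) -> tuple[float, float]:
    """Wavelength of minimum absorbance variance across a temperature sweep.

    Returns ``(wavelength_nm, sd_to_peak_ratio)`` computed on noiseless
    spectra.  By default the search is restricted to the interval between
    the two strongest band centers, where the crossing of the growing and
    shrinking species bands lives.  The crossing is a property of the
    continuous model and generally falls between instrument grid points,
    so the search uses a fine 0.02 nm grid by default.
    """
    if temps_C is None:
        temps_C = np.arange(20.0, 70.01, 2.0)
    wl = _default_grid(grid if grid is not None else (1300.0, 1600.0, 0.02))
    specs = np.array([model.clean_spectrum(wl, t) for t in temps_C])
    var = specs.var(axis=0)
    if search_between_main_bands:
        strongest = sorted(model.bands, key=lambda b: -b.base_amplitude)[:2]
        lo, hi = sorted(b.center_nm for b in strongest)
        mask = (wl >= lo) & (wl <= hi)
    else:
        mask = np.ones_like(wl, dtype=bool)
    i = int(np.argmin(var[mask]))
    return float(wl[mask][i]), float(np.sqrt(var[mask][i]) / specs.max())
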