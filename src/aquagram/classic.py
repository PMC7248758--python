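"""Classic aquagram: standardized, MSC-corrected absorbance at the WAMACs.

For the set of spectra being plotted together (the "examined set"), the
value of group g at coordinate wavelength lambda is

    A'_lambda(g) = mean over g's spectra of (A_lambda - mu_lambda) / sigma_lambda

where A is the MSC-corrected absorbance over the 1300-1600 nm window and
mu/sigma are the mean and sample SD over *all* spectra in the examined set.
Because mu and sigma depend on the whole set, removing groups from a plot
changes the remaining groups' values - the context dependence that the
temperature-based aquagram was designed to remove.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataset import SpectralDataset, subset_wavelengths
from .preprocess import msc, snv
from .results import AquagramResult
from .temperature import FIRST_OVERTONE
from .wamacs import WamacScheme, default_scheme

__all__ = ["classic_aquagram", "bootstrap_ci", "DegenerateStandardizationError",
           "StandardizationContext"]


class DegenerateStandardizationError(ValueError):
    """sigma_lambda is zero at a WAMAC center (all spectra identical there)."""


class StandardizationContext:
    """Per-wavelength mean and sample SD over the examined set (after MSC)."""

    def __init__(self, corrected: np.ndarray):
        if corrected.shape[0] < 2:
            raise DegenerateStandardizationError(
                "standardization needs at least 2 spectra"
            )
        self.mu_lambda = corrected.mean(axis=0)
        self.sigma_lambda = corrected.std(axis=0, ddof=1)

    def zscore(self, corrected: np.ndarray, columns: np.ndarray) -> np.ndarray:
        return (corrected[:, columns] - self.mu_lambda[columns]) / self.sigma_lambda[
            columns
        ]


def bootstrap_ci(
    groups: dict,
    statistic=None,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Percentile 95% bootstrap intervals of a per-group statistic.

    ``groups`` maps labels to 2-D arrays (rows = observations).  Rows are
    resampled with replacement *within* each group; the statistic (default:
    column mean) is recomputed per replicate and the 2.5/97.5 percentiles
    returned as ``{label: (lcl, ucl)}``.  Reproducible under a fixed seed.
    A single-row group yields a zero-width interval.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if statistic is None:
        statistic = lambda rows: rows.mean(axis=0)
    rng = np.random.default_rng(seed)
    out = {}
    for label, rows in groups.items():
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        n = rows.shape[0]
        stats = np.empty((n_boot, rows.shape[1]))
        for b in range(n_boot):
            stats[b] = statistic(rows[rng.integers(0, n, size=n)])
        out[label] = (
            np.percentile(stats, 2.5, axis=0),
            np.percentile(stats, 97.5, axis=0),
        )
    return out


def classic_aquagram(
    ds: SpectralDataset,
    group_key: str = "group_label",
    scheme: WamacScheme | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    pretreatment: str = "msc",
    scope: str = "set",
) -> AquagramResult:
    """Classic aquagram with bootstrap confidence intervals.

    Pipeline: subset to 1300-1600 nm, scatter-correct the whole examined
    set (MSC against its mean spectrum, or SNV), build mu/sigma from all
    spectra, z-score each spectrum at the 12 WAMAC center wavelengths and
    average the z-scores per group.  Confidence limits come from
    resampling each group's spectra (the standardization context is part
    of the fixed examined set and is not recomputed per replicate).

    ``scope="group"`` standardizes within each group instead - the
    alternative reading of "the examined group" - and is provided for
    comparison only.
    """
    scheme = scheme or default_scheme()
    if group_key not in ds.meta.columns:
        raise ValueError(f"metadata lacks {group_key!r}")
    window = subset_wavelengths(ds, *FIRST_OVERTONE)
    if window.n_spectra < 2:
        raise DegenerateStandardizationError("need at least 2 spectra")
    if pretreatment == "msc":
        corrected = msc(window).dataset.absorbance
    elif pretreatment == "snv":
        corrected = snv(window).absorbance
    else:
        raise ValueError(f"unknown pretreatment {pretreatment!r}")
    cols = np.array([window.wavelength_index(c.center_nm) for c in scheme])

    labels = list(pd.unique(window.meta[group_key]))
    group_rows = {
        label: np.flatnonzero((window.meta[group_key] == label).to_numpy())
        for label in labels
    }

    def context_for(rows: np.ndarray) -> StandardizationContext:
        ctx = StandardizationContext(corrected[rows])
        flat = np.flatnonzero(ctx.sigma_lambda[cols] == 0)
        if flat.size:
            raise DegenerateStandardizationError(
                f"sigma = 0 at coordinate {scheme.ids[flat[0]]} "
                f"({scheme.centers_nm[flat[0]]} nm): all spectra identical there"
            )
        return ctx

    all_rows = np.arange(window.n_spectra)
    rows = []
    if scope == "set":
        ctx = context_for(all_rows)
        z = {label: ctx.zscore(corrected[idx], cols) for label, idx in group_rows.items()}
    elif scope == "group":
        z = {
            label: context_for(idx).zscore(corrected[idx], cols)
            for label, idx in group_rows.items()
        }
    else:
        raise ValueError(f"unknown scope {scope!r}")

    cis = bootstrap_ci(z, n_boot=n_boot, seed=seed)
    for label in labels:
        values = z[label].mean(axis=0)
        lcl, ucl = cis[label]
        lcl = np.minimum(lcl, values)
        ucl = np.maximum(ucl, values)
        for j, cid in enumerate(scheme.ids):
            rows.append(
                {
                    "group": label, "coordinate": cid, "value": values[j],
                    "lcl95": lcl[j], "ucl95": ucl[j], "n": len(group_rows[label]),
                }
            )
    result = AquagramResult(pd.DataFrame(rows), mode="classic")
    result.validate()
    return result
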