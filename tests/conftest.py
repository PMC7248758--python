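import numpy as np
import pandas as pd
import pytest

import aquagram as aq


def noiseless(model_factory, **overrides):
    return model_factory(
        noise_sd=0.0,
        scatter_multiplicative_sd=0.0,
        scatter_additive_sd=0.0,
        **overrides,
    )


@pytest.fixture(scope="session")
def clean_rich_model():
    return noiseless(aq.rich_water_model)


@pytest.fixture(scope="session")
def clean_two_band_model():
    return noiseless(aq.two_band_model)


@pytest.fixture(scope="session")
def reference_ramp(clean_rich_model):
    """Noiseless 20-70 degC ramp, 2 degC steps, 3 consecutive scans (78 rows)."""
    return aq.simulate_temperature_series(clean_rich_model)


def stack(datasets):
    """Concatenate datasets sharing a wavelength grid."""
    wl = datasets[0].wavelengths_nm
    return aq.SpectralDataset(
        wl,
        np.vstack([d.absorbance for d in datasets]),
        pd.concat([d.meta for d in datasets], ignore_index=True),
    )


@pytest.fixture(scope="session")
def groups_27_29(clean_rich_model):
    """Noiseless experimental groups measured at 27 and 29 degC, 3 scans each."""
    return stack(
        [
            aq.simulate_temperature_series(clean_rich_model, temps_C=[t], n_scans=3)
            for t in (27.0, 29.0)
        ]
    )
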