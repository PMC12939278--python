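import numpy as np
import pytest

from millet_nirs import simulate as sim
from millet_nirs.preprocess import SpectraMatrix


@pytest.fixture(scope="session")
def default_grid():
    return sim.make_wavelength_grid()


@pytest.fixture(scope="session")
def small_panel_spectra():
    """A small noiseless-ish synthetic dataset shared across tests."""
    cfg = sim.default_config(n_samples=40, seed=11)
    grid = sim.make_wavelength_grid()
    panel = sim.sample_reference_values(cfg)
    values = sim.generate_spectra(panel, grid, sim.default_band_models(), cfg)
    return panel, SpectraMatrix(tuple(panel.index), grid, values)


def random_spectra(n_samples=8, n_bands=30, seed=0, positive=True):
    """Helper: arbitrary positive spectra on an ad-hoc uniform grid."""
    rng = np.random.default_rng(seed)
    grid = sim.make_wavelength_grid(n_bands=n_bands, spacing=4.715, anchor=992.363, anchor_index=0)
    values = rng.random((n_samples, n_bands)) + (0.1 if positive else -0.5)
    ids = tuple(f"S{i}" for i in range(n_samples))
    return SpectraMatrix(ids, grid, values)
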