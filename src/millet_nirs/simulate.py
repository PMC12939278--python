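"""Synthetic NIR spectra and wet-chemistry reference utilities.

The study's raw hyperspectral cubes and wet-chemistry panels are not
deposited, so every downstream stage is exercised on seeded synthetic data
that reproduces the documented structure of the real measurements:

* a uniform 172-band wavelength grid at 4.715 nm resolution, nominally
  spanning 900-1700 nm, of which the 148 bands in 950-1650 nm are modelled;
* per-sample fat and protein contents drawn from moment-matched skew-normal
  distributions (fat: mean 3.74 %, SD 0.35 %, slight negative skew;
  protein: mean 10.43 %, CV 3.72 %, moderate negative skew);
* reflectance spectra generated by a decadic Beer-Lambert forward model,
  R = 10^(-A) with absorbance linear in analyte content through Gaussian
  absorption bands at the C-H (fat) and N-H/amide (protein) positions,
  plus multiplicative scatter, baseline tilt and additive noise — the
  artefacts SNV and Savitzky-Golay smoothing exist to remove.

Also provided are the reference-method formulas (Soxhlet fat, Kjeldahl
protein) used to convert bench measurements into mass percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "WavelengthGrid",
    "ComponentBandModel",
    "SimulationConfig",
    "CalibrationFrames",
    "SoxhletMeasurement",
    "KjeldahlMeasurement",
    "make_wavelength_grid",
    "sample_reference_values",
    "generate_spectra",
    "make_calibration_frames",
    "make_planted_dataset",
    "soxhlet_fat",
    "kjeldahl_protein",
    "default_band_models",
    "default_config",
]

#: instrument resolution in nm
DEFAULT_SPACING = 4.715
#: number of instrument bands
DEFAULT_N_BANDS = 172
#: a printed protein key wavelength known to lie exactly on the grid
DEFAULT_ANCHOR = 992.363
#: grid start = anchor - 20 spacings = 898.063 nm, so the grid spans
#: 898.063-1704.328 nm and contains 148 bands within [950, 1650]
DEFAULT_ANCHOR_INDEX = 20


@dataclass(frozen=True)
class WavelengthGrid:
    """Ascending, uniformly spaced band axis in nm."""

    values: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("grid must be a non-empty 1-D array")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        diffs = np.diff(values)
        if values.size > 1 and not np.all(diffs > 0):
            raise ValueError("grid must be strictly increasing")
        if values.size > 1 and np.max(np.abs(diffs - self.spacing)) > 1e-3:
            raise ValueError("grid is not uniform at the stated spacing")

    @property
    def n_bands(self) -> int:
        return int(self.values.size)

    def index_of(self, wavelength: float, tol: float = 1e-6) -> int:
        """Index of the grid point equal to ``wavelength`` (within tol)."""
        idx = int(np.argmin(np.abs(self.values - wavelength)))
        if abs(self.values[idx] - wavelength) > tol:
            raise KeyError(f"{wavelength} nm is not a grid point")
        return idx


@dataclass(frozen=True)
class ComponentBandModel:
    """Gaussian absorption bands of one analyte.

    Each band is (center nm, width nm, amplitude), amplitude in absorbance
    units per % analyte content at the band center.
    """

    analyte: str
    bands: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        for center, width, amplitude in self.bands:
            if width <= 0:
                raise ValueError(f"band width must be > 0 (got {width})")
            if amplitude < 0:
                raise ValueError("band amplitude must be >= 0")
            del center

    def absorptivity(self, wavelengths: np.ndarray) -> np.ndarray:
        """Absorbance per % content at each wavelength (sum of Gaussians)."""
        lam = np.asarray(wavelengths, dtype=float)
        k = np.zeros_like(lam)
        for center, width, amplitude in self.bands:
            k += amplitude * np.exp(-0.5 * ((lam - center) / width) ** 2)
        return k


@dataclass(frozen=True)
class AnalyteDistribution:
    """Moment parameterisation of one analyte's content distribution."""

    mean: float
    sd: float
    skew: float = 0.0

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError("analyte mean must be > 0")
        if self.sd < 0:
            raise ValueError("analyte SD must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic-data forward model."""

    n_samples: int = 214
    analytes: dict[str, AnalyteDistribution] = field(
        default_factory=lambda: {
            "fat": AnalyteDistribution(mean=3.74, sd=0.35, skew=-0.13),
            # CV 3.72 % of 10.43 % -> SD 0.388 %
            "protein": AnalyteDistribution(mean=10.43, sd=0.388, skew=-0.41),
        }
    )
    scatter_sd: float = 0.02
    baseline_amplitude: float = 0.03
    noise_sd: float = 0.003
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        for name in ("scatter_sd", "baseline_amplitude", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class CalibrationFrames:
    """Raw, white-reference and dark-reference intensity frames."""

    R0: np.ndarray
    Rw: np.ndarray
    Rb: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.asarray(self.Rw) > np.asarray(self.Rb)):
            raise ValueError("white frame must exceed dark frame everywhere")


@dataclass(frozen=True)
class SoxhletMeasurement:
    """Soxhlet extraction bench readings: flask weight gain P and sample mass m (g)."""

    P: float
    m: float

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ValueError("sample mass must be > 0")
        if self.P < 0:
            raise ValueError("flask weight gain must be >= 0")


@dataclass(frozen=True)
class KjeldahlMeasurement:
    """Kjeldahl titration readings.

    V1/V0 are sample/blank HCl volumes (mL), C the HCl concentration
    (mol/L), m the sample mass (g). The nitrogen factor 0.014 g/mmol and
    the millet nitrogen-to-protein conversion factor 5.83 are fixed.
    """

    V1: float
    V0: float
    C: float
    m: float
    conversion_factor: float = 5.83
    nitrogen_factor: float = 0.014

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ValueError("sample mass must be > 0")
        if self.C <= 0:
            raise ValueError("HCl concentration must be > 0")
        if self.V1 < self.V0:
            raise ValueError("sample titration volume must be >= blank volume")


def make_wavelength_grid(
    n_bands: int = DEFAULT_N_BANDS,
    spacing: float = DEFAULT_SPACING,
    anchor: float = DEFAULT_ANCHOR,
    anchor_index: int | None = None,
) -> WavelengthGrid:
    """Build a uniform band axis that contains ``anchor`` exactly.

    The instrument never states its first band's wavelength, but the
    printed consecutive protein key wavelengths (992.363, 997.077,
    1001.79 nm) pin the grid phase; anchoring at 992.363 nm with the
    default start 20 spacings below reproduces those wavelengths and the
    148-band count in 950-1650 nm.
    """
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if anchor_index is None:
        anchor_index = min(DEFAULT_ANCHOR_INDEX, n_bands - 1)
    if not 0 <= anchor_index < n_bands:
        raise ValueError("anchor_index must fall inside the grid")
    start = anchor - anchor_index * spacing
    values = start + spacing * np.arange(n_bands)
    return WavelengthGrid(values=values, spacing=spacing)


def _skewnorm_params(mean: float, sd: float, skew: float):
    """Moment-match (shape, loc, scale) of a skew-normal distribution.

    Uses the standard inversion of the skew-normal moment formulas; the
    attainable skewness is bounded (|skew| < ~0.995), which covers the
    moderate skews observed in grain composition panels.
    """
    if sd == 0 or skew == 0:
        return 0.0, mean, sd
    g = abs(skew)
    if g >= 0.99:
        raise ValueError("skew-normal cannot express |skewness| >= ~0.99")
    c = (2.0 * g / (4.0 - np.pi)) ** (2.0 / 3.0)
    delta2 = (np.pi / 2.0) * c / (1.0 + c)
    delta = np.sign(skew) * np.sqrt(delta2)
    shape = delta / np.sqrt(1.0 - delta2)
    scale = sd / np.sqrt(1.0 - 2.0 * delta2 / np.pi)
    loc = mean - scale * delta * np.sqrt(2.0 / np.pi)
    return shape, loc, scale


def sample_reference_values(config: SimulationConfig, rng=None):
    """Draw per-sample analyte contents (mass %) from skew-normal laws.

    Returns a pandas-free dict-of-arrays plus sample ids; the preprocess
    module wraps it into a ReferencePanel. Non-positive draws (possible in
    principle in the left tail) are redrawn.
    """
    import pandas as pd

    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_samples
    data = {}
    for name, dist in config.analytes.items():
        if dist.sd == 0:
            values = np.full(n, dist.mean)
        else:
            shape, loc, scale = _skewnorm_params(dist.mean, dist.sd, dist.skew)
            values = stats.skewnorm.rvs(shape, loc=loc, scale=scale, size=n, random_state=rng)
            bad = values <= 0
            while np.any(bad):
                values[bad] = stats.skewnorm.rvs(
                    shape, loc=loc, scale=scale, size=int(bad.sum()), random_state=rng
                )
                bad = values <= 0
        data[name] = values
    ids = [f"S{i:04d}" for i in range(1, n + 1)]
    return pd.DataFrame(data, index=pd.Index(ids, name="sample_id"))


def default_band_models() -> tuple[ComponentBandModel, ComponentBandModel]:
    """Default absorption-band models for fat and protein.

    Fat bands sit at the C-H overtone/combination positions (1048, 1210,
    1390, 1510 nm); protein bands at the N-H/amide positions (995, 1190,
    1270, 1440, 1650 nm). Both share a band at 1341 nm, the overlapping
    C-H/N-H region, so the synthetic spectra carry the fat/protein
    collinearity the real spectra show. Amplitudes are absorbance per %
    content, sized so each analyte's natural variation moves absorbance by
    a few hundredths — comfortably above the additive noise floor but far
    from saturation.
    """
    fat = ComponentBandModel(
        analyte="fat",
        bands=(
            (1048.0, 18.0, 0.020),
            (1210.0, 22.0, 0.028),
            (1341.0, 20.0, 0.012),
            (1390.0, 25.0, 0.022),
            (1510.0, 28.0, 0.018),
        ),
    )
    protein = ComponentBandModel(
        analyte="protein",
        bands=(
            (995.0, 15.0, 0.0065),
            (1190.0, 20.0, 0.0085),
            (1270.0, 22.0, 0.0075),
            (1341.0, 20.0, 0.0045),
            (1440.0, 25.0, 0.0095),
            (1650.0, 30.0, 0.0070),
        ),
    )
    return fat, protein


def default_config(**overrides) -> SimulationConfig:
    """The study-conditions simulation config, optionally overridden."""
    return replace(SimulationConfig(), **overrides) if overrides else SimulationConfig()


def generate_spectra(panel, grid: WavelengthGrid, models, config: SimulationConfig, rng=None):
    """Generate reflectance spectra from analyte contents.

    Absorbance is linear in content, ``A_i = sum_a content_ia * k_a(lam)
    + baseline_i(lam) + eps``, and reflectance is decadic Beer-Lambert
    with multiplicative scatter, ``R_i = 10**(-A_i) * scatter_i``. The
    baseline is a per-sample offset plus linear tilt across the grid
    (what SNV exists to remove); scatter_i ~ Normal(1, scatter_sd).

    Returns an (n_samples, n_bands) float array aligned with ``panel``'s
    rows and ``grid``.
    """
    model_map = {m.analyte: m for m in models}
    panel_analytes = list(panel.columns)
    if set(model_map) != set(panel_analytes):
        raise ValueError(
            f"panel analytes {sorted(panel_analytes)} do not match band models "
            f"{sorted(model_map)}"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    lam = grid.values
    n, d = len(panel), grid.n_bands

    K = np.vstack([model_map[a].absorptivity(lam) for a in panel_analytes])
    contents = panel.to_numpy(dtype=float)
    absorbance = contents @ K

    if config.baseline_amplitude > 0:
        t = (lam - lam.mean()) / (lam.max() - lam.min() + 1e-12)
        offset = rng.uniform(0.0, config.baseline_amplitude, size=n)
        tilt = rng.normal(0.0, config.baseline_amplitude / 2.0, size=n)
        absorbance = absorbance + offset[:, None] + tilt[:, None] * t[None, :]
    if config.noise_sd > 0:
        absorbance = absorbance + rng.normal(0.0, config.noise_sd, size=(n, d))

    reflectance = np.power(10.0, -absorbance)
    if config.scatter_sd > 0:
        scatter = rng.normal(1.0, config.scatter_sd, size=n)
        scatter = np.clip(scatter, 0.5, None)  # keep reflectance positive
        reflectance = reflectance * scatter[:, None]
    if not np.all(np.isfinite(reflectance)) or np.any(reflectance <= 0):
        raise RuntimeError("forward model produced non-finite or non-positive reflectance")
    return reflectance


def make_calibration_frames(
    truth: np.ndarray,
    config: SimulationConfig | None = None,
    dark_level: float = 100.0,
    white_level: float = 4000.0,
) -> CalibrationFrames:
    """Wrap true reflectance into raw/white/dark intensity frames.

    Constructed so the standard two-point calibration
    ``(R0 - Rb) / (Rw - Rb)`` inverts exactly to ``truth``.
    """
    truth = np.asarray(truth, dtype=float)
    Rb = np.full_like(truth, dark_level)
    Rw = np.full_like(truth, white_level)
    R0 = Rb + truth * (Rw - Rb)
    return CalibrationFrames(R0=R0, Rw=Rw, Rb=Rb)


def make_planted_dataset(
    n_samples: int = 300,
    n_bands: int = 148,
    planted: tuple[int, ...] = (12, 47, 75, 103, 131),
    coef_scale: float = 1.0,
    noise_sd: float = 0.3,
    band_corr: float = 0.3,
    seed: int = 0,
):
    """Regression dataset with a known set of informative bands.

    Emulates the wavelength-selection problem in isolation: ``X`` is a
    spectra-like matrix whose neighbouring bands are mildly correlated
    (moving-average smoothing with weight ``band_corr`` on each
    neighbour), and ``y`` depends linearly on exactly the ``planted``
    columns plus Gaussian noise. Coefficients alternate in sign at
    magnitude ``coef_scale``. Returns ``(X, y, planted_indices)``.
    """
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_samples, n_bands))
    X = Z.copy()
    if band_corr > 0:
        X[:, 1:] += band_corr * Z[:, :-1]
        X[:, :-1] += band_corr * Z[:, 1:]
    coefs = coef_scale * np.array([1.0 if i % 2 == 0 else -1.0 for i in range(len(planted))])
    y = X[:, list(planted)] @ coefs + rng.normal(0.0, noise_sd, size=n_samples)
    return X, y, tuple(planted)


def soxhlet_fat(meas: SoxhletMeasurement) -> float:
    """Fat content (%) from Soxhlet extraction: 100 * P / m."""
    return 100.0 * meas.P / meas.m


def kjeldahl_protein(meas: KjeldahlMeasurement) -> float:
    """Protein content (%) from Kjeldahl titration.

    100 * (V1 - V0) * C * 0.014 * 5.83 / m, with 5.83 the foxtail-millet
    nitrogen-to-protein conversion factor.
    """
    return (
        100.0
        * (meas.V1 - meas.V0)
        * meas.C
        * meas.nitrogen_factor
        * meas.conversion_factor
        / meas.m
    )
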