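"""Reflectance calibration, spectral preprocessing and dataset handling.

Covers every step between raw instrument frames and model-ready data:
two-point reflectance calibration against white/dark references, cropping
to the effective 950-1650 nm modelling interval, Savitzky-Golay smoothing,
Standard Normal Variate scatter correction, interquartile-range outlier
screening of the reference values, descriptive statistics, and the 3:1
hold-out split into training and prediction sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .simulate import CalibrationFrames, WavelengthGrid

__all__ = [
    "SpectraMatrix",
    "AnalyteStats",
    "SplitAssignment",
    "calibrate_reflectance",
    "crop_wavelengths",
    "sg_smooth",
    "snv",
    "to_absorbance",
    "iqr_outliers",
    "describe",
    "holdout_split",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_panel_csv",
    "write_panel_csv",
]


@dataclass(frozen=True)
class SpectraMatrix:
    """Samples x bands spectral values on a shared wavelength grid."""

    sample_ids: tuple[str, ...]
    grid: WavelengthGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if values.ndim != 2:
            raise ValueError("values must be a 2-D samples x bands array")
        if values.shape[0] != len(self.sample_ids):
            raise ValueError("row count must match sample_ids")
        if values.shape[1] != self.grid.n_bands:
            raise ValueError("column count must match the wavelength grid")
        if not np.all(np.isfinite(values)):
            raise ValueError("spectra contain NaN or Inf")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, ids) -> "SpectraMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in ids]
        return SpectraMatrix(tuple(ids), self.grid, self.values[rows])

    def select_bands(self, indices) -> "SpectraMatrix":
        indices = np.asarray(indices, dtype=int)
        sub = self.grid.values[indices]
        spacing = self.grid.spacing
        # a band subset is generally non-uniform; keep a grid-like axis by
        # relaxing the uniformity check through direct construction
        grid = WavelengthGrid.__new__(WavelengthGrid)
        object.__setattr__(grid, "values", sub)
        object.__setattr__(grid, "spacing", spacing)
        return SpectraMatrix(self.sample_ids, grid, self.values[:, indices])


@dataclass(frozen=True)
class AnalyteStats:
    """Descriptive statistics of one analyte's reference values (all in %)."""

    n: int
    mean: float
    sd: float
    cv: float
    skewness: float
    kurtosis: float  # non-excess (normal = 3)
    median: float
    q1: float
    q3: float
    ci_low: float
    ci_high: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class SplitAssignment:
    """Hold-out partition into training and prediction sets."""

    training: tuple[str, ...]
    prediction: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if set(self.training) & set(self.prediction):
            raise ValueError("training and prediction sets overlap")


def calibrate_reflectance(frames: CalibrationFrames) -> np.ndarray:
    """Two-point reflectance calibration R = (R0 - Rb) / (Rw - Rb)."""
    Rw = np.asarray(frames.Rw, dtype=float)
    Rb = np.asarray(frames.Rb, dtype=float)
    denom = Rw - Rb
    if np.any(denom == 0):
        raise ValueError("white and dark frames coincide at some band")
    return (np.asarray(frames.R0, dtype=float) - Rb) / denom


def crop_wavelengths(spectra: SpectraMatrix, low: float, high: float) -> SpectraMatrix:
    """Retain bands with low <= lambda <= high (closed interval).

    The spectral edges below 950 nm and above 1650 nm are dominated by
    instrument dark-current noise and are discarded before modelling.
    """
    if low >= high:
        raise ValueError("low must be < high")
    lam = spectra.grid.values
    mask = (lam >= low) & (lam <= high)
    if not np.any(mask):
        raise ValueError(f"no bands fall inside [{low}, {high}] nm")
    grid = WavelengthGrid(values=lam[mask], spacing=spectra.grid.spacing)
    return SpectraMatrix(spectra.sample_ids, grid, spectra.values[:, mask])


def sg_smooth(spectra: SpectraMatrix, window: int = 11, polyorder: int = 2) -> SpectraMatrix:
    """Per-spectrum Savitzky-Golay smoothing (local least-squares polynomial fit)."""
    if window % 2 != 1:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if window > spectra.n_bands:
        raise ValueError("window exceeds the number of bands")
    smoothed = signal.savgol_filter(spectra.values, window, polyorder, axis=1)
    return SpectraMatrix(spectra.sample_ids, spectra.grid, smoothed)


def snv(spectra: SpectraMatrix) -> SpectraMatrix:
    """Standard Normal Variate: centre and unit-scale each spectrum (ddof=1).

    Removes per-sample multiplicative scatter and additive baseline offsets.
    """
    X = spectra.values
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("a constant spectrum cannot be SNV-scaled")
    return SpectraMatrix(spectra.sample_ids, spectra.grid, (X - mu) / sd)


def to_absorbance(spectra: SpectraMatrix) -> SpectraMatrix:
    """Decadic absorbance log10(1/R); requires strictly positive reflectance."""
    if np.any(spectra.values <= 0):
        raise ValueError("reflectance must be positive for absorbance conversion")
    return SpectraMatrix(spectra.sample_ids, spectra.grid, -np.log10(spectra.values))


def iqr_outliers(panel: pd.DataFrame, analyte: str, k: float = 1.5) -> list[str]:
    """Sample ids whose analyte value falls outside [Q1 - k*IQR, Q3 + k*IQR].

    Screening is per analyte: a sample flagged for protein is removed from
    the protein dataset only, leaving the fat dataset intact.
    """
    values = panel[analyte].to_numpy(dtype=float)
    if values.size < 4:
        raise ValueError("IQR screening needs at least 4 samples")
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    low, high = q1 - k * iqr, q3 + k * iqr
    mask = (values < low) | (values > high)
    return [s for s, m in zip(panel.index, mask) if m]


def describe(panel: pd.DataFrame, analyte: str) -> AnalyteStats:
    """Descriptive statistics with the conventions used throughout.

    SD uses the n-1 denominator, kurtosis is the non-excess (Pearson)
    moment ratio so a normal law scores 3, and the 95 % CI of the mean is
    the Student-t interval.
    """
    x = panel[analyte].to_numpy(dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("describe needs at least 2 samples")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    q1, med, q3 = (float(v) for v in np.percentile(x, [25, 50, 75]))
    half = stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
    if sd == 0:  # shape moments are undefined for constant data
        skewness = kurt = 0.0
    else:
        skewness = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=False, bias=True))
    return AnalyteStats(
        n=n,
        mean=mean,
        sd=sd,
        cv=100.0 * sd / mean,
        skewness=skewness,
        kurtosis=kurt,
        median=med,
        q1=q1,
        q3=q3,
        ci_low=mean - half,
        ci_high=mean + half,
    )


def holdout_split(ids, ratio: float = 0.75, seed: int = 0) -> SplitAssignment:
    """Random hold-out split with round-half-up training size.

    ratio=0.75 gives the 3:1 allocation: 214 samples -> 161/53 and
    192 samples -> 144/48.
    """
    ids = list(ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    n_train = int(math.floor(ratio * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    order = np.random.default_rng(seed).permutation(n)
    train = tuple(ids[i] for i in sorted(order[:n_train]))
    pred = tuple(ids[i] for i in sorted(order[n_train:]))
    return SplitAssignment(training=train, prediction=pred, seed=seed)


# ---------------------------------------------------------------------------
# CSV dialects

def write_spectra_csv(spectra: SpectraMatrix, path) -> None:
    """Spectra CSV: sample_id column, then one column per band named by
    wavelength with 3 decimals."""
    cols = [f"{lam:.3f}" for lam in spectra.grid.values]
    df = pd.DataFrame(spectra.values, columns=cols)
    df.insert(0, "sample_id", list(spectra.sample_ids))
    df.to_csv(path, index=False)


def read_spectra_csv(path, spacing: float = 4.715) -> SpectraMatrix:
    df = pd.read_csv(path)
    ids = tuple(str(s) for s in df["sample_id"])
    lam = np.array([float(c) for c in df.columns[1:]])
    grid = WavelengthGrid(values=lam, spacing=spacing)
    return SpectraMatrix(ids, grid, df.iloc[:, 1:].to_numpy(dtype=float))


def write_panel_csv(panel: pd.DataFrame, path) -> None:
    """Reference panel CSV: sample_id, then one mass-% column per analyte."""
    out = panel.copy()
    out.insert(0, "sample_id", panel.index)
    out.to_csv(path, index=False)


def read_panel_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["sample_id"] = df["sample_id"].astype(str)
    return df.set_index("sample_id")
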