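"""Calibration, smoothing, SNV, outlier screening, stats and splitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from millet_nirs import preprocess as prep
from millet_nirs import simulate as sim
from tests.conftest import random_spectra


class TestCalibration:
    def test_hand_arithmetic(self):
        frames = sim.CalibrationFrames(
            R0=np.full((1, 1), 60.0), Rw=np.full((1, 1), 110.0), Rb=np.full((1, 1), 10.0)
        )
        assert prep.calibrate_reflectance(frames)[0, 0] == pytest.approx(0.5)

    def test_references_map_to_zero_and_one(self):
        Rb, Rw = np.full((1, 3), 50.0), np.full((1, 3), 4000.0)
        assert np.allclose(
            prep.calibrate_reflectance(sim.CalibrationFrames(R0=Rb, Rw=Rw, Rb=Rb)), 0.0
        )
        assert np.allclose(
            prep.calibrate_reflectance(sim.CalibrationFrames(R0=Rw, Rw=Rw, Rb=Rb)), 1.0
        )

    def test_round_trip_with_simulator_frames(self):
        rng = np.random.default_rng(0)
        truth = rng.random((6, 20)) * 0.8 + 0.1
        recovered = prep.calibrate_reflectance(sim.make_calibration_frames(truth))
        assert np.max(np.abs(recovered - truth) / truth) < 1e-12


class TestCrop:
    def test_default_grid_crops_to_148_bands(self):
        spectra = random_spectra(n_samples=3, n_bands=172, seed=1)
        spectra = prep.SpectraMatrix(
            spectra.sample_ids, sim.make_wavelength_grid(), spectra.values
        )
        cropped = prep.crop_wavelengths(spectra, 950.0, 1650.0)
        assert cropped.n_bands == 148
        assert cropped.grid.values[0] >= 950.0
        assert cropped.grid.values[-1] <= 1650.0

    def test_full_range_is_identity(self):
        spectra = random_spectra(seed=2)
        lam = spectra.grid.values
        cropped = prep.crop_wavelengths(spectra, lam[0], lam[-1])
        assert np.array_equal(cropped.values, spectra.values)

    def test_empty_interval_raises(self):
        with pytest.raises(ValueError, match="no bands"):
            prep.crop_wavelengths(random_spectra(), 2000.0, 2100.0)


class TestSavitzkyGolay:
    def test_constant_spectrum_unchanged(self):
        spectra = random_spectra(n_samples=1, n_bands=25, seed=0)
        const = prep.SpectraMatrix(
            spectra.sample_ids, spectra.grid, np.full_like(spectra.values, 2.5)
        )
        assert np.allclose(prep.sg_smooth(const, 7, 2).values, 2.5)

    def test_quadratic_reproduced_exactly(self):
        spectra = random_spectra(n_samples=1, n_bands=31, seed=0)
        t = np.arange(31, dtype=float)
        quad = prep.SpectraMatrix(
            spectra.sample_ids, spectra.grid, (0.3 * t**2 - 2 * t + 1)[None, :]
        )
        out = prep.sg_smooth(quad, 11, 2)
        assert np.max(np.abs(out.values - quad.values)) < 1e-9

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(4)
        spectra = random_spectra(n_samples=1, n_bands=120, seed=0)
        t = np.linspace(0, 4 * np.pi, 120)
        clean = np.sin(t)
        noisy = clean + rng.normal(0, 0.2, size=120)
        sm = prep.sg_smooth(
            prep.SpectraMatrix(spectra.sample_ids, spectra.grid, noisy[None, :]), 11, 2
        ).values[0]
        assert np.var(sm - clean) < np.var(noisy - clean)

    @pytest.mark.parametrize("window,order", [(10, 2), (5, 5), (201, 2)])
    def test_invalid_parameters(self, window, order):
        with pytest.raises(ValueError):
            prep.sg_smooth(random_spectra(n_bands=100), window, order)


class TestSNV:
    def test_known_rows(self):
        spectra = random_spectra(n_samples=2, n_bands=3, seed=0)
        X = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]])
        out = prep.snv(prep.SpectraMatrix(spectra.sample_ids, spectra.grid, X))
        assert np.allclose(out.values, [[-1, 0, 1], [-1, 0, 1]])

    def test_rows_standardised_and_idempotent(self):
        spectra = random_spectra(n_samples=6, n_bands=40, seed=5)
        once = prep.snv(spectra)
        assert np.max(np.abs(once.values.mean(axis=1))) < 1e-12
        assert np.max(np.abs(once.values.std(axis=1, ddof=1) - 1)) < 1e-12
        twice = prep.snv(once)
        assert np.max(np.abs(twice.values - once.values)) < 1e-12

    def test_constant_spectrum_rejected(self):
        spectra = random_spectra(n_samples=1, n_bands=5, seed=0)
        const = prep.SpectraMatrix(
            spectra.sample_ids, spectra.grid, np.ones_like(spectra.values)
        )
        with pytest.raises(ValueError):
            prep.snv(const)


class TestIQROutliers:
    @staticmethod
    def _panel(values, analyte="protein"):
        ids = [f"S{i}" for i in range(len(values))]
        return pd.DataFrame({analyte: values}, index=pd.Index(ids, name="sample_id"))

    def test_single_gross_outlier_flagged(self):
        panel = self._panel(list(range(1, 11)) + [100])
        assert prep.iqr_outliers(panel, "protein") == ["S10"]

    def test_constant_values_flag_nothing(self):
        panel = self._panel([5.0] * 8)
        assert prep.iqr_outliers(panel, "protein") == []

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(6)
        values = np.concatenate([rng.normal(10, 0.4, 50), [14.0, 6.0]])
        panel = self._panel(values)
        q1, q3 = np.percentile(values, [25, 75])
        lo, hi = q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1)
        expected = [f"S{i}" for i, v in enumerate(values) if v < lo or v > hi]
        assert prep.iqr_outliers(panel, "protein") == expected

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            prep.iqr_outliers(self._panel([1.0, 2.0, 3.0]), "protein")


class TestDescribe:
    @staticmethod
    def _panel(values):
        ids = [f"S{i}" for i in range(len(values))]
        return pd.DataFrame({"fat": values}, index=pd.Index(ids, name="sample_id"))

    def test_hand_arithmetic(self):
        stats = prep.describe(self._panel([1.0, 2.0, 3.0, 4.0, 5.0]), "fat")
        assert stats.mean == pytest.approx(3.0)
        assert stats.sd == pytest.approx(1.5811, abs=1e-4)
        assert stats.cv == pytest.approx(100 * 1.5811 / 3.0, abs=1e-2)
        assert stats.median == 3.0

    def test_constant_data(self):
        stats = prep.describe(self._panel([2.0] * 5), "fat")
        assert stats.sd == 0.0
        assert stats.cv == 0.0

    def test_kurtosis_is_non_excess_convention(self):
        rng = np.random.default_rng(8)
        stats = prep.describe(self._panel(rng.normal(0, 1, 10000) + 10), "fat")
        assert stats.kurtosis == pytest.approx(3.0, abs=0.15)

    def test_agrees_with_moment_oracle(self):
        rng = np.random.default_rng(9)
        x = rng.random(200) * 3 + 1
        stats = prep.describe(self._panel(x), "fat")
        n, mean = x.size, x.mean()
        sd = np.sqrt(((x - mean) ** 2).sum() / (n - 1))
        m2 = ((x - mean) ** 2).mean()
        m3 = ((x - mean) ** 3).mean()
        m4 = ((x - mean) ** 4).mean()
        assert abs(stats.mean - mean) < 1e-10
        assert abs(stats.sd - sd) < 1e-10
        assert abs(stats.skewness - m3 / m2**1.5) < 1e-10
        assert abs(stats.kurtosis - m4 / m2**2) < 1e-10
        assert stats.q1 <= stats.median <= stats.q3
        assert stats.ci_low <= stats.mean <= stats.ci_high


class TestHoldoutSplit:
    @pytest.mark.parametrize("n,expected", [(214, (161, 53)), (192, (144, 48)), (4, (3, 1))])
    def test_study_partition_sizes(self, n, expected):
        split = prep.holdout_split([f"S{i}" for i in range(n)], 0.75, seed=0)
        assert (len(split.training), len(split.prediction)) == expected

    @given(n=st.integers(2, 400), seed=st.integers(0, 2**16))
    @settings(max_examples=40, deadline=None)
    def test_partition_property(self, n, seed):
        ids = [f"S{i}" for i in range(n)]
        split = prep.holdout_split(ids, 0.75, seed=seed)
        assert set(split.training) | set(split.prediction) == set(ids)
        assert not set(split.training) & set(split.prediction)

    def test_reproducible_under_seed(self):
        ids = [f"S{i}" for i in range(50)]
        assert prep.holdout_split(ids, seed=3) == prep.holdout_split(ids, seed=3)
        assert prep.holdout_split(ids, seed=3) != prep.holdout_split(ids, seed=4)

    def test_invalid_ratio(self):
        with pytest.raises(ValueError):
            prep.holdout_split(["a", "b"], ratio=1.0)


class TestCsvRoundTrip:
    def test_spectra_and_panel_round_trip(self, tmp_path):
        spectra = random_spectra(n_samples=4, n_bands=12, seed=3)
        prep.write_spectra_csv(spectra, tmp_path / "x.csv")
        back = prep.read_spectra_csv(tmp_path / "x.csv")
        assert back.sample_ids == spectra.sample_ids
        assert np.allclose(back.values, spectra.values)
        assert np.allclose(back.grid.values, np.round(spectra.grid.values, 3))

        panel = pd.DataFrame(
            {"fat": [3.5, 3.9], "protein": [10.2, 10.6]},
            index=pd.Index(["A", "B"], name="sample_id"),
        )
        prep.write_panel_csv(panel, tmp_path / "y.csv")
        assert prep.read_panel_csv(tmp_path / "y.csv").equals(panel)
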