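"""Generate the synthetic study dataset.

Draws a 300-sample reference panel (fat and protein contents with the
study's distributional shape) and the matching 172-band reflectance
spectra from the Beer-Lambert forward model, then writes both as CSV
under results/data/.
"""

from pathlib import Path

from millet_nirs import preprocess as prep
from millet_nirs import simulate as sim

SEED = 1
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = sim.default_config(n_samples=300, seed=SEED)
    grid = sim.make_wavelength_grid()
    panel = sim.sample_reference_values(cfg)
    reflectance = sim.generate_spectra(panel, grid, sim.default_band_models(), cfg)
    frames = sim.make_calibration_frames(reflectance, cfg)
    spectra = prep.SpectraMatrix(
        tuple(panel.index), grid, prep.calibrate_reflectance(frames)
    )
    prep.write_spectra_csv(spectra, OUT / "spectra.csv")
    prep.write_panel_csv(panel, OUT / "panel.csv")
    print(f"{spectra.n_samples} samples x {spectra.n_bands} bands -> {OUT}")
    for analyte in ("fat", "protein"):
        stats = prep.describe(panel, analyte)
        print(
            f"  {analyte}: mean {stats.mean:.2f}%  SD {stats.sd:.3f}%  "
            f"CV {stats.cv:.2f}%  skew {stats.skewness:.2f}"
        )


if __name__ == "__main__":
    main()
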