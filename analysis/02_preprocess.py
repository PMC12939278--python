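"""Preprocess the spectra and split each analyte's dataset.

Crops to the 950-1650 nm modelling interval (148 bands), applies
Savitzky-Golay smoothing (window 11, order 2) then SNV, screens
reference outliers per analyte with the 1.5 x IQR rule, and performs the
3:1 hold-out split. Writes the processed spectra, per-analyte panels and
a JSON report under results/preprocess/.
"""

import json
from pathlib import Path

from millet_nirs import preprocess as prep

SEED = 1
DATA = Path("results/data")
OUT = Path("results/preprocess")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spectra = prep.read_spectra_csv(DATA / "spectra.csv")
    panel = prep.read_panel_csv(DATA / "panel.csv")

    processed = prep.snv(prep.sg_smooth(prep.crop_wavelengths(spectra, 950, 1650)))
    prep.write_spectra_csv(processed, OUT / "spectra_processed.csv")
    print(f"preprocessed: {processed.n_bands} bands retained")

    report = {}
    for k, analyte in enumerate(("fat", "protein")):
        flagged = set(prep.iqr_outliers(panel, analyte))
        kept = [s for s in panel.index if s not in flagged]
        split = prep.holdout_split(kept, 0.75, seed=SEED + 1000 + k)
        stats = prep.describe(panel.loc[kept], analyte)
        report[analyte] = {
            "n_outliers": len(flagged),
            "n_retained": len(kept),
            "n_train": len(split.training),
            "n_prediction": len(split.prediction),
            "training_ids": list(split.training),
            "prediction_ids": list(split.prediction),
            "stats": stats.as_dict(),
        }
        prep.write_panel_csv(panel.loc[kept], OUT / f"panel_{analyte}.csv")
        print(
            f"  {analyte}: removed {len(flagged)} outliers, kept {len(kept)}, "
            f"split {len(split.training)}/{len(split.prediction)}"
        )
    with open(OUT / "preprocess.json", "w") as fh:
        json.dump(report, fh, indent=2)


if __name__ == "__main__":
    main()
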