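"""Fit and evaluate the calibration models on the selected wavelengths.

Trains PLS, random forest and SVR on each analyte's training partition
restricted to its chosen wavelength set, scores R2/RMSE/RPD on both
partitions, and writes the ranked metrics table to
results/models/metrics.csv.
"""

import json
from pathlib import Path

import pandas as pd

from millet_nirs import model as mod
from millet_nirs import preprocess as prep

SEED = 1
OUT = Path("results/models")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spectra = prep.read_spectra_csv(Path("results/preprocess/spectra_processed.csv"))
    with open("results/preprocess/preprocess.json") as fh:
        split_info = json.load(fh)

    rows = []
    for analyte in ("fat", "protein"):
        panel = prep.read_panel_csv(f"results/preprocess/panel_{analyte}.csv")
        with open(f"results/select/best_set_{analyte}.json") as fh:
            chosen_nm = json.load(fh)["wavelengths_nm"]
        idx = [spectra.grid.index_of(w, tol=5e-4) for w in chosen_nm]

        tr = split_info[analyte]["training_ids"]
        te = split_info[analyte]["prediction_ids"]
        Xtr = spectra.subset_samples(tr).values[:, idx]
        Xte = spectra.subset_samples(te).values[:, idx]
        ytr = panel.loc[tr, analyte].to_numpy()
        yte = panel.loc[te, analyte].to_numpy()

        reports = []
        for family in ("PLS", "RF", "SVM"):
            m = mod.fit(mod.ModelSpec(family=family, seed=SEED + 5000), Xtr, ytr)
            reports.append(mod.evaluate_model(m, Xtr, ytr, Xte, yte))
        for rank, r in enumerate(mod.compare(reports), start=1):
            rows.append({"Type": analyte, "Rank": rank, **r.as_dict()})
        best = rows[-3]
        print(
            f"{analyte}: best {best['Model']} "
            f"R2_P={best['R2_P']:.3f} RMSE_P={best['RMSE_P']:.3f}% "
            f"RPD_P={best['RPD_P']:.3f}"
        )
    pd.DataFrame(rows).to_csv(OUT / "metrics.csv", index=False)


if __name__ == "__main__":
    main()
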