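"""Sparrow-search wavelength selection with frequency-stability screening.

For each analyte: 20 independent SSA runs (population 30, 100
iterations) on the training partition, per-band selection frequencies,
the three candidate-set strategies, and 5-fold CV PLS adjudication.
Writes frequency tables and the chosen wavelength sets under
results/select/. The full protocol scale (50 runs, population 100, 500
iterations) is a flag away but takes correspondingly longer.
"""

import json
from pathlib import Path

import pandas as pd

from millet_nirs import preprocess as prep
from millet_nirs import select as sel

SEED = 1
OUT = Path("results/select")
N_RUNS, POPULATION, ITERATIONS = 20, 30, 100


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spectra = prep.read_spectra_csv(Path("results/preprocess/spectra_processed.csv"))
    with open("results/preprocess/preprocess.json") as fh:
        split_info = json.load(fh)

    for k, analyte in enumerate(("fat", "protein")):
        panel = prep.read_panel_csv(f"results/preprocess/panel_{analyte}.csv")
        train_ids = split_info[analyte]["training_ids"]
        X = spectra.subset_samples(train_ids).values
        y = panel.loc[train_ids, analyte].to_numpy()

        cfg = sel.SSAConfig(
            population=POPULATION, iterations=ITERATIONS, seed=SEED + 10_000 + 1000 * k
        )
        runs, freq = sel.repeat_runs(X, y, cfg, n_runs=N_RUNS)
        lam = spectra.grid.values
        pd.DataFrame(
            {"wavelength_nm": lam, "selection_probability": freq.probabilities}
        ).to_csv(OUT / f"frequency_{analyte}.csv", index=False)

        best = sel.adjudicate(sel.build_candidate_sets(freq), X, y, seed=cfg.seed)
        chosen_nm = [round(float(lam[i]), 3) for i in best.indices]
        with open(OUT / f"best_set_{analyte}.json", "w") as fh:
            json.dump(
                {
                    "analyte": analyte,
                    "strategy": best.strategy,
                    "wavelengths_nm": chosen_nm,
                    "n_selected": len(chosen_nm),
                    "fraction_of_bands_pct": 100.0 * len(chosen_nm) / len(lam),
                    "cv_mse": best.cv_mse,
                    "cv_rmse": best.cv_rmse,
                },
                fh,
                indent=2,
            )
        print(
            f"{analyte}: {len(chosen_nm)}/{len(lam)} wavelengths "
            f"({100.0 * len(chosen_nm) / len(lam):.3f}%), strategy {best.strategy}, "
            f"CV MSE {best.cv_mse:.4f}"
        )


if __name__ == "__main__":
    main()
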