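"""Shapley interpretation of each analyte's best calibration model.

Refits the top-ranked family per analyte, computes per-sample Shapley
attributions on the prediction partition (exact for PLS, permutation
sampling against the training background otherwise), and writes the
attribution matrices plus contribution reports (rates, cumulative
coverage, direction of mean effect) under results/explain/.
"""

import json
from pathlib import Path

import pandas as pd

from millet_nirs import explain as expl
from millet_nirs import model as mod
from millet_nirs import preprocess as prep

SEED = 1
OUT = Path("results/explain")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spectra = prep.read_spectra_csv(Path("results/preprocess/spectra_processed.csv"))
    with open("results/preprocess/preprocess.json") as fh:
        split_info = json.load(fh)
    metrics = pd.read_csv("results/models/metrics.csv")

    for k, analyte in enumerate(("fat", "protein")):
        panel = prep.read_panel_csv(f"results/preprocess/panel_{analyte}.csv")
        with open(f"results/select/best_set_{analyte}.json") as fh:
            chosen_nm = json.load(fh)["wavelengths_nm"]
        idx = [spectra.grid.index_of(w, tol=5e-4) for w in chosen_nm]
        best_family = metrics.query("Type == @analyte and Rank == 1")["Model"].item()

        tr = split_info[analyte]["training_ids"]
        te = split_info[analyte]["prediction_ids"]
        Xtr = spectra.subset_samples(tr).values[:, idx]
        Xte = spectra.subset_samples(te).values[:, idx]
        ytr = panel.loc[tr, analyte].to_numpy()

        m = mod.fit(mod.ModelSpec(family=best_family, seed=SEED + 5000), Xtr, ytr)
        names = [f"{w:.3f}" for w in chosen_nm]
        if best_family == "PLS":
            shap = expl.shap_linear(m, Xte, Xtr, feature_names=names)
        else:
            shap = expl.shap_tree(
                m, Xte, Xtr, n_permutations=200, seed=SEED + 7000 + k,
                feature_names=names,
            )
        contrib = expl.summarize(shap)
        pd.DataFrame(shap.values, index=te, columns=names).to_csv(
            OUT / f"shap_{analyte}.csv", index_label="sample_id"
        )
        with open(OUT / f"contrib_{analyte}.json", "w") as fh:
            json.dump(contrib.as_dict(), fh, indent=2)
        positives = int((contrib.mean_signed > 0).sum())
        print(
            f"{analyte} ({best_family}): {positives} wavelengths drive predictions "
            f"upward on average; top {contrib.k80} cover 80% of contribution, "
            f"top {contrib.k95} cover 95%"
        )


if __name__ == "__main__":
    main()
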