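"""End-to-end orchestration: simulate -> preprocess -> select -> model -> explain.

A single PipelineConfig drives all stages for one or more analytes; a
master seed deterministically derives every stage seed, so rerunning the
same configuration reproduces every artifact bit-identically. Outputs per
run: the simulated spectra and reference panel, descriptive statistics,
per-analyte selection-frequency tables and chosen wavelength sets, a
metrics table across model families, Shapley attribution and contribution
reports for the best model, and a JSON manifest recording seeds and
parameters.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import explain as explain_mod
from . import model as model_mod
from . import preprocess as prep
from . import select as select_mod
from . import simulate as sim

__all__ = ["PipelineConfig", "demo_config", "full_config", "run_pipeline"]

# fixed offsets deriving stage seeds from the master seed
_SEED_SIM = 0
_SEED_SPLIT = 1_000
_SEED_SSA = 10_000  # + 1000 per analyte branch
_SEED_MODEL = 5_000
_SEED_SHAP = 7_000


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters plus the master seed and output directory."""

    out_dir: str = "results/pipeline"
    seed: int = 0
    analytes: tuple[str, ...] = ("fat", "protein")
    n_samples: int = 300
    # preprocessing
    crop: tuple[float, float] = (950.0, 1650.0)
    sg_window: int = 11
    sg_polyorder: int = 2
    train_ratio: float = 0.75
    iqr_k: float = 1.5
    # selection
    n_runs: int = 20
    population: int = 30
    iterations: int = 100
    inner_components: int = 5
    # modelling
    families: tuple[str, ...] = ("PLS", "RF", "SVM")
    # interpretation
    n_permutations: int = 200

    def __post_init__(self) -> None:
        if self.seed < 0 or self.seed + _SEED_SSA + 1000 * len(self.analytes) >= 2**31:
            raise ValueError("master seed out of range")


def demo_config(**overrides) -> PipelineConfig:
    """Desk-scale demo: 300 samples, 20 SSA runs, population 30, 100 iterations."""
    return dataclasses.replace(PipelineConfig(), **overrides)


def full_config(**overrides) -> PipelineConfig:
    """Full protocol scale: 50 SSA runs, population 100, 500 iterations."""
    cfg = PipelineConfig(n_samples=214, n_runs=50, population=100, iterations=500)
    return dataclasses.replace(cfg, **overrides)


def _log(messages: list, stage: str, t0: float, detail: str = "") -> None:
    line = f"[{stage}] {time.perf_counter() - t0:.1f}s {detail}".rstrip()
    messages.append(line)
    print(line)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the report bundle and writes artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    t0 = time.perf_counter()
    bundle: dict = {"analytes": {}}

    try:
        stage = "simulate"
        sim_cfg = sim.default_config(n_samples=config.n_samples, seed=config.seed + _SEED_SIM)
        grid = sim.make_wavelength_grid()
        panel = sim.sample_reference_values(sim_cfg)
        models = sim.default_band_models()
        reflectance = sim.generate_spectra(panel, grid, models, sim_cfg)
        frames = sim.make_calibration_frames(reflectance, sim_cfg)
        spectra = prep.SpectraMatrix(
            tuple(panel.index), grid, prep.calibrate_reflectance(frames)
        )
        prep.write_spectra_csv(spectra, out / "spectra.csv")
        prep.write_panel_csv(panel, out / "panel.csv")
        _log(log, stage, t0, f"{spectra.n_samples} samples x {spectra.n_bands} bands")

        stage = "preprocess"
        cropped = prep.crop_wavelengths(spectra, *config.crop)
        smoothed = prep.sg_smooth(cropped, config.sg_window, config.sg_polyorder)
        snv_spectra = prep.snv(smoothed)
        stats_report = {}
        branches = {}
        for k, analyte in enumerate(config.analytes):
            flagged = prep.iqr_outliers(panel, analyte, config.iqr_k)
            kept = [s for s in panel.index if s not in set(flagged)]
            sub_panel = panel.loc[kept]
            stats_report[analyte] = {
                "n_outliers": len(flagged),
                "n_retained": len(kept),
                **prep.describe(sub_panel, analyte).as_dict(),
            }
            split = prep.holdout_split(
                kept, config.train_ratio, seed=config.seed + _SEED_SPLIT + k
            )
            branches[analyte] = (sub_panel, split)
        with open(out / "stats.json", "w") as fh:
            json.dump(stats_report, fh, indent=2)
        bundle["stats"] = stats_report
        _log(log, stage, t0, f"bands {snv_spectra.n_bands}")

        for k, analyte in enumerate(config.analytes):
            sub_panel, split = branches[analyte]
            X_all = snv_spectra.subset_samples(sub_panel.index)
            X_train = X_all.subset_samples(split.training).values
            X_test = X_all.subset_samples(split.prediction).values
            y_train = sub_panel.loc[list(split.training), analyte].to_numpy()
            y_test = sub_panel.loc[list(split.prediction), analyte].to_numpy()
            lam = snv_spectra.grid.values

            stage = f"select[{analyte}]"
            ssa_cfg = select_mod.SSAConfig(
                population=config.population,
                iterations=config.iterations,
                inner_components=config.inner_components,
                seed=config.seed + _SEED_SSA + 1000 * k,
            )
            runs, freq = select_mod.repeat_runs(X_train, y_train, ssa_cfg, config.n_runs)
            pd.DataFrame(
                {"wavelength_nm": lam, "selection_probability": freq.probabilities}
            ).to_csv(out / f"frequency_{analyte}.csv", index=False)
            candidates = select_mod.build_candidate_sets(freq)
            best_set = select_mod.adjudicate(
                candidates,
                X_train,
                y_train,
                n_components=config.inner_components,
                seed=ssa_cfg.seed,
            )
            chosen = list(best_set.indices)
            with open(out / f"best_set_{analyte}.json", "w") as fh:
                json.dump(
                    {
                        "analyte": analyte,
                        "strategy": best_set.strategy,
                        "wavelengths_nm": [round(float(lam[i]), 3) for i in chosen],
                        "n_selected": len(chosen),
                        "fraction_of_bands_pct": 100.0 * len(chosen) / len(lam),
                        "cv_mse": best_set.cv_mse,
                        "cv_rmse": best_set.cv_rmse,
                    },
                    fh,
                    indent=2,
                )
            _log(log, stage, t0, f"{len(chosen)}/{len(lam)} bands ({best_set.strategy})")

            stage = f"model[{analyte}]"
            Xtr, Xte = X_train[:, chosen], X_test[:, chosen]
            trained, reports = {}, []
            for family in config.families:
                spec = model_mod.ModelSpec(family=family, seed=config.seed + _SEED_MODEL)
                m = model_mod.fit(spec, Xtr, y_train)
                trained[family] = m
                reports.append(model_mod.evaluate_model(m, Xtr, y_train, Xte, y_test))
            ranked = model_mod.compare(reports)
            _log(log, stage, t0, f"best {ranked[0].family} R2_P={ranked[0].r2_p:.3f}")

            stage = f"explain[{analyte}]"
            best_family = ranked[0].family
            best_model = trained[best_family]
            names = [f"{lam[i]:.3f}" for i in chosen]
            if best_family == "PLS":
                shap = explain_mod.shap_linear(best_model, Xte, Xtr, feature_names=names)
            else:
                shap = explain_mod.shap_tree(
                    best_model,
                    Xte,
                    Xtr,
                    n_permutations=config.n_permutations,
                    seed=config.seed + _SEED_SHAP + k,
                    feature_names=names,
                )
            contrib = explain_mod.summarize(shap)
            pd.DataFrame(
                shap.values, index=list(split.prediction), columns=names
            ).to_csv(out / f"shap_{analyte}.csv", index_label="sample_id")
            with open(out / f"contrib_{analyte}.json", "w") as fh:
                json.dump(contrib.as_dict(), fh, indent=2)
            _log(log, stage, t0, f"k80={contrib.k80} k95={contrib.k95}")

            bundle["analytes"][analyte] = {
                "split": {"n_train": len(split.training), "n_test": len(split.prediction)},
                "selected_wavelengths_nm": [round(float(lam[i]), 3) for i in chosen],
                "n_selected": len(chosen),
                "fraction_of_bands_pct": 100.0 * len(chosen) / len(lam),
                "strategy": best_set.strategy,
                "metrics": [r.as_dict() for r in ranked],
                "best_family": best_family,
                "shap_base_value": shap.base_value,
                "k80": contrib.k80,
                "k95": contrib.k95,
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    rows = []
    for analyte, res in bundle["analytes"].items():
        for r in res["metrics"]:
            rows.append({"Type": analyte, **r})
    pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False)

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "stage_seeds": {
            "simulate": config.seed + _SEED_SIM,
            "split": {
                a: config.seed + _SEED_SPLIT + k for k, a in enumerate(config.analytes)
            },
            "ssa": {
                a: config.seed + _SEED_SSA + 1000 * k
                for k, a in enumerate(config.analytes)
            },
            "model": config.seed + _SEED_MODEL,
            "shap": {
                a: config.seed + _SEED_SHAP + k for k, a in enumerate(config.analytes)
            },
        },
        "artifacts": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    bundle["manifest"] = manifest
    bundle["log"] = log
    return bundle
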