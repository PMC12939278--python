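"""Shapley-value interpretation of the calibration models.

Two estimators cover the model families used here:

* exact linear Shapley for the PLS models — for an affine model the
  Shapley value of feature j on sample i is simply
  ``beta_j * (x_ij - mean_j(background))`` and additivity is exact;
* interventional permutation-sampling Shapley for black-box models
  (random forest, SVR) — feature orderings are sampled, background rows
  supply the "absent" feature values, and marginal prediction changes
  are averaged. Background rows are cycled deterministically so the
  estimator is seeded and its base value converges to the background
  mean prediction.

On top of per-sample attributions the module computes the global summary
used to read the models: mean signed Shapley value per wavelength (the
direction of its average effect), contribution rates from mean absolute
values (normalised to 100 %), the ranked cumulative-contribution curve
with the minimal wavelength counts reaching 80 % and 95 %, and
per-wavelength dependence profiles with a monotonicity flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ShapMatrix",
    "ContributionReport",
    "shap_linear",
    "shap_tree",
    "summarize",
    "dependence_profile",
]


@dataclass(frozen=True)
class ShapMatrix:
    """Per-sample, per-feature attributions plus the base value.

    ``base_value + values[i].sum()`` reproduces the model's prediction
    for sample i — exactly for the linear estimator, within sampling
    tolerance for the permutation estimator.
    """

    values: np.ndarray
    base_value: float
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        if v.ndim != 2 or v.shape[1] != len(self.feature_names):
            raise ValueError("values must be n_samples x n_features, aligned with names")


@dataclass(frozen=True)
class ContributionReport:
    """Global wavelength importance derived from a ShapMatrix."""

    feature_names: tuple[str, ...]
    mean_signed: np.ndarray
    mean_abs: np.ndarray
    contribution_rate: np.ndarray  # percent, sums to 100
    ranked_order: tuple[int, ...]  # feature indices, descending mean_abs
    cumulative_rate: np.ndarray  # percent along ranked_order
    k80: int
    k95: int

    def as_dict(self) -> dict:
        return {
            "features": list(self.feature_names),
            "mean_signed": self.mean_signed.tolist(),
            "mean_abs": self.mean_abs.tolist(),
            "contribution_rate_pct": self.contribution_rate.tolist(),
            "ranked_features": [self.feature_names[i] for i in self.ranked_order],
            "cumulative_rate_pct": self.cumulative_rate.tolist(),
            "k80": self.k80,
            "k95": self.k95,
        }


def _predict(model, X: np.ndarray) -> np.ndarray:
    return np.asarray(model.predict(np.asarray(X, dtype=float))).ravel()


def shap_linear(model, X, background, feature_names=None) -> ShapMatrix:
    """Exact Shapley values for a model affine in its features.

    Coefficients are probed as unit-perturbation prediction differences
    at the background mean, which is exact for any affine predictor and
    independent of how the model stores its parameters internally.
    """
    X = np.asarray(X, dtype=float)
    background = np.asarray(background, dtype=float)
    if background.size == 0:
        raise ValueError("background set is empty")
    mu = background.mean(axis=0)
    d = X.shape[1]
    probes = np.vstack([mu, mu + np.eye(d)])
    preds = _predict(model, probes)
    base = float(preds[0])
    beta = preds[1:] - base
    values = (X - mu) * beta
    names = _names(feature_names, d)
    return ShapMatrix(values=values, base_value=base, feature_names=names)


def shap_tree(
    model, X, background, n_permutations: int = 200, seed: int = 0, feature_names=None
) -> ShapMatrix:
    """Interventional permutation-sampling Shapley values.

    For each sample, feature orderings are sampled; within an ordering
    features switch one by one from a background row's values to the
    sample's values and the prediction changes are credited to the
    switched feature. Background rows are taken in a seeded shuffled
    cycle, so with a permutation budget that is a multiple of the
    background size the base value equals the exact background mean
    prediction. Works for any regressor; named for its primary use on
    the tree-ensemble models.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    X = np.asarray(X, dtype=float)
    background = np.asarray(background, dtype=float)
    if background.size == 0:
        raise ValueError("background set is empty")
    n, d = X.shape
    n_bg = background.shape[0]
    rng = np.random.default_rng(seed)
    bg_order = rng.permutation(n_bg)

    values = np.zeros((n, d))
    for i in range(n):
        x = X[i]
        # each sampled ordering is evaluated forward and reversed on the
        # same background row (antithetic pair: cancels most of the
        # position-dependent variance); one predict call per sample
        Z = np.empty((n_permutations, 2, d + 1, d))
        perms = np.empty((n_permutations, 2, d), dtype=int)
        for p in range(n_permutations):
            b = background[bg_order[p % n_bg]]
            perm = rng.permutation(d)
            for s, ordering in enumerate((perm, perm[::-1])):
                perms[p, s] = ordering
                z = b.copy()
                Z[p, s, 0] = z
                for k, j in enumerate(ordering):
                    z = z.copy()
                    z[j] = x[j]
                    Z[p, s, k + 1] = z
        preds = _predict(model, Z.reshape(-1, d)).reshape(n_permutations, 2, d + 1)
        contrib = np.diff(preds, axis=2)  # (n_permutations, 2, d)
        phi = np.zeros(d)
        for p in range(n_permutations):
            phi[perms[p, 0]] += contrib[p, 0]
            phi[perms[p, 1]] += contrib[p, 1]
        values[i] = phi / (2 * n_permutations)

    base = float(_predict(model, background).mean())
    names = _names(feature_names, d)
    return ShapMatrix(values=values, base_value=base, feature_names=names)


def _names(feature_names, d: int) -> tuple[str, ...]:
    if feature_names is None:
        return tuple(f"f{j}" for j in range(d))
    if len(feature_names) != d:
        raise ValueError("feature_names length must match the feature count")
    return tuple(str(f) for f in feature_names)


def summarize(shap: ShapMatrix) -> ContributionReport:
    """Global contribution summary: signed means, rates and coverage counts.

    contribution_rate_j = 100 * mean|phi_j| / sum_k mean|phi_k|; k80 and
    k95 are the minimal numbers of top-ranked wavelengths whose
    cumulative rate reaches 80 % and 95 %.
    """
    v = shap.values
    if v.size == 0:
        raise ValueError("empty attribution matrix")
    mean_signed = v.mean(axis=0)
    mean_abs = np.abs(v).mean(axis=0)
    total = mean_abs.sum()
    if total == 0:
        raise ValueError("all attributions are zero; contribution rates undefined")
    rate = 100.0 * mean_abs / total
    order = tuple(int(i) for i in np.argsort(-mean_abs, kind="stable"))
    cumulative = np.cumsum(rate[list(order)])
    k80 = int(np.searchsorted(cumulative, 80.0 - 1e-9) + 1)
    k95 = int(np.searchsorted(cumulative, 95.0 - 1e-9) + 1)
    return ContributionReport(
        feature_names=shap.feature_names,
        mean_signed=mean_signed,
        mean_abs=mean_abs,
        contribution_rate=rate,
        ranked_order=order,
        cumulative_rate=cumulative,
        k80=k80,
        k95=k95,
    )


def dependence_profile(shap: ShapMatrix, X, feature) -> dict:
    """(feature value, Shapley value) pairs for one wavelength.

    Returns the paired series sorted by feature value plus a Spearman
    monotonicity diagnostic: |rho| >= 0.95 flags the profile monotone.
    """
    X = np.asarray(X, dtype=float)
    try:
        j = shap.feature_names.index(str(feature))
    except ValueError:
        raise KeyError(f"unknown feature {feature!r}") from None
    x = X[:, j]
    phi = shap.values[:, j]
    order = np.argsort(x, kind="stable")
    if np.allclose(phi, 0.0) or np.std(x) == 0:
        rho = 0.0
    else:
        rho = float(stats.spearmanr(x, phi).statistic)
        if np.isnan(rho):
            rho = 0.0
    return {
        "feature": shap.feature_names[j],
        "x": x[order],
        "shap": phi[order],
        "spearman_rho": rho,
        "monotone": abs(rho) >= 0.95,
    }
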