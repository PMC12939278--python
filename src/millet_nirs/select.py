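"""Binary sparrow-search wavelength selection with stability screening.

The core computation of the pipeline. A population of binary
wavelength-inclusion vectors is evolved by the sparrow search algorithm
(SSA): the fittest "discoverers" exploit their subsets through low-rate
bitwise mutation, "followers" imitate a random discoverer with a high
flip rate, and the worst-ranked "sentinels" escape local optima by
re-initialising. Fitness of a subset is the 5-fold cross-validated mean
squared error of a PLS model restricted to that subset — lower is better.

Because a single metaheuristic run is stochastic, the algorithm is run
many times independently (50 in the full protocol) and each wavelength's
selection frequency across the runs' best subsets is recorded. Candidate
wavelength sets are then built from the frequency table by three
strategies (frequency > 50 %, top-N for N = 10..50 step 5, and frequency
levels 0.5..0.9 with a 5-member minimum) and adjudicated by 5-fold CV PLS
error; the minimiser is the final key-wavelength set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._fastpls import cv_mse, kfold_indices

__all__ = [
    "SSAConfig",
    "RunResult",
    "FrequencyTable",
    "CandidateSet",
    "FitnessEvaluator",
    "fitness",
    "ssa_run",
    "repeat_runs",
    "frequency_from_runs",
    "build_candidate_sets",
    "adjudicate",
]

TOP_N_RANGE = range(10, 51, 5)
PROBABILITY_LEVELS = (0.5, 0.6, 0.7, 0.8, 0.9)
MIN_LEVEL_SET_SIZE = 5


@dataclass(frozen=True)
class SSAConfig:
    """Sparrow-search hyperparameters.

    The full-scale protocol uses a population of 100 and 500 iterations;
    discoverers are the top 70 % of the population by fitness, sentinels
    the worst 20 %, followers the remainder. The safety threshold 0.8 is
    the probability that a sentinel fully re-initialises (otherwise it
    restarts from the global best with discoverer-rate mutation).
    Mutation rates: discoverers flip each bit with probability 0.1,
    followers with 0.3.
    """

    population: int = 100
    iterations: int = 500
    discoverer_fraction: float = 0.7
    vigilance_fraction: float = 0.2
    safety_threshold: float = 0.8
    discoverer_mutation: float = 0.1
    follower_flip: float = 0.3
    inner_components: int = 5
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2 or self.iterations < 1:
            raise ValueError("population must be >= 2 and iterations >= 1")
        for name in ("discoverer_fraction", "vigilance_fraction", "safety_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.discoverer_fraction + self.vigilance_fraction > 1.0:
            raise ValueError("discoverer + vigilance fractions must be <= 1")
        for name in ("discoverer_mutation", "follower_flip"):
            if not 0.0 < getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass(frozen=True)
class RunResult:
    """Best subset of one independent SSA run."""

    best_subset: np.ndarray  # binary vector of length D
    best_fitness: float  # CV mean MSE, analyte units squared
    history: tuple[float, ...] = ()  # global-best fitness per generation

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.best_subset)


@dataclass(frozen=True)
class FrequencyTable:
    """Per-band selection probability across R independent runs."""

    probabilities: np.ndarray
    n_runs: int

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("selection probabilities must lie in [0, 1]")


@dataclass
class CandidateSet:
    """A candidate wavelength set produced by one screening strategy."""

    strategy: str
    indices: tuple[int, ...]
    cv_mse: float | None = None
    cv_rmse: float | None = None

    def __post_init__(self) -> None:
        if len(self.indices) == 0:
            raise ValueError("candidate set must be non-empty")
        self.indices = tuple(int(i) for i in self.indices)


@dataclass
class FitnessEvaluator:
    """Cross-validated PLS subset fitness with memoisation.

    The subset MSE (the SSA's objective) is the mean over seeded 5-fold
    CV of the fold mean squared error of a PLS model with
    min(inner_components, |s|, fold train size - 1) latent variables.
    The SSA revisits subsets constantly, so results are cached on the
    subset bit pattern.
    """

    X: np.ndarray
    y: np.ndarray
    n_components: int = 5
    cv_folds: int = 5
    seed: int = 0
    _folds: list = field(init=False, repr=False)
    _cache: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.ascontiguousarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.shape[0] != self.y.size:
            raise ValueError("X and y are not aligned")
        self._folds = kfold_indices(self.y.size, self.cv_folds, self.seed)

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]

    def __call__(self, subset: np.ndarray) -> float:
        return self.mse_rmse(subset)[0]

    def mse_rmse(self, subset: np.ndarray) -> tuple[float, float]:
        subset = np.asarray(subset, dtype=bool)
        if not subset.any():
            raise ValueError("subset must select at least one band")
        key = subset.tobytes()
        hit = self._cache.get(key)
        if hit is None:
            Xs = self.X[:, subset]
            ncomp = min(self.n_components, int(subset.sum()))
            hit = cv_mse(Xs, self.y, ncomp, self._folds)
            self._cache[key] = hit
        return hit


def fitness(subset, X, y, n_components: int = 5, cv_folds: int = 5, seed: int = 0) -> float:
    """Convenience one-shot subset fitness (CV mean MSE); see FitnessEvaluator."""
    return FitnessEvaluator(X, y, n_components, cv_folds, seed)(np.asarray(subset))


def _repair(subset: np.ndarray, rng) -> np.ndarray:
    """Ensure at least one selected band (uniform random bit if empty)."""
    if not subset.any():
        subset = subset.copy()
        subset[rng.integers(subset.size)] = True
    return subset


def ssa_run(X, y, config: SSAConfig, evaluator: FitnessEvaluator | None = None) -> RunResult:
    """One independent binary sparrow-search run.

    Greedy acceptance everywhere: a mutated or imitated subset replaces
    its owner only on strict fitness improvement; sentinel
    re-initialisation is unconditional (its purpose is escape, not
    descent). The global best is tracked across generations and returned.
    """
    if evaluator is None:
        evaluator = FitnessEvaluator(
            X, y, config.inner_components, config.cv_folds, config.seed
        )
    rng = np.random.default_rng(config.seed)
    D = evaluator.n_bands
    pop_n = config.population

    pop = rng.random((pop_n, D)) < 0.5
    for i in range(pop_n):
        pop[i] = _repair(pop[i], rng)
    fit = np.array([evaluator(ind) for ind in pop])

    best_idx = int(np.argmin(fit))
    g_best = pop[best_idx].copy()
    g_fit = float(fit[best_idx])
    history = [g_fit]

    n_disc = max(1, int(round(config.discoverer_fraction * pop_n)))
    n_vig = max(1, int(round(config.vigilance_fraction * pop_n)))
    n_vig = min(n_vig, pop_n - n_disc) if pop_n - n_disc > 0 else 0

    for _ in range(config.iterations):
        order = np.argsort(fit, kind="stable")
        disc = order[:n_disc]
        vig = order[pop_n - n_vig:] if n_vig else np.empty(0, dtype=int)

        # discoverers: exploit via low-rate bitwise mutation
        for i in disc:
            trial = pop[i] ^ (rng.random(D) < config.discoverer_mutation)
            trial = _repair(trial, rng)
            f = evaluator(trial)
            if f < fit[i]:
                pop[i], fit[i] = trial, f

        # followers: imitate a random discoverer with high flip rate
        followers = order[n_disc: pop_n - n_vig]
        for i in followers:
            src = pop[disc[rng.integers(n_disc)]]
            trial = src ^ (rng.random(D) < config.follower_flip)
            trial = _repair(trial, rng)
            f = evaluator(trial)
            if f < fit[i]:
                pop[i], fit[i] = trial, f

        # sentinels: escape — full re-initialisation with probability equal
        # to the safety threshold, else restart from the global best
        for i in vig:
            if rng.random() < config.safety_threshold:
                trial = _repair(rng.random(D) < 0.5, rng)
            else:
                trial = g_best ^ (rng.random(D) < config.discoverer_mutation)
                trial = _repair(trial, rng)
            pop[i] = trial
            fit[i] = evaluator(trial)

        gen_best = int(np.argmin(fit))
        if fit[gen_best] < g_fit:
            g_fit = float(fit[gen_best])
            g_best = pop[gen_best].copy()
        history.append(g_fit)

    return RunResult(best_subset=g_best, best_fitness=g_fit, history=tuple(history))


def frequency_from_runs(results: list[RunResult], n_bands: int) -> FrequencyTable:
    """Per-band selection frequency over the runs' best subsets."""
    counts = np.zeros(n_bands)
    for res in results:
        counts += np.asarray(res.best_subset, dtype=float)
    return FrequencyTable(probabilities=counts / len(results), n_runs=len(results))


def repeat_runs(
    X, y, config: SSAConfig, n_runs: int = 50
) -> tuple[list[RunResult], FrequencyTable]:
    """n_runs independent SSA runs (seeds seed+0 .. seed+n_runs-1) and the
    per-band selection frequency over their best subsets."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    evaluator = FitnessEvaluator(
        X, y, config.inner_components, config.cv_folds, config.seed
    )
    results = []
    for r in range(n_runs):
        run_cfg = replace(config, seed=config.seed + r)
        results.append(ssa_run(X, y, run_cfg, evaluator=evaluator))
    return results, frequency_from_runs(results, evaluator.n_bands)


def build_candidate_sets(freq: FrequencyTable) -> list[CandidateSet]:
    """The three screening strategies over the selection-frequency table.

    1. all bands with frequency > 50 %;
    2. the top-N bands by frequency for N = 10, 15, ..., 50 (ties broken
       toward the lower band index);
    3. bands with frequency >= level for level in {0.5, ..., 0.9},
       discarding any level set with fewer than 5 members.
    """
    p = freq.probabilities
    D = p.size
    sets: list[CandidateSet] = []

    over_half = tuple(np.flatnonzero(p > 0.5))
    if over_half:
        sets.append(CandidateSet(strategy="threshold>0.5", indices=over_half))

    # stable sort on -p breaks frequency ties toward the lower index
    ranked = np.argsort(-p, kind="stable")
    for n in TOP_N_RANGE:
        top = tuple(sorted(int(i) for i in ranked[: min(n, D)]))
        sets.append(CandidateSet(strategy=f"top-{n}", indices=top))

    for level in PROBABILITY_LEVELS:
        members = tuple(np.flatnonzero(p >= level))
        if len(members) >= MIN_LEVEL_SET_SIZE:
            sets.append(CandidateSet(strategy=f"level>={level}", indices=members))

    if not sets:
        raise ValueError("degenerate frequency table produced no candidate sets")
    return sets


def adjudicate(
    candidates: list[CandidateSet],
    X,
    y,
    n_components: int = 5,
    cv_folds: int = 5,
    seed: int = 0,
) -> CandidateSet:
    """Score every candidate set by 5-fold CV PLS error and return the
    minimiser (ties: fewer bands, then lower first band index)."""
    if not candidates:
        raise ValueError("no candidate sets to adjudicate")
    evaluator = FitnessEvaluator(X, y, n_components, cv_folds, seed)
    D = evaluator.n_bands
    for cand in candidates:
        subset = np.zeros(D, dtype=bool)
        subset[list(cand.indices)] = True
        cand.cv_mse, cand.cv_rmse = evaluator.mse_rmse(subset)
    return min(
        candidates,
        key=lambda c: (c.cv_mse, len(c.indices), c.indices[0]),
    )
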