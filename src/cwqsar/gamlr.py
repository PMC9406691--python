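"""Genetic-algorithm descriptor selection with multiple linear regression.

The alternative QSAR route: a precomputed table of named numeric molecular
descriptors is filtered (near-constant columns and highly intercorrelated
pairs removed), then a genetic algorithm searches fixed-size descriptor
subsets, scoring each by the leave-one-out cross-validated q² of its OLS
fit.  The applicability domain of the resulting model is the Williams-plot
region: leverage below the warning value h* = 3(k+1)/n and |standardized
residual| below 3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

_COND_LIMIT = 1e10


@dataclass
class FilteredMatrix:
    """Descriptor matrix after variance/intercorrelation filtering.

    ``values`` holds the surviving raw columns; ``means``/``stds`` are the
    stored autoscaling parameters (the scaled matrix is ``scaled``).
    """

    ids: list
    names: list[str]
    values: pd.DataFrame
    means: pd.Series
    stds: pd.Series
    dropped_constant: list[str] = field(default_factory=list)
    dropped_correlated: list[str] = field(default_factory=list)

    @property
    def scaled(self) -> pd.DataFrame:
        return (self.values - self.means) / self.stds


@dataclass
class MLRModel:
    """Fixed-size OLS model over named descriptors, GA-selected."""

    descriptors: list[str]
    coefficients: dict[str, float]
    intercept: float
    r2: float
    q2_loo: float
    ga_settings: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps({
            "descriptors": self.descriptors,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "r2": self.r2, "q2_loo": self.q2_loo,
            "ga_settings": self.ga_settings, "seed": self.seed,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MLRModel":
        d = json.loads(text)
        return cls(
            descriptors=d["descriptors"],
            coefficients=d["coefficients"],
            intercept=d["intercept"],
            r2=d["r2"], q2_loo=d["q2_loo"],
            ga_settings=d.get("ga_settings", {}), seed=d.get("seed", 0),
        )


def filter_descriptors(
    matrix: pd.DataFrame,
    response,
    constant_fraction_cut: float = 0.80,
    intercorrelation_cut: float = 0.95,
) -> FilteredMatrix:
    """Drop near-constant and redundant columns, keep scaling parameters.

    A column goes when its modal value covers at least
    ``constant_fraction_cut`` of the rows.  Of each pair with
    |Pearson r| ≥ ``intercorrelation_cut`` the member with the weaker
    absolute correlation to the response is dropped.
    """
    if matrix.empty:
        raise ValueError("empty descriptor matrix")
    y = np.asarray(response, dtype=float)

    dropped_constant = []
    for name in matrix.columns:
        col = matrix[name]
        if col.value_counts(dropna=False).iloc[0] / len(col) >= constant_fraction_cut:
            dropped_constant.append(name)
    kept = [c for c in matrix.columns if c not in dropped_constant]

    resp_corr = {}
    for name in kept:
        col = matrix[name].to_numpy(dtype=float)
        resp_corr[name] = (
            abs(float(np.corrcoef(col, y)[0, 1])) if col.std() > 0 else 0.0
        )

    dropped_correlated: list[str] = []
    alive = list(kept)
    corr = matrix[kept].corr().abs()
    for i, a in enumerate(kept):
        if a in dropped_correlated:
            continue
        for b in kept[i + 1:]:
            if b in dropped_correlated:
                continue
            if corr.loc[a, b] >= intercorrelation_cut:
                weaker = b if resp_corr[a] >= resp_corr[b] else a
                dropped_correlated.append(weaker)
                if weaker == a:
                    break
    alive = [c for c in kept if c not in dropped_correlated]
    if not alive:
        raise ValueError("all descriptor columns removed by filtering")

    values = matrix[alive].astype(float)
    return FilteredMatrix(
        ids=list(matrix.index), names=alive, values=values,
        means=values.mean(), stds=values.std(ddof=0).replace(0.0, 1.0),
        dropped_constant=dropped_constant,
        dropped_correlated=dropped_correlated,
    )


def _ols_press_q2(X: np.ndarray, y: np.ndarray) -> float:
    """LOO q² of the OLS fit via the PRESS/hat-matrix identity."""
    n = X.shape[0]
    Z = np.column_stack([np.ones(n), X])
    if np.linalg.cond(Z) > _COND_LIMIT:
        return -np.inf
    ZtZ_inv = np.linalg.inv(Z.T @ Z)
    beta = ZtZ_inv @ (Z.T @ y)
    resid = y - Z @ beta
    h = np.einsum("ij,jk,ik->i", Z, ZtZ_inv, Z)
    if np.any(h >= 1.0 - 1e-12):
        return -np.inf
    press = float(np.sum((resid / (1.0 - h)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / ss_tot


def _ols_fit(X: np.ndarray, y: np.ndarray):
    Z = np.column_stack([np.ones(X.shape[0]), X])
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    pred = Z @ beta
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return beta, 1.0 - ss_res / ss_tot


def subset_fitness(matrix: np.ndarray, y: np.ndarray, subset) -> float:
    """Fitness of one descriptor subset: LOO q² of its OLS fit."""
    return _ols_press_q2(matrix[:, list(subset)], y)


def exhaustive_select(matrix: np.ndarray, y: np.ndarray, model_size: int):
    """Brute-force best subset (oracle for small pools)."""
    from itertools import combinations

    best, best_fit = None, -np.inf
    for subset in combinations(range(matrix.shape[1]), model_size):
        f = subset_fitness(matrix, y, subset)
        if f > best_fit:
            best, best_fit = subset, f
    return tuple(best), best_fit


def ga_select(
    matrix: np.ndarray,
    y: np.ndarray,
    model_size: int = 5,
    population: int = 10,
    generations: int = 500,
    mutation_rate: float = 0.20,
    seed: int = 0,
    elitism: int = 1,
    tournament: int = 2,
) -> tuple[tuple[int, ...], float, list[float]]:
    """GA search over fixed-size descriptor subsets.

    Chromosomes are descriptor index sets of size ``model_size``; selection
    is by tournament, crossover is uniform (repaired back to size), and each
    gene mutates with probability ``mutation_rate``.  Returns the best-ever
    subset, its fitness and the per-generation best-fitness trace.
    """
    n, p = matrix.shape
    if model_size >= n - 2:
        raise ValueError("model_size must be < number of molecules - 2")
    if model_size > p:
        raise ValueError("model_size exceeds descriptor count")
    rng = np.random.default_rng(seed)

    def random_chrom():
        return tuple(sorted(rng.choice(p, size=model_size, replace=False)))

    def mutate(chrom):
        genes = list(chrom)
        for i in range(model_size):
            if rng.random() < mutation_rate:
                choices = [g for g in range(p) if g not in genes]
                if choices:
                    genes[i] = choices[rng.integers(len(choices))]
        return tuple(sorted(genes))

    def crossover(a, b):
        pool = sorted(set(a) | set(b))
        keep = [g for g in pool if (g in a and g in b) or rng.random() < 0.5]
        # repair to exact size
        while len(keep) > model_size:
            keep.pop(rng.integers(len(keep)))
        spare = [g for g in pool if g not in keep]
        while len(keep) < model_size:
            if spare:
                keep.append(spare.pop(rng.integers(len(spare))))
            else:
                g = int(rng.integers(p))
                if g not in keep:
                    keep.append(g)
        return tuple(sorted(keep))

    pop = [random_chrom() for _ in range(population)]
    fits = [subset_fitness(matrix, y, c) for c in pop]
    # degenerate (collinear) chromosomes are resampled once at start
    for i, f in enumerate(fits):
        tries = 0
        while f == -np.inf and tries < 20:
            pop[i] = random_chrom()
            f = subset_fitness(matrix, y, pop[i])
            tries += 1
        fits[i] = f

    best_idx = int(np.argmax(fits))
    best, best_fit = pop[best_idx], fits[best_idx]
    trace = [best_fit]

    def tournament_pick():
        idx = rng.integers(population, size=tournament)
        return pop[max(idx, key=lambda i: fits[i])]

    for _ in range(generations):
        new_pop = [best]  # elitism
        while len(new_pop) < population:
            child = mutate(crossover(tournament_pick(), tournament_pick()))
            new_pop.append(child)
        pop = new_pop
        fits = [subset_fitness(matrix, y, c) for c in pop]
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best, best_fit = pop[gen_best], fits[gen_best]
        trace.append(best_fit)
    return best, best_fit, trace


def predict_mlr(model: MLRModel, row: dict | pd.Series) -> float:
    """intercept + Σ coefficient × descriptor value."""
    total = model.intercept
    for name, coef in model.coefficients.items():
        if name not in row:
            raise KeyError(f"missing descriptor {name!r}")
        total += coef * float(row[name])
    return total


def williams_ad(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_query: np.ndarray | None = None,
    y_query: np.ndarray | None = None,
    residual_limit: float = 3.0,
) -> list[dict]:
    """Williams-plot applicability domain.

    Leverage h comes from the hat matrix of the training design (intercept
    included); the warning leverage is h* = 3(k+1)/n.  Standardized residuals
    are residuals divided by the training residual standard error; membership
    requires h < h* and |standardized residual| < ``residual_limit`` (both
    strict).
    """
    n, k = X_train.shape
    Z = np.column_stack([np.ones(n), X_train])
    ZtZ_inv = np.linalg.inv(Z.T @ Z)
    beta = ZtZ_inv @ (Z.T @ y_train)
    resid = y_train - Z @ beta
    s = float(np.sqrt(np.sum(resid**2) / max(n - k - 1, 1)))
    h_star = 3.0 * (k + 1) / n

    def rows_for(Xq, yq, tag):
        out = []
        Zq = np.column_stack([np.ones(Xq.shape[0]), Xq])
        hq = np.einsum("ij,jk,ik->i", Zq, ZtZ_inv, Zq)
        rq = (yq - Zq @ beta) / s if yq is not None else np.full(len(hq), np.nan)
        for h, r in zip(hq, rq):
            ok = h < h_star and (np.isnan(r) or abs(r) < residual_limit)
            out.append({
                "set": tag, "leverage": float(h),
                "std_residual": float(r), "h_star": h_star,
                "in_domain": bool(ok),
            })
        return out

    rows = rows_for(X_train, y_train, "training")
    if X_query is not None:
        rows += rows_for(X_query, y_query, "query")
    return rows


class GAMLRRegressor(RegressorMixin, BaseEstimator):
    """Descriptor-table regressor: GA subset selection + OLS.

    Parameters mirror the conventional GA-MLR configuration: ``model_size``
    descriptors per model, population ``population`` evolved for
    ``generations`` generations at per-gene ``mutation_rate``.
    """

    def __init__(self, model_size: int = 5, population: int = 10,
                 generations: int = 500, mutation_rate: float = 0.20,
                 constant_fraction_cut: float = 0.80,
                 intercorrelation_cut: float = 0.95,
                 random_state: int = 0):
        self.model_size = model_size
        self.population = population
        self.generations = generations
        self.mutation_rate = mutation_rate
        self.constant_fraction_cut = constant_fraction_cut
        self.intercorrelation_cut = intercorrelation_cut
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=float)
        self.filtered_ = filter_descriptors(
            X, y, self.constant_fraction_cut, self.intercorrelation_cut
        )
        scaled = self.filtered_.scaled.to_numpy()
        subset, fitness, trace = ga_select(
            scaled, y, model_size=self.model_size,
            population=self.population, generations=self.generations,
            mutation_rate=self.mutation_rate, seed=self.random_state,
        )
        names = [self.filtered_.names[j] for j in subset]
        # final coefficients refit on the raw (unscaled) descriptor columns
        raw = self.filtered_.values[names].to_numpy()
        beta, r2 = _ols_fit(raw, y)
        self.selected_ = names
        self.intercept_ = float(beta[0])
        self.coef_ = dict(zip(names, map(float, beta[1:])))
        self.q2_loo_ = float(fitness)
        self.trace_ = trace
        self.model_ = MLRModel(
            descriptors=names, coefficients=self.coef_,
            intercept=self.intercept_, r2=float(r2),
            q2_loo=self.q2_loo_,
            ga_settings={
                "model_size": self.model_size,
                "population": self.population,
                "generations": self.generations,
                "mutation_rate": self.mutation_rate,
            },
            seed=self.random_state,
        )
        return self

    def predict(self, X: pd.DataFrame):
        if not hasattr(self, "model_"):
            raise ValueError("estimator is not fitted")
        return np.array([
            predict_mlr(self.model_, row) for _, row in X.iterrows()
        ])
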