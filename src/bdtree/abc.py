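"""Likelihood-free inference: rejection ABC, ABC-RF and ABC-DRF posteriors.

The reference table pairs parameter draws from the prior with summary vectors
simulated from the model.  Three posterior constructions over its rows:

* **rejection** — uniform weights on the rows whose standardized summaries are
  closest to the observation;
* **ABC-RF** — a regression forest per scalar parameter; the posterior weight
  of a row is its average in-bag leaf co-membership with the observation,
  giving a weighted marginal posterior;
* **ABC-DRF** — one forest with the multivariate response (p, theta); the same
  leaf-weighting scheme then equips the *joint* empirical law of the
  parameter vectors.

The forest is an ensemble of CART regression trees on bootstrap resamples with
feature subsampling.  For the multivariate response the split criterion is
summed variance reduction over standardized response components; the
leaf-weighting scheme that defines the posterior is the essential part.
Standardization constants come from the reference table only, never from the
observation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.tree import DecisionTreeRegressor

from .cell_model import SUMMARY_COLUMNS, CellSimConfig, summarize

__all__ = [
    "PriorSpec",
    "ReferenceTable",
    "Posterior",
    "ForestEnsemble",
    "build_reference_table",
    "abc_rejection",
    "fit_forest",
    "posterior_weights",
    "variable_importance",
    "posterior_report",
    "qq_table",
]

PARAM_COLUMNS = ["p", "theta"]


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors, one (low, high) pair per parameter."""

    bounds: dict

    def __post_init__(self) -> None:
        for name, (low, high) in self.bounds.items():
            if not low < high:
                raise ValueError(f"prior for {name}: need low < high, got ({low}, {high})")

    @property
    def names(self) -> list[str]:
        return list(self.bounds)

    def sample(self, rng: np.random.Generator) -> dict:
        return {k: rng.uniform(lo, hi) for k, (lo, hi) in self.bounds.items()}


@dataclass
class ReferenceTable:
    """Paired parameter draws and summary vectors from prior-predictive simulation."""

    data: pd.DataFrame
    param_names: list[str] = field(default_factory=lambda: list(PARAM_COLUMNS))
    stat_names: list[str] = field(default_factory=lambda: list(SUMMARY_COLUMNS))

    def __len__(self) -> int:
        return len(self.data)

    @property
    def params(self) -> np.ndarray:
        return self.data[self.param_names].to_numpy()

    @property
    def stats(self) -> np.ndarray:
        return self.data[self.stat_names].to_numpy()


@dataclass
class Posterior:
    """Weighted empirical distribution over reference-table parameter rows."""

    params: pd.DataFrame  # columns = parameter names
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        total = w.sum()
        if not total > 0:
            raise ValueError("weights must not all vanish")
        self.weights = w / total

    def mean(self) -> pd.Series:
        return pd.Series(self.weights @ self.params.to_numpy(), index=self.params.columns)

    def quantile(self, q, name: str):
        """Weighted quantile(s) of one parameter (inverse of the weighted ECDF)."""
        support = self.weights > 0
        x = self.params[name].to_numpy()[support]
        order = np.argsort(x)
        x, w = x[order], self.weights[support][order]
        cdf = np.cumsum(w)
        q_arr = np.atleast_1d(np.asarray(q, dtype=float))
        idx = np.searchsorted(cdf, np.clip(q_arr, 0.0, cdf[-1]), side="left")
        out = x[np.minimum(idx, len(x) - 1)]
        return out if np.ndim(q) else float(out[0])

    def credible_interval(self, name: str, level: float = 0.9) -> tuple[float, float]:
        a = (1.0 - level) / 2.0
        lo, hi = self.quantile([a, 1.0 - a], name)
        return float(lo), float(hi)


def build_reference_table(
    priors: PriorSpec, R: int, sim_template: CellSimConfig, seed=None
) -> ReferenceTable:
    """Simulate R (parameter, summary) rows from the prior predictive.

    Growth attempts that die out before reaching N cells are discarded
    *together with their parameter draw*, and a fresh (p, theta) is drawn for
    the next attempt.  The table's realized p-marginal is therefore the
    survival-conditioned prior — stochastically above the nominal uniform —
    while the theta-marginal stays uniform (survival does not depend on
    theta).  Row k uses its own RNG substream, reproducible in isolation.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    from .cell_model import drop_mutations, sample_tree, try_grow_population

    streams = np.random.SeedSequence(seed).spawn(R)
    rows = []
    for k in range(R):
        rng = np.random.default_rng(streams[k])
        for attempt in range(1, sim_template.max_attempts + 1):
            draw = priors.sample(rng)
            config = CellSimConfig(
                split_prob=draw.get("p", sim_template.split_prob),
                mutation_rate=draw.get("theta", sim_template.mutation_rate),
                target_size=sim_template.target_size,
                sample_size=sim_template.sample_size,
                event_rate=sim_template.event_rate,
                include_stem=sim_template.include_stem,
                per_division=sim_template.per_division,
                max_attempts=sim_template.max_attempts,
            )
            population = try_grow_population(config, rng)
            if population is not None:
                break
        else:
            raise RuntimeError(f"row {k}: no draw reached N in {sim_template.max_attempts} attempts")
        sub = sample_tree(population, config.sample_size, rng=rng)
        sfs = drop_mutations(
            sub, config.mutation_rate, rng=rng,
            include_stem=config.include_stem, per_division=config.per_division,
        )
        stats = summarize(sfs)
        rows.append(
            {**{k2: draw[k2] for k2 in priors.names},
             **dict(zip(SUMMARY_COLUMNS, stats.vector())),
             "attempts": attempt}
        )
    return ReferenceTable(data=pd.DataFrame(rows), param_names=priors.names)


def abc_rejection(
    table: ReferenceTable, observed, accept_fraction: float = 0.01
) -> Posterior:
    """Rejection ABC: keep the rows closest to the observation.

    Euclidean distance on summaries standardized by the table's per-column
    mean and standard deviation; the closest ceil(fraction * R) rows get
    uniform weight.  accept_fraction = 1 returns the (conditioned) prior sample.
    """
    if not 0 < accept_fraction <= 1:
        raise ValueError("accept_fraction must be in (0, 1]")
    if len(table) == 0:
        raise ValueError("empty reference table")
    obs = np.asarray(observed, dtype=float)
    if obs.shape != (len(table.stat_names),):
        raise ValueError(f"observed must have length {len(table.stat_names)}")
    x = table.stats
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    d = np.linalg.norm((x - mu) / sd - (obs - mu) / sd, axis=1)
    n_keep = math.ceil(accept_fraction * len(table))
    keep = np.argsort(d, kind="stable")[:n_keep]
    w = np.zeros(len(table))
    w[keep] = 1.0
    return Posterior(params=table.data[table.param_names].copy(), weights=w)


@dataclass
class ForestEnsemble:
    """Bagged regression trees with per-tree in-bag bookkeeping.

    ``mode`` is "rf" for a univariate response (ABC-RF) and "drf" for the
    multivariate parameter vector (ABC-DRF); splitting in DRF mode minimizes
    summed variance over standardized response components.
    """

    trees: list
    bag_indices: list  # per tree: array of training-row indices (with repeats)
    x: np.ndarray
    y: np.ndarray  # standardized response, 2-D
    y_raw: np.ndarray
    response_names: list[str]
    feature_names: list[str]
    mode: str

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def oob_matrix(self) -> np.ndarray:
        """Boolean (n_trees, R): row r out of bag for tree k."""
        n = len(self.x)
        oob = np.ones((self.n_trees, n), dtype=bool)
        for k, bag in enumerate(self.bag_indices):
            oob[k, bag] = False
        return oob

    def oob_prediction(self) -> np.ndarray:
        """OOB-averaged prediction of the standardized response per row."""
        n = len(self.x)
        acc = np.zeros((n, self.y.shape[1]))
        cnt = np.zeros(n)
        oob = self.oob_matrix()
        for k, tree in enumerate(self.trees):
            mask = oob[k]
            if mask.any():
                acc[mask] += tree.predict(self.x[mask]).reshape(mask.sum(), -1)
                cnt[mask] += 1
        cnt[cnt == 0] = 1.0
        return acc / cnt[:, None]

    def oob_error(self) -> float:
        """Mean squared OOB error summed over standardized response components."""
        pred = self.oob_prediction()
        return float(np.mean(np.sum((pred - self.y) ** 2, axis=1)))


def fit_forest(
    table: ReferenceTable,
    response="theta",
    n_trees: int = 500,
    min_leaf: int = 5,
    max_features: int | None = None,
    seed=None,
) -> ForestEnsemble:
    """Fit a regression forest of the reference table's summaries on parameters.

    ``response`` is one parameter name (ABC-RF) or a sequence of names
    (ABC-DRF).  Defaults: 500 trees, leaves of at least 5 rows, ceil(d/3)
    candidate features per split.  Out-of-bag rows are tracked per tree for
    OOB error and permutation importance.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    names = [response] if isinstance(response, str) else list(response)
    mode = "rf" if len(names) == 1 else "drf"
    x = table.stats
    y_raw = table.data[names].to_numpy(dtype=float)
    sd = y_raw.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("response has zero variance")
    y = (y_raw - y_raw.mean(axis=0)) / sd
    d = x.shape[1]
    max_features = max_features or math.ceil(d / 3)
    rng = np.random.default_rng(seed)
    n = len(x)
    trees, bags = [], []
    for _ in range(n_trees):
        bag = rng.integers(n, size=n)
        tree = DecisionTreeRegressor(
            min_samples_leaf=min_leaf,
            max_features=max_features,
            random_state=int(rng.integers(2**31 - 1)),
        )
        tree.fit(x[bag], y[bag])
        trees.append(tree)
        bags.append(bag)
    return ForestEnsemble(
        trees=trees,
        bag_indices=bags,
        x=x,
        y=y,
        y_raw=y_raw,
        response_names=names,
        feature_names=list(table.stat_names),
        mode=mode,
    )


def posterior_weights(ensemble: ForestEnsemble, table: ReferenceTable, observed) -> Posterior:
    """Leaf co-membership posterior weights for an observed summary vector.

    Row i's weight is the average over trees of
    [row i falls in the leaf containing the observation] / (leaf size),
    with leaves populated by all reference rows.  In DRF mode the same weights
    equip the joint empirical law of the parameter vector.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.shape != (len(ensemble.feature_names),):
        raise ValueError(f"observed must have length {len(ensemble.feature_names)}")
    n = len(ensemble.x)
    w = np.zeros(n)
    obs_row = obs.reshape(1, -1)
    for tree in ensemble.trees:
        leaf_obs = tree.apply(obs_row)[0]
        in_leaf = tree.apply(ensemble.x) == leaf_obs
        size = in_leaf.sum()
        if size:
            w[in_leaf] += 1.0 / size
    w /= ensemble.n_trees
    return Posterior(params=table.data[ensemble.response_names].copy(), weights=w)


def variable_importance(ensemble: ForestEnsemble, seed=None) -> pd.Series:
    """Out-of-bag permutation importance per summary statistic, descending.

    For each tree, the increase in OOB squared error (summed over standardized
    response components) when one feature column is permuted among the OOB
    rows; averaged over trees.
    """
    rng = np.random.default_rng(seed)
    oob = ensemble.oob_matrix()
    d = ensemble.x.shape[1]
    scores = np.zeros(d)
    counts = np.zeros(d)
    for k, tree in enumerate(ensemble.trees):
        mask = oob[k]
        if not mask.any():
            continue
        x_oob = ensemble.x[mask]
        y_oob = ensemble.y[mask]
        base = np.mean(np.sum((tree.predict(x_oob).reshape(len(x_oob), -1) - y_oob) ** 2, axis=1))
        for j in range(d):
            x_perm = x_oob.copy()
            x_perm[:, j] = x_perm[rng.permutation(len(x_perm)), j]
            err = np.mean(
                np.sum((tree.predict(x_perm).reshape(len(x_perm), -1) - y_oob) ** 2, axis=1)
            )
            scores[j] += err - base
            counts[j] += 1
    counts[counts == 0] = 1.0
    return pd.Series(scores / counts, index=ensemble.feature_names).sort_values(ascending=False)


def posterior_report(
    posterior: Posterior,
    levels=(0.5, 0.9),
    kde_grid: int = 256,
    joint_grid: int = 64,
) -> dict:
    """Posterior summaries: means, medians, credible intervals, densities.

    Returns a dict with ``mean``, ``median``, ``ci`` (per level, per parameter),
    ``marginal`` (per-parameter weighted-KDE grids), and for two-parameter
    posteriors ``joint``: a 2-D weighted-KDE density grid.
    """
    names = list(posterior.params.columns)
    report: dict = {
        "mean": posterior.mean(),
        "median": pd.Series({n: posterior.quantile(0.5, n) for n in names}),
        "ci": {
            lvl: {n: posterior.credible_interval(n, lvl) for n in names} for lvl in levels
        },
        "marginal": {},
    }
    w = posterior.weights
    for n in names:
        x = posterior.params[n].to_numpy()
        grid = np.linspace(x.min(), x.max(), kde_grid)
        if np.average((x - np.average(x, weights=w)) ** 2, weights=w) > 0:
            dens = gaussian_kde(x, weights=w)(grid)
        else:  # degenerate posterior: all mass at one support point
            dens = np.zeros(kde_grid)
            dens[np.argmin(np.abs(grid - x[np.argmax(w)]))] = 1.0
        report["marginal"][n] = pd.DataFrame({n: grid, "density": dens})
    if len(names) == 2:
        a, b = (posterior.params[n].to_numpy() for n in names)
        ga = np.linspace(a.min(), a.max(), joint_grid)
        gb = np.linspace(b.min(), b.max(), joint_grid)
        xx, yy = np.meshgrid(ga, gb)
        try:
            kde = gaussian_kde(np.vstack([a, b]), weights=w)
            zz = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
        except np.linalg.LinAlgError:  # singular weighted covariance
            zz = np.zeros_like(xx)
        report["joint"] = {"x": ga, "y": gb, "density": zz, "names": names}
    return report


def qq_table(post_a: Posterior, post_b: Posterior, name: str, n_points: int = 99) -> pd.DataFrame:
    """Quantile-quantile comparison of one parameter under two posteriors."""
    q = np.linspace(0.01, 0.99, n_points)
    return pd.DataFrame(
        {"q": q, "a": post_a.quantile(q, name), "b": post_b.quantile(q, name)}
    )
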