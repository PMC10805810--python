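"""Design-of-experiments agent: random/LHS start, then Thompson-sampling
multi-objective Bayesian optimisation.

One Gaussian-process surrogate per objective (maximise yield, minimise cost) is
fitted on all non-abnormal cross-lab history; a proposal is made by drawing one
approximate posterior sample per objective via spectral (random Fourier
feature) approximation, running NSGA-II on the sampled functions, and returning
the candidate with the largest hypervolume improvement over the current
measured Pareto front.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import qmc
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .kg_store import (C, CONDITION_FIELDS, Graph, Iri, ReactionCondition,
                       analysed_experiments)

# TSEMO-style defaults; all exposed in the campaign config.
DEFAULT_N_INIT = 8
DEFAULT_N_SPECTRAL = 300
DEFAULT_NSGA_POP = 60
DEFAULT_NSGA_GEN = 60
DEFAULT_REF_MARGIN = 0.1
DEFAULT_GP_RESTARTS = 2


@dataclass(frozen=True)
class SearchSpace:
    """Box bounds over the four continuous reaction-condition variables."""

    bounds: dict  # field name -> (lower, upper)

    def __post_init__(self) -> None:
        missing = [f for f in CONDITION_FIELDS if f not in self.bounds]
        if missing:
            raise ValueError(f"search space missing bounds for {missing}")
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"degenerate bounds for {name}: ({lo}, {hi})")

    @property
    def lower(self) -> np.ndarray:
        return np.array([self.bounds[f][0] for f in CONDITION_FIELDS])

    @property
    def upper(self) -> np.ndarray:
        return np.array([self.bounds[f][1] for f in CONDITION_FIELDS])

    def contains(self, condition: ReactionCondition) -> bool:
        x = condition.as_array()
        return bool(np.all(x >= self.lower) and np.all(x <= self.upper))

    def to_unit(self, x: np.ndarray) -> np.ndarray:
        return (x - self.lower) / (self.upper - self.lower)

    def from_unit(self, u: np.ndarray) -> np.ndarray:
        return self.lower + u * (self.upper - self.lower)


@dataclass
class HistoricalData:
    """Cross-lab optimiser history: Analysed, non-abnormal experiments only."""

    experiments: list            # ReactionExperiment records
    stock: dict = field(default_factory=dict)  # pump container iri -> fill level mL

    def __post_init__(self) -> None:
        from .kg_store import ExperimentStatus
        for exp in self.experiments:
            if exp.status is not ExperimentStatus.Analysed:
                raise ValueError(f"{exp.iri}: history must contain only Analysed runs")
            if exp.indicators.abnormal_flag:
                raise ValueError(f"{exp.iri}: abnormal runs never enter history")

    def __len__(self) -> int:
        return len(self.experiments)

    def arrays(self):
        x = np.array([e.condition.as_array() for e in self.experiments])
        y = np.array([[e.indicators.yield_pct, e.indicators.run_material_cost]
                      for e in self.experiments])
        return x, y


def gather_history(graph: Graph, goalset=None, is_control=None) -> HistoricalData:
    """All Analysed, non-abnormal experiments across participating labs, plus a
    stock snapshot (control/onboarding runs are not optimiser data)."""
    from .kg_store import P
    experiments = []
    for exp in analysed_experiments(graph, include_abnormal=False):
        if is_control is not None and is_control(exp.iri):
            continue
        experiments.append(exp)
    stock = {}
    for t in graph.query(None, P.hasFillLevel, None):
        stock[t.subject.value] = t.object.to_python()
    return HistoricalData(experiments=experiments, stock=stock)


def propose_random(space: SearchSpace, rng: np.random.Generator) -> ReactionCondition:
    """One uniform draw strictly inside the box (reproducible per generator state)."""
    u = rng.uniform(size=len(CONDITION_FIELDS))
    return ReactionCondition.from_array(space.from_unit(u))


def lhs_batch(space: SearchSpace, n: int, rng: np.random.Generator) -> list:
    """Space-filling initial batch: one sample per 1/n stratum in every dimension."""
    if n <= 0:
        raise ValueError("batch size must be positive")
    sampler = qmc.LatinHypercube(d=len(CONDITION_FIELDS), seed=rng)
    u = sampler.random(n)
    return [ReactionCondition.from_array(space.from_unit(row)) for row in u]


# -- surrogates --------------------------------------------------------------


@dataclass
class GPSurrogate:
    """One fitted objective model in normalised coordinates.

    ``gp`` is None for the degenerate (constant-objective) fallback, in which
    case the prior mean (the constant) is used everywhere.
    """

    gp: Optional[GaussianProcessRegressor]
    x_train: np.ndarray          # unit-cube inputs
    y_mean: float
    y_std: float
    constant: bool = False

    def predict(self, u: np.ndarray) -> np.ndarray:
        if self.constant:
            return np.full(len(np.atleast_2d(u)), self.y_mean)
        z = self.gp.predict(np.atleast_2d(u))
        return z * self.y_std + self.y_mean

    def hyperparameters(self):
        k = self.gp.kernel_
        signal = k.k1.k1.constant_value
        lengthscales = np.atleast_1d(k.k1.k2.length_scale)
        noise = k.k2.noise_level + self.gp.alpha
        return signal, lengthscales, noise


@dataclass
class SurrogatePair:
    yield_model: GPSurrogate
    cost_model: GPSurrogate
    space: SearchSpace

    @property
    def models(self):
        return (self.yield_model, self.cost_model)


def _fit_one(x_unit: np.ndarray, y: np.ndarray, restarts: int,
             random_state: int) -> GPSurrogate:
    y_mean, y_std = float(np.mean(y)), float(np.std(y))
    if y_std < 1e-12:
        warnings.warn("degenerate constant objective: falling back to prior-only GP",
                      stacklevel=3)
        return GPSurrogate(gp=None, x_train=x_unit, y_mean=y_mean, y_std=1.0,
                           constant=True)
    z = (y - y_mean) / y_std
    kernel = (ConstantKernel(1.0, (1e-3, 1e3))
              * RBF(length_scale=[0.3] * x_unit.shape[1],
                    length_scale_bounds=(1e-2, 1e2))
              + WhiteKernel(noise_level=1e-4, noise_level_bounds=(1e-9, 1e-1)))
    gp = GaussianProcessRegressor(kernel=kernel, alpha=1e-10, normalize_y=False,
                                  n_restarts_optimizer=restarts,
                                  random_state=random_state)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        gp.fit(x_unit, z)
    return GPSurrogate(gp=gp, x_train=x_unit, y_mean=y_mean, y_std=y_std)


def fit_surrogates(history, space: SearchSpace, rng: np.random.Generator,
                   n_init: int = DEFAULT_N_INIT,
                   restarts: int = DEFAULT_GP_RESTARTS) -> SurrogatePair:
    """Fit the (yield, cost) GP pair on normalised inputs / standardised outputs.

    ``history`` is a :class:`HistoricalData` or an ``(X, Y)`` pair of raw
    condition rows and objective columns.  Requires at least ``n_init`` points.
    """
    if isinstance(history, HistoricalData):
        x, y = history.arrays()
    else:
        x, y = history
        x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < n_init:
        raise ValueError(f"need at least n_init={n_init} points, got {len(x)}")
    x_unit = space.to_unit(x)
    seeds = rng.integers(0, 2**31 - 1, size=2)
    return SurrogatePair(
        yield_model=_fit_one(x_unit, y[:, 0], restarts, int(seeds[0])),
        cost_model=_fit_one(x_unit, y[:, 1], restarts, int(seeds[1])),
        space=space,
    )


def _thompson_sample(model: GPSurrogate, rng: np.random.Generator, n_features: int):
    """Approximate posterior function sample via random Fourier features.

    phi(x) = sqrt(2 s^2 / M) cos(W x + b) with W ~ N(0, diag(1/l^2)); Bayesian
    linear regression on the training set gives w | y ~ N(A^-1 Phi^T y,
    sigma_n^2 A^-1) with A = Phi^T Phi + sigma_n^2 I.
    """
    if model.constant:
        mean = model.y_mean
        return lambda u: np.full(len(np.atleast_2d(u)), mean)
    signal, lengthscales, noise = model.hyperparameters()
    d = model.x_train.shape[1]
    w_freq = rng.normal(size=(n_features, d)) / np.asarray(lengthscales)
    b = rng.uniform(0.0, 2.0 * np.pi, size=n_features)
    scale = np.sqrt(2.0 * signal / n_features)

    def phi(u):
        return scale * np.cos(np.atleast_2d(u) @ w_freq.T + b)

    phi_x = phi(model.x_train)
    z = model.gp.y_train_
    a = phi_x.T @ phi_x + noise * np.eye(n_features)
    cf = cho_factor(a, lower=True)
    w_mean = cho_solve(cf, phi_x.T @ z)
    lower = np.linalg.cholesky(a)
    w = w_mean + np.sqrt(noise) * np.linalg.solve(lower.T, rng.normal(size=n_features))
    y_mean, y_std = model.y_mean, model.y_std

    def sample(u):
        return phi(u) @ w * y_std + y_mean

    return sample


# -- Pareto / hypervolume -----------------------------------------------------


def pareto_mask(yields, costs) -> np.ndarray:
    """Non-dominated mask (maximise yield, minimise cost); identical objective
    vectors keep a single representative (first occurrence).

    O(n log n) sweep: sorted by (cost asc, yield desc, index), a point survives
    iff its yield strictly exceeds every yield seen so far (all of which are at
    most as expensive).
    """
    y = np.asarray(yields, float)
    c = np.asarray(costs, float)
    n = len(y)
    mask = np.zeros(n, dtype=bool)
    order = np.lexsort((np.arange(n), -y, c))
    best = -np.inf
    for i in order:
        if y[i] > best:
            mask[i] = True
            best = y[i]
    return mask


@dataclass
class ParetoFront:
    points: np.ndarray           # (n, 2) columns: yield %, cost
    iris: list                   # experiment IRIs aligned with rows (may be empty)
    reference_point: tuple       # (yield_ref, cost_ref), dominated by every point

    @property
    def hypervolume(self) -> float:
        return hypervolume(self.points, self.reference_point)


def pareto_front(points, iris=None, reference_point=None,
                 ref_margin: float = DEFAULT_REF_MARGIN) -> ParetoFront:
    """Exact non-dominated subset of (yield, cost) points."""
    pts = np.atleast_2d(np.asarray(points, float))
    if pts.size == 0:
        pts = pts.reshape(0, 2)
    if not np.all(np.isfinite(pts)):
        raise ValueError("Pareto points must be finite")
    iris = list(iris) if iris is not None else [None] * len(pts)
    mask = pareto_mask(pts[:, 0], pts[:, 1]) if len(pts) else np.zeros(0, bool)
    front = pts[mask]
    if reference_point is None:
        if len(pts):
            span_y = max(np.ptp(pts[:, 0]), 1.0)
            span_c = max(np.ptp(pts[:, 1]), 1.0)
            reference_point = (float(pts[:, 0].min() - ref_margin * span_y),
                               float(pts[:, 1].max() + ref_margin * span_c))
        else:
            reference_point = (0.0, 1.0)
    front_iris = [i for i, m in zip(iris, mask) if m]
    if len(front):
        order = np.argsort(front[:, 1])
        front = front[order]
        front_iris = [front_iris[i] for i in order]
    return ParetoFront(points=front, iris=front_iris, reference_point=reference_point)


def hypervolume(front_points, reference_point) -> float:
    """2-D hypervolume by sweep (maximise yield, minimise cost).

    The reference point must be dominated (weakly) by every front point.
    """
    pts = np.atleast_2d(np.asarray(front_points, float))
    if pts.size == 0:
        return 0.0
    y_ref, c_ref = reference_point
    if np.any(pts[:, 0] < y_ref) or np.any(pts[:, 1] > c_ref):
        raise ValueError(f"reference point {reference_point} is not dominated by "
                         "every front point")
    mask = pareto_mask(pts[:, 0], pts[:, 1])
    pts = pts[mask]
    order = np.argsort(pts[:, 1])  # cost ascending -> yield ascending on a front
    pts = pts[order]
    hv = 0.0
    for i in range(len(pts)):
        next_cost = pts[i + 1, 1] if i + 1 < len(pts) else c_ref
        hv += (pts[i, 0] - y_ref) * (next_cost - pts[i, 1])
    return float(hv)


# -- NSGA-II on the sampled functions ----------------------------------------


def _fast_nondominated_rank(obj: np.ndarray) -> np.ndarray:
    """Rank (0 = best front) for a minimisation problem, O(n^2)."""
    n = len(obj)
    dominates = ((obj[:, None, :] <= obj[None, :, :]).all(axis=2)
                 & (obj[:, None, :] < obj[None, :, :]).any(axis=2))
    counts = dominates.sum(axis=0)
    ranks = np.full(n, -1)
    current = np.where(counts == 0)[0]
    r = 0
    remaining = counts.copy()
    while len(current):
        ranks[current] = r
        for i in current:
            remaining -= dominates[i]
        remaining[current] = np.iinfo(int).max
        current = np.where(remaining == 0)[0]
        r += 1
    return ranks


def _crowding(obj: np.ndarray, idx: np.ndarray) -> np.ndarray:
    dist = np.zeros(len(idx))
    for m in range(obj.shape[1]):
        vals = obj[idx, m]
        order = np.argsort(vals)
        span = vals[order[-1]] - vals[order[0]]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span <= 0 or len(idx) < 3:
            continue
        dist[order[1:-1]] += (vals[order[2:]] - vals[order[:-2]]) / span
    return dist


def _nsga2(fns, d: int, rng: np.random.Generator, pop_size: int, generations: int,
           eta_c: float = 15.0, eta_m: float = 20.0) -> np.ndarray:
    """Minimise the vector of callables ``fns`` over the unit cube; returns the
    final population's non-dominated decision vectors."""

    def evaluate(u):
        return np.column_stack([f(u) for f in fns])

    pop = rng.uniform(size=(pop_size, d))
    obj = evaluate(pop)
    for _ in range(generations):
        ranks = _fast_nondominated_rank(obj)
        crowd = np.zeros(pop_size)
        for r in np.unique(ranks):
            idx = np.where(ranks == r)[0]
            crowd[idx] = _crowding(obj, idx)
        # binary tournaments
        a = rng.integers(pop_size, size=pop_size)
        b = rng.integers(pop_size, size=pop_size)
        better = (ranks[a] < ranks[b]) | ((ranks[a] == ranks[b]) & (crowd[a] > crowd[b]))
        parents = pop[np.where(better, a, b)]
        # SBX crossover
        p1, p2 = parents[0::2], parents[1::2]
        u = rng.uniform(size=p1.shape)
        beta = np.where(u <= 0.5, (2 * u) ** (1 / (eta_c + 1)),
                        (1 / (2 * (1 - u))) ** (1 / (eta_c + 1)))
        mask = rng.uniform(size=p1.shape) < 0.9
        beta = np.where(mask, beta, 1.0)
        c1 = 0.5 * ((1 + beta) * p1 + (1 - beta) * p2)
        c2 = 0.5 * ((1 - beta) * p1 + (1 + beta) * p2)
        children = np.vstack([c1, c2])
        # polynomial mutation, prob 1/d per gene
        mut = rng.uniform(size=children.shape) < 1.0 / d
        u = rng.uniform(size=children.shape)
        delta = np.where(u < 0.5, (2 * u) ** (1 / (eta_m + 1)) - 1,
                         1 - (2 * (1 - u)) ** (1 / (eta_m + 1)))
        children = np.clip(children + np.where(mut, delta, 0.0), 0.0, 1.0)
        child_obj = evaluate(children)
        # elitist environmental selection
        all_pop = np.vstack([pop, children])
        all_obj = np.vstack([obj, child_obj])
        ranks = _fast_nondominated_rank(all_obj)
        chosen: list[int] = []
        for r in np.unique(ranks):
            idx = np.where(ranks == r)[0]
            if len(chosen) + len(idx) <= pop_size:
                chosen.extend(idx.tolist())
            else:
                crowd = _crowding(all_obj, idx)
                take = np.argsort(-crowd)[: pop_size - len(chosen)]
                chosen.extend(idx[take].tolist())
                break
        pop, obj = all_pop[chosen], all_obj[chosen]
    ranks = _fast_nondominated_rank(obj)
    return pop[ranks == 0]


def propose_tsemo(surrogates: SurrogatePair, space: SearchSpace, front: ParetoFront,
                  rng: np.random.Generator,
                  n_spectral: int = DEFAULT_N_SPECTRAL,
                  nsga_pop: int = DEFAULT_NSGA_POP,
                  nsga_gen: int = DEFAULT_NSGA_GEN) -> ReactionCondition:
    """One Thompson-sampling proposal maximising hypervolume improvement.

    Falls back to a random in-bounds proposal (with a logged warning) if the
    evolutionary search fails to produce candidates.
    """
    try:
        f_yield = _thompson_sample(surrogates.yield_model, rng, n_spectral)
        f_cost = _thompson_sample(surrogates.cost_model, rng, n_spectral)
        candidates = _nsga2([lambda u: -f_yield(u), f_cost],
                            d=len(CONDITION_FIELDS), rng=rng,
                            pop_size=nsga_pop, generations=nsga_gen)
        if len(candidates) == 0:
            raise RuntimeError("empty candidate set")
        pred = np.column_stack([f_yield(candidates), f_cost(candidates)])
        ref = front.reference_point
        # clip predictions into the dominated-region frame so HVI is defined
        pred_clipped = np.column_stack([np.maximum(pred[:, 0], ref[0]),
                                        np.minimum(pred[:, 1], ref[1])])
        base = hypervolume(front.points, ref) if len(front.points) else 0.0
        hvi = np.array([
            hypervolume(np.vstack([front.points, p[None, :]]) if len(front.points)
                        else p[None, :], ref) - base
            for p in pred_clipped])
        best = int(np.argmax(hvi))
        return ReactionCondition.from_array(
            np.clip(space.from_unit(candidates[best]), space.lower, space.upper))
    except Exception as exc:  # noqa: BLE001 - optimiser robustness path
        warnings.warn(f"TSEMO proposal failed ({exc}); falling back to random",
                      stacklevel=2)
        return propose_random(space, rng)
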