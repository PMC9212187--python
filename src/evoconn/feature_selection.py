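"""Fixed-cardinality feature-subset search.

Wrapper feature selection: the quality (fitness) of a candidate subset of
feature columns is the cross-validated accuracy of the perceptron trained
on exactly those columns.  Five stochastic search strategies are provided —
genetic algorithm (GA), nondominated sorting genetic algorithm II
(NSGA-II), ant colony optimization (ACO), simulated annealing (SA) and
particle swarm optimization (PSO) — together with a filter baseline that
ranks features by Welch two-sample t-test p-values.

All algorithms search subsets of a fixed cardinality k (NSGA-II lets the
cardinality float up to k_max and trades it off against accuracy), repair
candidates back to valid cardinality after variation, memoize fitness
evaluations, and are bit-reproducible given (seed, config, table).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .classifier import TrainConfig, cross_validate
from .graph_features import FeatureTable

__all__ = [
    "FeatureSubset",
    "SelectionResult",
    "Nsga2Result",
    "FitnessConfig",
    "GaParams",
    "Nsga2Params",
    "AcoParams",
    "SaParams",
    "PsoParams",
    "EaConfig",
    "FitnessCache",
    "evaluate_fitness",
    "ga_select",
    "nsga2_select",
    "aco_select",
    "sa_select",
    "pso_select",
    "ttest_select",
    "stat_select",
    "welch_t_pvalues",
]


@dataclass(frozen=True)
class FeatureSubset:
    """An ordered set of distinct feature column indices."""

    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = tuple(sorted(int(i) for i in self.indices))
        if len(set(idx)) != len(idx) or not idx:
            raise ValueError("indices must be non-empty and distinct")
        if idx[0] < 0:
            raise ValueError("indices must be non-negative")
        object.__setattr__(self, "indices", idx)

    @property
    def k(self) -> int:
        return len(self.indices)


@dataclass
class SelectionResult:
    """Outcome of one subset search run."""

    algorithm: str
    seed: int
    k: int
    best_indices: tuple[int, ...]
    best_feature_names: list[str]
    best_fitness: float  # accuracy, percent
    history: list[float]  # best-so-far fitness per iteration
    evaluations: int
    config: dict

    def to_json(self) -> str:
        d = asdict(self)
        d["best_indices"] = list(d["best_indices"])
        return json.dumps(d, sort_keys=True, separators=(",", ":"))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "SelectionResult":
        d = json.loads(text)
        d["best_indices"] = tuple(d["best_indices"])
        return cls(**d)


# ---------------------------------------------------------------------------
# fitness


@dataclass
class FitnessConfig:
    """How subset fitness (classifier accuracy, %) is measured.

    ``mode='single'`` scores one stratified 90/10 split — the cheap variant
    intended for the inner loop of subset searches; ``mode='kfold'`` is the
    full stratified cross-validation used for final reporting.
    """

    mode: str = "kfold"
    n_folds: int = 10
    repeats: int = 1
    seed: int = 0
    hidden: tuple[int, int] = (10, 10)
    train: TrainConfig = field(default_factory=TrainConfig)


def fast_fitness_config(seed: int = 0) -> FitnessConfig:
    """Single-split fitness with a short LM budget, for search inner loops."""
    return FitnessConfig(mode="single", seed=seed, train=TrainConfig(max_epochs=30))


class FitnessCache:
    """Memoizes subset -> accuracy; identical queries return identical values."""

    def __init__(self, fn: Callable[[tuple[int, ...]], float]):
        self._fn = fn
        self._store: dict[tuple[int, ...], float] = {}
        self.hits = 0
        self.misses = 0

    def __call__(self, indices: Sequence[int]) -> float:
        key = tuple(sorted(int(i) for i in indices))
        if key in self._store:
            self.hits += 1
        else:
            self.misses += 1
            self._store[key] = self._fn(key)
        return self._store[key]

    @property
    def evaluations(self) -> int:
        return self.misses


def evaluate_fitness(
    subset: FeatureSubset | Sequence[int],
    table: FeatureTable,
    cfg: FitnessConfig | None = None,
) -> float:
    """Cross-validated accuracy (%) of the MLP on the given feature columns.

    Columns are standardized per fold on the training split only.
    """
    cfg = cfg or FitnessConfig()
    idx = subset.indices if isinstance(subset, FeatureSubset) else tuple(subset)
    if any(i < 0 or i >= table.n_features for i in idx):
        raise IndexError(f"subset indices out of range for F={table.n_features}")
    res = cross_validate(
        table.data[:, list(idx)],
        table.labels,
        n_folds=cfg.n_folds,
        repeats=cfg.repeats,
        seed=cfg.seed,
        cfg=cfg.train,
        standardize=True,
        mode="kfold" if cfg.mode == "kfold" else "single",
        hidden=cfg.hidden,
    )
    return res.mean_accuracy


def _make_fitness(
    table: FeatureTable | None,
    cfg: "EaConfig",
    fitness_fn: Callable[[tuple[int, ...]], float] | None,
) -> FitnessCache:
    if fitness_fn is None:
        if table is None:
            raise ValueError("either a feature table or a fitness_fn is required")
        fitness_fn = lambda idx: evaluate_fitness(idx, table, cfg.fitness)  # noqa: E731
    return FitnessCache(fitness_fn)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class GaParams:
    pop: int = 20
    mutation_percentage: float = 0.3
    mutation_rate: float = 0.1
    crossover_count: int = 14
    selection_pressure: float = 8.0


@dataclass
class Nsga2Params:
    pop: int = 25
    mutation_percentage: float = 0.4
    mutation_rate: float = 0.1
    crossover_count: int = 14


@dataclass
class AcoParams:
    n_ants: int = 10
    evaporation: float = 0.05
    initial_weight: float = 1.0
    exponential_weight: float = 1.0
    heuristic_weight: float = 1.0


@dataclass
class SaParams:
    t0: float = 10.0
    cooling: float = 0.99


@dataclass
class PsoParams:
    swarm: int = 20
    c1: float = 1.5
    c2: float = 1.5
    inertia: float = 0.72


@dataclass
class EaConfig:
    """Search budget, seed and per-algorithm parameters."""

    iterations: int = 200
    seed: int = 0
    fitness: FitnessConfig = field(default_factory=FitnessConfig)
    ga: GaParams = field(default_factory=GaParams)
    nsga2: Nsga2Params = field(default_factory=Nsga2Params)
    aco: AcoParams = field(default_factory=AcoParams)
    sa: SaParams = field(default_factory=SaParams)
    pso: PsoParams = field(default_factory=PsoParams)

    def __post_init__(self) -> None:
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if not (0 < self.sa.cooling < 1):
            raise ValueError("SA cooling must lie in (0, 1)")
        for rate in (self.ga.mutation_rate, self.nsga2.mutation_rate):
            if not (0 < rate <= 1):
                raise ValueError("mutation rates must lie in (0, 1]")

    def summary(self, algorithm: str) -> dict:
        d = {"iterations": self.iterations, "fitness_mode": self.fitness.mode}
        params = getattr(self, algorithm, None)
        if params is not None:
            d[algorithm] = asdict(params)
        return d


# ---------------------------------------------------------------------------
# shared helpers


def _random_mask(rng: np.random.Generator, F: int, k: int) -> np.ndarray:
    mask = np.zeros(F, dtype=bool)
    mask[rng.choice(F, size=k, replace=False)] = True
    return mask


def _repair(mask: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Force the mask back to exactly k selected features."""
    mask = mask.copy()
    sel = np.flatnonzero(mask)
    if sel.size > k:
        drop = rng.choice(sel, size=sel.size - k, replace=False)
        mask[drop] = False
    elif sel.size < k:
        unsel = np.flatnonzero(~mask)
        add = rng.choice(unsel, size=k - sel.size, replace=False)
        mask[add] = True
    return mask


def _crossover(p1: np.ndarray, p2: np.ndarray, rng: np.random.Generator):
    """One of single-point, double-point or uniform crossover on the masks."""
    F = p1.size
    if F < 2:
        return p1.copy(), p2.copy()
    op = rng.integers(3)
    if op == 0:  # single point
        c = int(rng.integers(1, F))
        c1 = np.concatenate([p1[:c], p2[c:]])
        c2 = np.concatenate([p2[:c], p1[c:]])
    elif op == 1:  # double point
        a, b = sorted(rng.choice(np.arange(1, F), size=2, replace=False)) if F > 2 else (1, 1)
        c1, c2 = p1.copy(), p2.copy()
        c1[a:b], c2[a:b] = p2[a:b], p1[a:b]
    else:  # uniform
        m = rng.random(F) < 0.5
        c1 = np.where(m, p1, p2)
        c2 = np.where(m, p2, p1)
    return c1, c2


def _mutate_swap(mask: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Swap each selected feature, with probability ``rate``, for an unselected one."""
    mask = mask.copy()
    for i in np.flatnonzero(mask):
        if rng.random() < rate:
            unsel = np.flatnonzero(~mask)
            if unsel.size == 0:
                break
            j = rng.choice(unsel)
            mask[i] = False
            mask[j] = True
    return mask


def _boltzmann_probs(fitness: np.ndarray, beta: float) -> np.ndarray:
    fmin, fmax = fitness.min(), fitness.max()
    if fmax - fmin < 1e-12:
        return np.full(fitness.size, 1.0 / fitness.size)
    w = np.exp(beta * (fitness - fmax) / (fmax - fmin))
    return w / w.sum()


def _result(
    algorithm: str,
    cfg: EaConfig,
    k: int,
    best_mask: np.ndarray,
    best_fit: float,
    history: list[float],
    cache: FitnessCache,
    table: FeatureTable | None,
) -> SelectionResult:
    idx = tuple(int(i) for i in np.flatnonzero(best_mask))
    names = [table.feature_names[i] for i in idx] if table is not None else []
    return SelectionResult(
        algorithm=algorithm,
        seed=cfg.seed,
        k=k,
        best_indices=idx,
        best_feature_names=names,
        best_fitness=float(best_fit),
        history=[float(h) for h in history],
        evaluations=cache.evaluations,
        config=cfg.summary(algorithm),
    )


# ---------------------------------------------------------------------------
# genetic algorithm


def ga_select(
    table: FeatureTable | None,
    k: int,
    cfg: EaConfig | None = None,
    fitness_fn: Callable[[tuple[int, ...]], float] | None = None,
) -> SelectionResult:
    """Elitist genetic algorithm over fixed-cardinality subsets.

    Boltzmann roulette parent selection (pressure beta), crossover operator
    drawn uniformly from {single-point, double-point, uniform} followed by
    cardinality repair, swap mutation applied to a fraction of the
    offspring, and survivor truncation of parents + offspring to the
    population size (which keeps the best individual: elitism).
    """
    cfg = cfg or EaConfig()
    cache = _make_fitness(table, cfg, fitness_fn)
    F = table.n_features if table is not None else _infer_F(fitness_fn, k)
    if k > F:
        raise ValueError(f"k={k} exceeds number of features F={F}")
    rng = np.random.default_rng(cfg.seed)
    p = cfg.ga

    if k == F:
        mask = np.ones(F, dtype=bool)
        f = cache(np.flatnonzero(mask))
        return _result("ga", cfg, k, mask, f, [f], cache, table)

    pop = [_random_mask(rng, F, k) for _ in range(p.pop)]
    fit = np.array([cache(np.flatnonzero(m)) for m in pop])
    order = np.argsort(-fit, kind="stable")
    pop = [pop[i] for i in order]
    fit = fit[order]
    history = [float(fit[0])]

    for _ in range(cfg.iterations):
        probs = _boltzmann_probs(fit, p.selection_pressure)
        n_children = p.crossover_count
        children: list[np.ndarray] = []
        while len(children) < n_children:
            i, j = rng.choice(len(pop), size=2, p=probs)
            c1, c2 = _crossover(pop[i], pop[j], rng)
            children.append(_repair(c1, k, rng))
            if len(children) < n_children:
                children.append(_repair(c2, k, rng))
        n_mut = int(round(p.mutation_percentage * len(children)))
        for idx in rng.choice(len(children), size=n_mut, replace=False):
            children[idx] = _mutate_swap(children[idx], p.mutation_rate, rng)

        cand = pop + children
        cand_fit = np.concatenate([fit, [cache(np.flatnonzero(m)) for m in children]])
        # truncate to the best distinct individuals; duplicates would
        # otherwise take over and stall recombination
        order = np.argsort(-cand_fit, kind="stable")
        distinct, dupes, seen = [], [], set()
        for i in order:
            key = cand[i].tobytes()
            (distinct if key not in seen else dupes).append(i)
            seen.add(key)
        keep = (distinct + dupes)[: p.pop]
        pop = [cand[i] for i in keep]
        fit = cand_fit[keep]
        history.append(float(fit[0]))

    return _result("ga", cfg, k, pop[0], fit[0], history, cache, table)


def _infer_F(fitness_fn, k: int) -> int:
    raise ValueError("a feature table is required to determine F")


# ---------------------------------------------------------------------------
# NSGA-II


@dataclass
class Nsga2Result:
    """Final nondominated archive plus the best archived subset per cardinality."""

    archive: list[tuple[tuple[int, ...], float]]  # (indices, accuracy %)
    per_k: dict[int, SelectionResult]
    evaluations: int
    history: list[float]  # best accuracy in the population per generation


def _nondominated_sort(acc: np.ndarray, card: np.ndarray) -> list[np.ndarray]:
    """Fast nondominated sorting for (maximize acc, minimize card)."""
    n = acc.size
    dominates = [[] for _ in range(n)]
    dominated_by = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if (
                acc[i] >= acc[j]
                and card[i] <= card[j]
                and (acc[i] > acc[j] or card[i] < card[j])
            ):
                dominates[i].append(j)
    for i in range(n):
        for j in dominates[i]:
            dominated_by[j] += 1
    fronts = []
    current = np.flatnonzero(dominated_by == 0)
    while current.size:
        fronts.append(current)
        nxt = []
        for i in current:
            for j in dominates[i]:
                dominated_by[j] -= 1
                if dominated_by[j] == 0:
                    nxt.append(j)
        current = np.array(sorted(set(nxt)), dtype=int)
    return fronts


def _crowding(acc: np.ndarray, card: np.ndarray, front: np.ndarray) -> np.ndarray:
    dist = np.zeros(front.size)
    for obj in (acc[front], card[front].astype(float)):
        order = np.argsort(obj, kind="stable")
        span = obj[order[-1]] - obj[order[0]]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span > 0 and front.size > 2:
            for pos in range(1, front.size - 1):
                dist[order[pos]] += (obj[order[pos + 1]] - obj[order[pos - 1]]) / span
    return dist


def nsga2_select(
    table: FeatureTable | None,
    k_max: int,
    cfg: EaConfig | None = None,
    fitness_fn: Callable[[tuple[int, ...]], float] | None = None,
) -> Nsga2Result:
    """NSGA-II over subsets of free cardinality in [1, k_max].

    Objectives: maximize cross-validated accuracy, minimize cardinality.
    Survivor selection uses fast nondominated sorting with crowding-distance
    truncation; the returned archive is the final first front.
    """
    cfg = cfg or EaConfig()
    cache = _make_fitness(table, cfg, fitness_fn)
    F = table.n_features if table is not None else _infer_F(fitness_fn, k_max)
    if k_max > F:
        raise ValueError(f"k_max={k_max} exceeds F={F}")
    rng = np.random.default_rng(cfg.seed)
    p = cfg.nsga2

    def clamp(mask: np.ndarray) -> np.ndarray:
        size = int(mask.sum())
        if size == 0:
            mask = mask.copy()
            mask[rng.integers(F)] = True
        elif size > k_max:
            mask = _repair(mask, k_max, rng)
        return mask

    pop = [_random_mask(rng, F, int(rng.integers(1, k_max + 1))) for _ in range(p.pop)]
    acc = np.array([cache(np.flatnonzero(m)) for m in pop])
    card = np.array([int(m.sum()) for m in pop])
    history = [float(acc.max())]

    for _ in range(cfg.iterations):
        fronts = _nondominated_sort(acc, card)
        rank = np.empty(len(pop), dtype=int)
        crowd = np.empty(len(pop))
        for r, front in enumerate(fronts):
            rank[front] = r
            crowd[front] = _crowding(acc, card, front)

        def tournament() -> int:
            i, j = rng.integers(len(pop), size=2)
            if rank[i] != rank[j]:
                return i if rank[i] < rank[j] else j
            return i if crowd[i] >= crowd[j] else j

        children: list[np.ndarray] = []
        while len(children) < p.crossover_count:
            c1, c2 = _crossover(pop[tournament()], pop[tournament()], rng)
            children.append(clamp(c1))
            if len(children) < p.crossover_count:
                children.append(clamp(c2))
        n_mut = int(round(p.mutation_percentage * len(children)))
        for idx in rng.choice(len(children), size=n_mut, replace=False):
            children[idx] = _mutate_swap(children[idx], p.mutation_rate, rng)

        pop = pop + children
        acc = np.concatenate([acc, [cache(np.flatnonzero(m)) for m in children]])
        card = np.concatenate([card, [int(m.sum()) for m in children]])

        fronts = _nondominated_sort(acc, card)
        keep: list[int] = []
        for front in fronts:
            if len(keep) + front.size <= p.pop:
                keep.extend(front.tolist())
            else:
                dist = _crowding(acc, card, front)
                order = np.argsort(-dist, kind="stable")
                keep.extend(front[order][: p.pop - len(keep)].tolist())
                break
        pop = [pop[i] for i in keep]
        acc = acc[keep]
        card = card[keep]
        history.append(float(acc.max()))

    fronts = _nondominated_sort(acc, card)
    archive_idx = fronts[0]
    seen: dict[tuple[int, ...], float] = {}
    for i in archive_idx:
        key = tuple(int(v) for v in np.flatnonzero(pop[i]))
        seen.setdefault(key, float(acc[i]))
    archive = sorted(seen.items(), key=lambda kv: (len(kv[0]), kv[0]))

    per_k: dict[int, SelectionResult] = {}
    for indices, fitness in archive:
        kk = len(indices)
        if kk not in per_k or fitness > per_k[kk].best_fitness:
            mask = np.zeros(F, dtype=bool)
            mask[list(indices)] = True
            per_k[kk] = _result("nsga2", cfg, kk, mask, fitness, history, cache, table)
    return Nsga2Result(
        archive=archive, per_k=per_k, evaluations=cache.evaluations, history=[float(h) for h in history]
    )


# ---------------------------------------------------------------------------
# ant colony optimization


def aco_select(
    table: FeatureTable | None,
    k: int,
    cfg: EaConfig | None = None,
    fitness_fn: Callable[[tuple[int, ...]], float] | None = None,
    heuristic: np.ndarray | None = None,
) -> SelectionResult:
    """Ant colony optimization over k-subsets.

    Each ant samples k distinct features with probability proportional to
    tau^alpha * eta^beta, where tau is the pheromone level and eta the
    per-feature heuristic (|Welch t| between groups by default).  After each
    iteration pheromone evaporates and the iteration-best ant deposits
    pheromone proportional to its fitness on its features.
    """
    cfg = cfg or EaConfig()
    cache = _make_fitness(table, cfg, fitness_fn)
    F = table.n_features if table is not None else _infer_F(fitness_fn, k)
    if k > F:
        raise ValueError(f"k={k} exceeds F={F}")
    rng = np.random.default_rng(cfg.seed)
    p = cfg.aco

    if heuristic is None:
        if isinstance(table, FeatureTable):
            tvals, _ = welch_t_statistics(table)
            heuristic = np.abs(tvals)
        else:
            heuristic = np.ones(F)
    eta = np.asarray(heuristic, dtype=float) + 1e-12
    tau = np.full(F, float(p.initial_weight))

    best_mask: np.ndarray | None = None
    best_fit = -np.inf
    history: list[float] = []
    for _ in range(max(cfg.iterations, 1)):
        iter_best_mask = None
        iter_best_fit = -np.inf
        for _ant in range(p.n_ants):
            weights = (tau**p.exponential_weight) * (eta**p.heuristic_weight)
            mask = np.zeros(F, dtype=bool)
            w = weights.copy()
            for _step in range(k):
                probs = w / w.sum()
                choice = rng.choice(F, p=probs)
                mask[choice] = True
                w[choice] = 0.0
            f = cache(np.flatnonzero(mask))
            if f > iter_best_fit:
                iter_best_fit, iter_best_mask = f, mask
        tau *= 1.0 - p.evaporation
        tau[iter_best_mask] += iter_best_fit / 100.0
        if iter_best_fit > best_fit:
            best_fit, best_mask = iter_best_fit, iter_best_mask
        history.append(float(best_fit))

    res = _result("aco", cfg, k, best_mask, best_fit, history, cache, table)
    res.config["pheromone"] = tau.tolist()
    return res


# ---------------------------------------------------------------------------
# simulated annealing


def sa_select(
    table: FeatureTable | None,
    k: int,
    cfg: EaConfig | None = None,
    fitness_fn: Callable[[tuple[int, ...]], float] | None = None,
) -> SelectionResult:
    """Simulated annealing on the swap neighbourhood of k-subsets.

    A neighbour exchanges one selected feature for one unselected feature;
    improving moves are always accepted, worsening moves with probability
    exp(-delta / T), and T decays geometrically from t0.  At T = 0 the
    procedure degenerates to a pure hill-climb.
    """
    cfg = cfg or EaConfig()
    cache = _make_fitness(table, cfg, fitness_fn)
    F = table.n_features if table is not None else _infer_F(fitness_fn, k)
    if k > F:
        raise ValueError(f"k={k} exceeds F={F}")
    rng = np.random.default_rng(cfg.seed)
    p = cfg.sa

    current = _random_mask(rng, F, k)
    f_cur = cache(np.flatnonzero(current))
    best, f_best = current, f_cur
    T = p.t0
    history = [float(f_best)]
    for _ in range(cfg.iterations):
        if k < F:
            neighbour = current.copy()
            out = rng.choice(np.flatnonzero(current))
            inn = rng.choice(np.flatnonzero(~current))
            neighbour[out], neighbour[inn] = False, True
            f_new = cache(np.flatnonzero(neighbour))
            delta = f_cur - f_new
            if delta < 0 or (T > 0 and rng.random() < np.exp(-delta / T)):
                current, f_cur = neighbour, f_new
            if f_cur > f_best:
                best, f_best = current, f_cur
        T *= p.cooling
        history.append(float(f_best))
    return _result("sa", cfg, k, best, f_best, history, cache, table)


# ---------------------------------------------------------------------------
# particle swarm optimization


def pso_select(
    table: FeatureTable | None,
    k: int,
    cfg: EaConfig | None = None,
    fitness_fn: Callable[[tuple[int, ...]], float] | None = None,
) -> SelectionResult:
    """Particle swarm optimization with rank-based subset decoding.

    Particles carry a continuous position over all F features; a particle's
    subset is the k features with the largest position values (ties broken
    by lower index).  Velocities follow the standard inertia + cognitive +
    social update; personal and global bests are tracked on decoded fitness.
    """
    cfg = cfg or EaConfig()
    cache = _make_fitness(table, cfg, fitness_fn)
    F = table.n_features if table is not None else _infer_F(fitness_fn, k)
    if k > F:
        raise ValueError(f"k={k} exceeds F={F}")
    rng = np.random.default_rng(cfg.seed)
    p = cfg.pso

    def decode(pos: np.ndarray) -> np.ndarray:
        idx = np.argsort(-pos, kind="stable")[:k]
        mask = np.zeros(F, dtype=bool)
        mask[idx] = True
        return mask

    X = rng.uniform(0, 1, size=(p.swarm, F))
    V = np.zeros((p.swarm, F))
    pbest_x = X.copy()
    pbest_f = np.array([cache(np.flatnonzero(decode(x))) for x in X])
    g = int(np.argmax(pbest_f))
    gbest_x, gbest_f = pbest_x[g].copy(), float(pbest_f[g])
    gbest_mask = decode(gbest_x)
    history = [gbest_f]

    for _ in range(cfg.iterations):
        r1 = rng.uniform(size=(p.swarm, F))
        r2 = rng.uniform(size=(p.swarm, F))
        V = p.inertia * V + p.c1 * r1 * (pbest_x - X) + p.c2 * r2 * (gbest_x - X)
        X = X + V
        for i in range(p.swarm):
            f = cache(np.flatnonzero(decode(X[i])))
            if f > pbest_f[i]:
                pbest_f[i] = f
                pbest_x[i] = X[i].copy()
            if f > gbest_f:
                gbest_f = float(f)
                gbest_x = X[i].copy()
                gbest_mask = decode(X[i])
        history.append(gbest_f)
    return _result("pso", cfg, k, gbest_mask, gbest_f, history, cache, table)


# ---------------------------------------------------------------------------
# statistical baseline


def welch_t_statistics(table: FeatureTable) -> tuple[np.ndarray, np.ndarray]:
    """Welch two-sample t statistic and p-value for every feature column.

    Features with zero variance in both groups get t = 0, p = 1.
    """
    g0 = table.data[table.labels == 0]
    g1 = table.data[table.labels == 1]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("both groups need at least 2 subjects")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, pvals = stats.ttest_ind(g0, g1, axis=0, equal_var=False)
    t = np.asarray(t, dtype=float)
    pvals = np.asarray(pvals, dtype=float)
    # zero variance in both groups: no evidence either way
    nan_t = np.isnan(t)
    t[nan_t] = 0.0
    pvals[nan_t] = 1.0
    # zero variance but different means: perfectly separated
    inf_t = np.isinf(t)
    t[inf_t] = np.sign(t[inf_t]) * 1e6
    pvals[inf_t] = 0.0
    pvals[np.isnan(pvals)] = 1.0
    return t, pvals


def ttest_select(table: FeatureTable, k: int) -> tuple[FeatureSubset, np.ndarray]:
    """Filter baseline: the k features with the smallest Welch p-values.

    Ties are broken by lower index; features with zero variance in both
    groups are forced to rank last.
    """
    if k > table.n_features:
        raise ValueError(f"k={k} exceeds F={table.n_features}")
    t, pvals = welch_t_statistics(table)
    g0 = table.data[table.labels == 0]
    g1 = table.data[table.labels == 1]
    degenerate = (g0.std(axis=0) == 0) & (g1.std(axis=0) == 0)
    order = np.lexsort((np.arange(table.n_features), degenerate.astype(int), pvals))
    return FeatureSubset(tuple(int(i) for i in order[:k])), pvals


def stat_select(
    table: FeatureTable, k: int, cfg: EaConfig | None = None
) -> SelectionResult:
    """t-test ranking wrapped as a SelectionResult (fitness evaluated once)."""
    cfg = cfg or EaConfig()
    subset, _ = ttest_select(table, k)
    f = evaluate_fitness(subset, table, cfg.fitness)
    mask = np.zeros(table.n_features, dtype=bool)
    mask[list(subset.indices)] = True
    cache = FitnessCache(lambda idx: f)
    cache.misses = 1
    return _result("stat", cfg, k, mask, f, [f], cache, table)
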