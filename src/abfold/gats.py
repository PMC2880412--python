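"""Hybrid genetic / tabu-search optimizer for AB-model folding.

The search maintains an energy-sorted population of angle-vector
conformations and alternates two phases each generation:

* **TSR** (tabu-search recombination): parents drawn from the worst 90%
  of the population are crossed (by default with the incumbent best
  conformation) via a random linear combination pulled toward the best;
  offspring are screened against the population-mean energy (the
  "desired level") and a FIFO list of recently accepted fitness values.

* **TSM** (tabu-search mutation): a few parents, chosen by linear
  ranking, each undergo a tabu-guided neighborhood search.  Neighbors
  are annealed disturbances of the current solution (two parameters
  early in the run, one late); the lowest-energy non-tabu candidate is
  accepted even if it is uphill, which gives the operator its
  hill-climbing power.  A candidate beating the global best is always
  accepted (aspiration).  If every candidate is tabu ("total tabu") the
  search escapes by disturbing the global best.

The population grows with fresh random individuals when the best and
mean energies converge, and shrinks when they spread, within configured
bounds.  The incumbent best individual is never crossed over or mutated
in place, so the best energy is non-increasing across generations.

Budgeted runs are organised as a few short exploration epochs followed
by a refinement epoch anchored at the best conformation found and a
final greedy polish; see :func:`gats_run`.
"""

from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .energy import EnergyModel
from .geometry import DEFAULT_CONVENTION, Conformation, GeometryConvention, wrap_angle
from .sequences import ABSequence

__all__ = [
    "GATSConfig",
    "Individual",
    "Population",
    "TabuState",
    "RunResult",
    "initialize_population",
    "ranking_select",
    "adjust_population_size",
    "disturb",
    "is_tabu",
    "tsm_step",
    "handle_total_tabu",
    "tsr_crossover",
    "tsr_accept",
    "select_crossover_pairs",
    "gats_run",
]


# ---------------------------------------------------------------------------
# configuration

_RANGES = {
    "pop_min": (100, 500),
    "pop_max": (100, 500),
    "crossover_rate": (0.88, 0.88),
    "mutation_rate": (0.012, 0.025),
    "tabu_min": (7, 14),
    "tabu_max": (7, 14),
    "neighborhood_size": (30, 50),
    "candidate_size": (5, 6),
}


@dataclass(frozen=True)
class GATSConfig:
    """Run configuration.

    The population bounds, crossover rate, mutation rate, tabu-list
    length bounds, neighborhood size and candidate-set size default to
    the published experimental settings; values outside those ranges
    are rejected unless ``allow_out_of_range`` is set (with a warning).
    The remaining knobs (stopping, thresholds, scale factor) are this
    package's design choices, documented in the methods note.
    """

    pop_min: int = 100
    pop_max: int = 500
    crossover_rate: float = 0.88
    mutation_rate: float = 0.025
    tabu_min: int = 7
    tabu_max: int = 14
    neighborhood_size: int = 30
    candidate_size: int = 5
    max_generations: int = 500
    stagnation_limit: int = 100
    max_evaluations: int | None = None
    tsm_iterations: int = 80
    psi: float | None = None  # None: adaptive 0.01*|E_current| + 1e-6
    eta: float | None = None  # None: 0.1 * sqrt(2n - 5)
    lambda_scale: float = math.pi
    disturb_shape: float = 1.0
    pop_delta: float = 0.01
    selection_pressure: float = 2.0
    explore_epochs: int = 3
    explore_frac: float = 0.5
    refine_alpha_floor: float = 0.0
    polish_frac: float = 0.1
    cross_with_best: bool = True
    rng_seed: int | None = None
    allow_out_of_range: bool = False

    def __post_init__(self):
        for name, (lo, hi) in _RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                if self.allow_out_of_range:
                    warnings.warn(
                        f"GATSConfig.{name}={v} is outside the benchmark range [{lo}, {hi}]",
                        stacklevel=2,
                    )
                else:
                    raise ValueError(
                        f"GATSConfig.{name}={v} outside [{lo}, {hi}]; "
                        "pass allow_out_of_range=True to override"
                    )
        if self.pop_min > self.pop_max or self.tabu_min > self.tabu_max:
            raise ValueError("lower bounds must not exceed upper bounds")
        if not 0.0 < self.crossover_rate <= 1.0:
            raise ValueError("crossover_rate must be in (0, 1]")
        if not 1.0 <= self.selection_pressure <= 2.0:
            raise ValueError("selection_pressure must be in [1, 2]")
        if self.explore_epochs < 1:
            raise ValueError("explore_epochs must be >= 1")
        if not 0.0 < self.explore_frac < 1.0:
            raise ValueError("explore_frac must be in (0, 1)")
        if not 0.0 <= self.polish_frac < 0.5:
            raise ValueError("polish_frac must be in [0, 0.5)")


# ---------------------------------------------------------------------------
# population machinery


@dataclass(frozen=True, eq=False)
class Individual:
    """A conformation with its cached energy."""

    conf: Conformation
    energy: float

    @property
    def vector(self) -> np.ndarray:
        return self.conf.vector


class Population:
    """Energy-sorted collection of individuals with size bounds."""

    def __init__(self, members: list[Individual], pop_min: int, pop_max: int):
        self.members = sorted(members, key=lambda m: m.energy)
        self.pop_min = pop_min
        self.pop_max = pop_max

    def __len__(self) -> int:
        return len(self.members)

    def __getitem__(self, i) -> Individual:
        return self.members[i]

    def sort(self) -> None:
        self.members.sort(key=lambda m: m.energy)

    @property
    def best(self) -> Individual:
        return self.members[0]

    def mean_energy(self) -> float:
        e = np.array([m.energy for m in self.members])
        finite = e[np.isfinite(e)]
        return float(finite.mean()) if len(finite) else float("inf")


def _random_individual(n: int, model: EnergyModel, rng: np.random.Generator) -> Individual:
    conf = Conformation.random(n, rng)
    return Individual(conf, model(conf))


def initialize_population(
    seq: ABSequence, config: GATSConfig, rng: np.random.Generator, model: EnergyModel | None = None
) -> Population:
    """``pop_min`` random individuals, angles uniform on (-pi, pi], sorted."""
    model = model or EnergyModel(seq)
    n = len(seq)
    members = [_random_individual(n, model, rng) for _ in range(config.pop_min)]
    return Population(members, config.pop_min, config.pop_max)


def _rank_weights(size: int, pressure: float) -> np.ndarray:
    # linear ranking: weight `pressure` for the best, 2 - pressure for the worst
    if size == 1:
        return np.ones(1)
    ranks = np.arange(size)
    w = pressure - (2.0 * pressure - 2.0) * ranks / (size - 1)
    return w / w.sum()


def ranking_select(
    pop: Population | list[Individual],
    count: int,
    rng: np.random.Generator,
    pressure: float = 1.8,
) -> list[Individual]:
    """Sample ``count`` individuals (without replacement) by linear rank weight.

    The best rank gets weight ``pressure`` (1.8 by default) and the worst
    ``2 - pressure``, linearly interpolated, so selection favours low
    energies without ever starving the tail.
    """
    members = pop.members if isinstance(pop, Population) else list(pop)
    if not 1 <= count <= len(members):
        raise ValueError(f"count must be in [1, {len(members)}], got {count}")
    p = _rank_weights(len(members), pressure)
    idx = rng.choice(len(members), size=count, replace=False, p=p)
    return [members[i] for i in idx]


def adjust_population_size(
    pop: Population,
    config: GATSConfig,
    rng: np.random.Generator,
    model: EnergyModel,
) -> Population:
    """Grow on convergence, shrink on spread, within [pop_min, pop_max].

    If the best energy is within a relative ``pop_delta`` of the mean the
    population has converged: add 10% fresh random individuals (clamped
    at ``pop_max``).  If best and mean differ by more than twice that,
    drop the worst 10% (never below ``pop_min``).
    """
    e_min, e_mean = pop.best.energy, pop.mean_energy()
    scale = max(abs(e_mean), 1e-12)
    gap = abs(e_min - e_mean)
    size = len(pop)
    if gap < config.pop_delta * scale:
        target = min(config.pop_max, size + max(1, size // 10))
        n = pop.best.conf.n
        pop.members.extend(_random_individual(n, model, rng) for _ in range(target - size))
        pop.sort()
    elif gap > 2.0 * config.pop_delta * scale and size > config.pop_min:
        target = max(config.pop_min, size - max(1, size // 10))
        del pop.members[target:]
    return pop


# ---------------------------------------------------------------------------
# tabu machinery


class TabuState:
    """Paired FIFO lists of recent solutions and their energies.

    The list length self-adjusts between ``min_len`` and ``max_len``:
    it grows by one whenever a total-tabu event occurs (memory was too
    short to be discriminating) and shrinks by one after 50 consecutive
    event-free additions.
    """

    RELAX_AFTER = 50

    def __init__(self, min_len: int = 7, max_len: int = 14):
        if min_len > max_len:
            raise ValueError("min_len must not exceed max_len")
        self.min_len = min_len
        self.max_len = max_len
        self.bound = min_len
        self.solutions: deque[np.ndarray] = deque()
        self.energies: deque[float] = deque()
        self.total_tabu_events = 0
        self._event_free = 0

    def __len__(self) -> int:
        return len(self.solutions)

    def add(self, vector: np.ndarray, energy: float) -> None:
        self.solutions.append(np.array(vector, copy=True))
        self.energies.append(float(energy))
        while len(self.solutions) > self.bound:
            self.solutions.popleft()
            self.energies.popleft()
        self._event_free += 1
        if self._event_free >= self.RELAX_AFTER:
            self.bound = max(self.min_len, self.bound - 1)
            self._event_free = 0

    def on_total_tabu(self) -> None:
        self.total_tabu_events += 1
        self._event_free = 0
        self.bound = min(self.max_len, self.bound + 1)


def _wrapped_distance(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.linalg.norm(wrap_angle(x - y)))


def is_tabu(candidate: Individual, tabu: TabuState, psi: float, eta: float) -> bool:
    """True iff some stored solution is close in BOTH energy and angle space.

    The criterion is a conjunction: |E(y) - E(h)| <= psi AND
    ||y - h|| <= eta, with the norm taken over wrapped angle
    differences.  An empty list is never tabu.
    """
    e = candidate.energy
    for y, ey in zip(tabu.solutions, tabu.energies):
        if abs(ey - e) <= psi and _wrapped_distance(y, candidate.vector) <= eta:
            return True
    return False


# ---------------------------------------------------------------------------
# mutation (TSM)


def disturb(
    conf: Conformation,
    j: int,
    alpha: float,
    lambda_j: float,
    rng: np.random.Generator,
    shape: float = 1.0,
) -> Conformation:
    """Annealed single-parameter disturbance.

    Parameter ``j`` of the flattened angle vector is shifted by
    ``s * lambda_j * (1 - r**((1 - alpha)**shape))`` with random sign
    ``s`` and ``r ~ U(0, 1)``: at the start of a run (alpha = 0) shifts
    are uniform on (0, lambda_j); as alpha -> 1 they vanish, so the
    search anneals from exploration to refinement.  ``shape`` controls
    how early the move distribution tightens (1 = linear annealing;
    larger values concentrate refinement earlier in the run).
    """
    x = conf.vector
    if not 0 <= j < len(x):
        raise IndexError(f"parameter index {j} out of range for {len(x)} parameters")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    r = rng.uniform(0.0, 1.0)
    s = 1.0 if rng.uniform(0.0, 1.0) < 0.5 else -1.0
    x = x.copy()
    x[j] += s * lambda_j * (1.0 - r ** ((1.0 - alpha) ** shape))
    return Conformation.from_vector(wrap_angle(x), conf.n)


def _neighbor(conf: Conformation, alpha: float, config: GATSConfig, rng: np.random.Generator) -> Conformation:
    """Two-point disturbance early in the search, single-point late.

    The two disturbed parameters are a matched (theta, beta) pair, i.e.
    the two angles steering one bond direction, so an early move
    reorients one bond — rigidly translating the downstream segment —
    rather than shearing two unrelated coordinates.  Chains too short to
    have a torsion fall back to single-point moves.
    """
    n = conf.n
    dim = 2 * n - 5
    if alpha < 0.5 and n > 3:
        t = int(rng.integers(1, n - 2))  # theta index of a bond that also has a torsion
        indices = (t, (n - 3) + t)
    else:
        indices = (int(rng.integers(dim)),)
    for j in indices:
        conf = disturb(conf, j, alpha, config.lambda_scale, rng, config.disturb_shape)
    return conf


def _psi(config: GATSConfig, current_energy: float) -> float:
    if config.psi is not None:
        return config.psi
    ref = abs(current_energy) if math.isfinite(current_energy) else 1.0
    return 0.01 * ref + 1e-6


def _eta(config: GATSConfig, n: int) -> float:
    return config.eta if config.eta is not None else 0.1 * math.sqrt(2 * n - 5)


def handle_total_tabu(
    tabu: TabuState,
    best: Individual,
    alpha: float,
    config: GATSConfig,
    rng: np.random.Generator,
    model: EnergyModel,
) -> Individual:
    """Escape a fully-forbidden candidate set by disturbing the global best."""
    tabu.on_total_tabu()
    conf = _neighbor(best.conf, alpha, config, rng)
    return Individual(conf, model(conf))


def tsm_step(
    current: Individual,
    tabu: TabuState,
    best: Individual,
    alpha: float,
    config: GATSConfig,
    rng: np.random.Generator,
    model: EnergyModel,
) -> tuple[Individual, TabuState]:
    """One tabu-guided neighborhood move from ``current``.

    Generates ``neighborhood_size`` disturbed copies, keeps the
    ``candidate_size`` lowest-energy ones, and returns the first
    candidate that is not tabu — accepting uphill moves, which is what
    lets the operator climb out of local minima.  A candidate below the
    global best energy is accepted regardless of tabu status
    (aspiration).  If all candidates are forbidden, the move restarts
    from a disturbance of the global best.
    """
    neighbors = []
    for _ in range(config.neighborhood_size):
        conf = _neighbor(current.conf, alpha, config, rng)
        neighbors.append(Individual(conf, model(conf)))
    neighbors.sort(key=lambda m: m.energy)
    candidates = neighbors[: config.candidate_size]

    psi = _psi(config, current.energy)
    eta = _eta(config, current.conf.n)
    accepted = None
    for cand in candidates:
        if cand.energy < best.energy:  # aspiration
            accepted = cand
            break
        if not is_tabu(cand, tabu, psi, eta):
            accepted = cand
            break
    if accepted is None:
        accepted = handle_total_tabu(tabu, best, alpha, config, rng, model)
    tabu.add(accepted.vector, accepted.energy)
    return accepted, tabu


# ---------------------------------------------------------------------------
# recombination (TSR)


def tsr_crossover(
    parent_a: Individual,
    parent_b: Individual,
    best: Individual,
    rng: np.random.Generator,
) -> Conformation:
    """Random linear combination of the parents, pulled toward the best.

    c = r1*a + (1 - r1)*b, then c' = c + r2*(best - c), with r1 and r2
    each drawn once per crossover.  Every unwrapped component of c' lies
    in the interval hull of the corresponding parent/best components.
    """
    a, b = parent_a.vector, parent_b.vector
    if len(a) != len(b) or len(a) != len(best.vector):
        raise ValueError("crossover requires equal-length angle vectors")
    r1 = rng.uniform(0.0, 1.0)
    r2 = rng.uniform(0.0, 1.0)
    c = r1 * a + (1.0 - r1) * b
    c = c + r2 * (best.vector - c)
    return Conformation.from_vector(wrap_angle(c), parent_a.conf.n)


def tsr_accept(
    offspring: Individual,
    parents: tuple[Individual, Individual],
    pop_mean_energy: float,
    fitness_tabu: deque,
    psi: float,
) -> Individual:
    """Screen a crossover offspring against the desired level and fitness tabu.

    Below the population mean: accepted outright.  Above the mean but
    not within ``psi`` of any recently accepted fitness value: accepted
    (the list is still diverse).  Otherwise the better parent survives.
    Accepted energies are appended to the FIFO fitness-tabu list.
    """
    e = offspring.energy
    if e < pop_mean_energy or not any(abs(e - t) <= psi for t in fitness_tabu):
        fitness_tabu.append(e)
        return offspring
    return min(parents, key=lambda m: m.energy)


def select_crossover_pairs(
    pop: Population,
    rate: float,
    rng: np.random.Generator,
    cross_with_best: bool = True,
    return_indices: bool = False,
):
    """Draw crossover parents from the worst 90% of a sorted population.

    ``ceil(rate * |pop|)`` parents are sampled (without replacement when
    possible) from below the top decile — the top 10% are treated as
    near-duplicates of the best and left alone.  In the default mode
    each parent is paired with the incumbent best individual; otherwise
    parents are paired among themselves, greedily matching the most
    distant angle vectors to avoid close matings.
    """
    if not 0.0 < rate <= 1.0:
        raise ValueError(f"crossover rate must be in (0, 1], got {rate}")
    size = len(pop)
    elite = max(1, math.ceil(0.1 * size))
    pool = np.arange(elite, size)
    count = math.ceil(rate * size)
    if count <= len(pool):
        chosen = rng.choice(pool, size=count, replace=False)
    else:
        chosen = rng.choice(pool, size=count, replace=True)
    chosen = [int(i) for i in chosen]
    if cross_with_best:
        pairs = [(i, 0) for i in chosen]
    else:
        pairs = []
        remaining = list(chosen)
        while len(remaining) >= 2:
            i = remaining.pop(0)
            vi = pop[i].vector
            dists = [_wrapped_distance(vi, pop[j].vector) for j in remaining]
            k = int(np.argmax(dists))
            pairs.append((i, remaining.pop(k)))
    if return_indices:
        return pairs
    return [(pop[i], pop[j]) for i, j in pairs]


# ---------------------------------------------------------------------------
# main loop


@dataclass(frozen=True, eq=False)
class RunResult:
    """Outcome of one optimizer run."""

    best_conf: Conformation
    best_energy: float
    trajectory: list  # per generation: dict with best/mean energy, sizes, tabu stats
    evaluations: int
    seed: int | None
    sequence: str
    config: GATSConfig = field(repr=False, default=None)

    @property
    def best_series(self) -> np.ndarray:
        return np.array([g["e_min"] for g in self.trajectory])


class _GlobalBest:
    """Tracks the best individual seen anywhere in a run (h_min, E_min)."""

    def __init__(self):
        self.individual: Individual | None = None

    def offer(self, ind: Individual) -> None:
        if self.individual is None or ind.energy < self.individual.energy:
            self.individual = ind

    @property
    def energy(self) -> float:
        return self.individual.energy if self.individual else float("inf")


def _run_epoch(
    seq: ABSequence,
    config: GATSConfig,
    rng: np.random.Generator,
    model: EnergyModel,
    epoch_budget: int | None,
    max_generations: int,
    gen_offset: int,
    seed_individuals: list[Individual],
    tracker: _GlobalBest,
    trajectory: list[dict],
    log,
    alpha_floor: float = 0.0,
) -> int:
    """One self-contained GATS search epoch; returns generations consumed.

    The epoch starts from a fresh random population (plus any
    ``seed_individuals``, which anchor a refinement epoch at the
    incumbent best), with fresh tabu memory and its own annealing
    schedule, and ends on its evaluation share, a generation cap, or
    stagnation.
    """
    pop = initialize_population(seq, config, rng, model)
    for ind in seed_individuals:
        pop.members.append(ind)
    pop.sort()
    best = pop.best  # epoch-local incumbent used by the operators
    tracker.offer(best)
    tabu = TabuState(config.tabu_min, config.tabu_max)
    fitness_tabu: deque = deque(maxlen=config.tabu_max)
    stagnation = 0
    epoch_start = model.evaluations

    def out_of_budget() -> bool:
        return epoch_budget is not None and model.evaluations - epoch_start >= epoch_budget

    for local_gen in range(1, max_generations + 1):
        gen = gen_offset + local_gen
        e_min_at_start = best.energy
        alpha = local_gen / max_generations
        if epoch_budget is not None:
            alpha = max(alpha, min(1.0, (model.evaluations - epoch_start) / epoch_budget))
        alpha = alpha_floor + (1.0 - alpha_floor) * alpha

        # --- TSR phase ---
        mean_e = pop.mean_energy()
        psi = _psi(config, best.energy)
        pairs = select_crossover_pairs(
            pop, config.crossover_rate, rng, config.cross_with_best, return_indices=True
        )
        for i, j in pairs:
            if out_of_budget():
                break
            child_conf = tsr_crossover(pop[i], pop[j], best, rng)
            child = Individual(child_conf, model(child_conf))
            pop.members[i] = tsr_accept(child, (pop[i], pop[j]), mean_e, fitness_tabu, psi)
        pop.sort()

        # --- TSM phase ---
        k = max(1, round(config.mutation_rate * len(pop)))
        candidates_pool = pop.members[1:]  # never mutate the incumbent best in place
        chosen = ranking_select(candidates_pool, min(k, len(candidates_pool)), rng,
                                config.selection_pressure)
        chosen_ids = {id(m) for m in chosen}
        for idx in range(1, len(pop)):
            if id(pop.members[idx]) not in chosen_ids:
                continue
            current = pop.members[idx]
            for it in range(config.tsm_iterations):
                if out_of_budget():
                    break
                # each TSM chain anneals from the epoch-level progress down to
                # fine moves, so refinement happens throughout the epoch
                chain_alpha = max(alpha, it / max(1, config.tsm_iterations))
                current, tabu = tsm_step(
                    current, tabu, best, chain_alpha, config, rng, model
                )
                if current.energy < best.energy:
                    best = current
            pop.members[idx] = current
        pop.sort()

        if pop.best.energy < best.energy:
            best = pop.best
        # keep the epoch incumbent physically present in the population
        if pop.best.energy > best.energy:
            pop.members[0] = best
            pop.sort()

        pop = adjust_population_size(pop, config, rng, model)
        if pop.best.energy < best.energy:
            best = pop.best
        tracker.offer(best)
        if best.energy < e_min_at_start:
            stagnation = 0
        else:
            stagnation += 1

        record = {
            "generation": gen,
            "pop_size": len(pop),
            "e_min": tracker.energy,
            "e_epoch": best.energy,
            "e_mean": pop.mean_energy(),
            "tabu_len": len(tabu),
            "tabu_bound": tabu.bound,
            "total_tabu_events": tabu.total_tabu_events,
            "evaluations": model.evaluations,
        }
        trajectory.append(record)
        if log is not None:
            log(record)

        if out_of_budget() or stagnation >= config.stagnation_limit:
            return local_gen
    return max_generations


def _polish(
    start: Individual,
    budget: int,
    config: GATSConfig,
    rng: np.random.Generator,
    model: EnergyModel,
) -> Individual:
    """Greedy annealed coordinate descent from the incumbent best.

    The end-game of a run: single-parameter (or matched theta/beta pair)
    Gaussian steps with a scale annealing geometrically from 0.2 to
    0.002 rad, accepting only strict improvements.  TSM chains keep
    hill-climbing power until the end, which is what the search needs,
    but it also means they never settle into the bottom of the final
    basin; this stage recovers that remaining depth at one evaluation
    per move.
    """
    n = start.conf.n
    dim = 2 * n - 5
    x, e = start.vector.copy(), start.energy
    spent = 0
    while spent < budget:
        a = spent / budget
        scale = 0.2 * (0.002 / 0.2) ** a
        if rng.uniform() < 0.3 and n > 3:
            t = int(rng.integers(1, n - 2))
            idx = np.array([t, (n - 3) + t])
        else:
            idx = rng.integers(dim, size=1)
        y = x.copy()
        y[idx] = wrap_angle(y[idx] + scale * rng.standard_normal(len(idx)))
        ey = model.energy_of_arrays(y[: n - 2], y[n - 2:])
        spent += 1
        if ey < e:
            x, e = y, ey
    return Individual(Conformation.from_vector(x, n), e)


def gats_run(
    seq: ABSequence | str,
    config: GATSConfig | None = None,
    convention: GeometryConvention = DEFAULT_CONVENTION,
    log=None,
) -> RunResult:
    """Run the hybrid genetic / tabu search on one AB sequence.

    When an evaluation budget is set, the run is organised as
    ``explore_epochs`` short self-contained search epochs followed by a
    long refinement epoch whose population is seeded with the best
    conformation found so far: the exploration epochs draw independent
    candidate basins, the refinement epoch commits the remaining budget
    to the most promising one.  Without a budget (or with
    ``explore_epochs=1``) the whole run is a single epoch.

    Each epoch generation applies TSR to parents from the worst 90% of
    the population, then TSM chains to a few rank-selected parents,
    resorts, tracks the incumbent best, and adjusts the population size.
    Epochs end on their evaluation share, ``stagnation_limit``
    generations without improvement, or ``max_generations``; budget
    checks happen between operator applications, so the budget may be
    exceeded by at most one neighborhood batch.

    ``log``, if given, is called with one dict per generation.
    """
    if isinstance(seq, str):
        seq = ABSequence(seq)
    config = config or GATSConfig()
    rng = np.random.default_rng(config.rng_seed)
    model = EnergyModel(seq, convention)

    tracker = _GlobalBest()
    trajectory: list[dict] = []
    budget = config.max_evaluations
    epochs = config.explore_epochs

    if budget is None:
        _run_epoch(seq, config, rng, model, None, config.max_generations, 0,
                   [], tracker, trajectory, log)
    else:
        polish_budget = int(config.polish_frac * budget)
        search_budget = budget - polish_budget
        gens = 0
        if epochs > 1:
            explore_share = int(config.explore_frac * search_budget / epochs)
            for _ in range(epochs):
                if model.evaluations >= search_budget:
                    break
                share = min(explore_share, search_budget - model.evaluations)
                gens += _run_epoch(seq, config, rng, model, share, config.max_generations,
                                   gens, [], tracker, trajectory, log)
        if model.evaluations < search_budget:
            seeds = [tracker.individual] if tracker.individual is not None else []
            _run_epoch(seq, config, rng, model, search_budget - model.evaluations,
                       config.max_generations, gens, seeds,
                       tracker, trajectory, log,
                       alpha_floor=config.refine_alpha_floor)
        if polish_budget > 0:
            tracker.offer(_polish(tracker.individual, polish_budget, config, rng, model))

    best = tracker.individual
    return RunResult(
        best_conf=best.conf,
        best_energy=best.energy,
        trajectory=trajectory,
        evaluations=model.evaluations,
        seed=config.rng_seed,
        sequence=str(seq),
        config=config,
    )
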