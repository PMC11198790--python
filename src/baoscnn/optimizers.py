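"""Atomic Orbital Search (AOS), its Lévy-boosted variant (BAOS), and a
budget-matched random-search baseline.

AOS treats each candidate solution as an *electron* with an objective value
("energy", lower is better) orbiting a nucleus.  Every iteration the
population is sorted by energy and partitioned into a random number of
imaginary concentric *layers*; each layer has a binding state ``BS_k``
(position centroid) and binding energy ``BE_k`` (mean energy), and the
population has global ``BS``/``BE`` and a best-so-far candidate ``LE``.
Per electron a uniform draw ``phi`` against its photon rate ``PR`` decides
between a photon-interaction move (a pull towards ``LE``/``BS`` at global
or layer scale, depending on whether the electron is below its layer's
binding energy) and a small uniform random walk.  Moves are boundary
repaired and accepted greedily; consecutive rejections increment a
per-electron limit counter.

BAOS adds two Lévy-flight ingredients: the photon rate itself is re-drawn
each iteration from a scaled absolute Lévy step (so interaction likelihood
fluctuates heavy-tailedly around the canonical 0.1), and any electron whose
limit counter exceeds a threshold is relocated by a Lévy jump from the
best-so-far position — a stagnation restart that supplies the rare long
jumps behind the variant's improved global search.

The restart jump scale is landscape-adaptive.  On smooth landscapes the
jump is scaled by the electron's distance from the best-so-far (floored at
0.001 span), so restarts are global early and anneal into local refinement
as the population converges.  An exact energy tie between an electron and
its rejected proposal is evidence of a plateau (e.g. the piecewise-constant
landscape a discrete space induces on its continuous embedding, where
within-cell refinement is pointless); once an electron has seen a tie since
its last strict improvement, it restarts immediately with a full-span Lévy
jump, folded into the bounds by reflection so long jumps do not pile up on
the boundary.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
from scipy.stats import norm

from baoscnn.levy import LevyConfig, levy_displacement, levy_move, sample_steps
from baoscnn.search_space import SearchSpace

__all__ = [
    "ObjectiveError",
    "Electron",
    "Population",
    "LayerAssignment",
    "BindingRecord",
    "OptimizerParams",
    "OptimizationResult",
    "initialize",
    "evaluate",
    "assign_layers",
    "binding",
    "aos_step",
    "baos_step",
    "optimize",
    "random_search",
]

# Canonical AOS photon-interaction rate; also the target median of the
# Lévy-modulated photon-rate updates in BAOS.
DEFAULT_PHOTON_RATE = 0.1

# Fraction of the dimension span bounding the non-photon uniform walk.
_WALK_FRACTION = 0.05

# Restart-jump scales (in dimension spans): floor of the distance-annealed
# scale on smooth landscapes, and the full-span scale used once a plateau
# (an exact energy tie) has been detected.
_RESTART_FLOOR = 1e-3
_PLATEAU_SCALE = 4.0


class ObjectiveError(RuntimeError):
    """Raised when an objective returns a non-finite value."""

    def __init__(self, value: float, position: np.ndarray):
        super().__init__(f"objective returned non-finite value {value!r}")
        self.value = value
        self.position = np.asarray(position)


@dataclass
class Electron:
    """One candidate: a position in the space embedding plus its bookkeeping.

    ``ties`` counts exact energy ties with rejected proposals since the
    last strict improvement — the plateau signal driving restart policy.
    """

    position: np.ndarray
    energy: float | None = None
    phi: float | None = None
    photon_rate: float = DEFAULT_PHOTON_RATE
    limit_counter: int = 0
    ties: int = 0


@dataclass
class Population:
    electrons: list[Electron]
    best_position: np.ndarray | None = None
    best_energy: float = math.inf

    @property
    def m(self) -> int:
        return len(self.electrons)

    def note(self, position: np.ndarray, energy: float) -> None:
        """Track the best (position, energy) ever evaluated this run."""
        if energy < self.best_energy:
            self.best_energy = energy
            self.best_position = position.copy()


@dataclass(frozen=True)
class LayerAssignment:
    n_layers: int
    layer_of: np.ndarray  # per-electron layer index, 1-based


@dataclass(frozen=True)
class BindingRecord:
    layer_bs: list[np.ndarray]  # per-layer position centroid
    layer_be: list[float]  # per-layer mean energy
    layer_le: list[np.ndarray]  # per-layer best position
    layer_le_energy: list[float]
    bs: np.ndarray  # global centroid
    be: float  # global mean energy
    le: np.ndarray  # best-so-far position
    le_energy: float


@dataclass(frozen=True)
class OptimizerParams:
    """Run protocol: population of 30 evolved for 20 iterations, repeated
    over 10 independent restarts, by default."""

    m: int = 30
    max_iterations: int = 20
    n_runs: int = 10
    layer_max: int = 5
    limit_threshold: float = 5
    algorithm: str = "baos"
    levy: LevyConfig = field(default_factory=LevyConfig)
    seed: int = 0
    pr_update: bool = True

    def __post_init__(self) -> None:
        if self.m < 1 or self.max_iterations < 1 or self.layer_max < 1 or self.n_runs < 1:
            raise ValueError("m, max_iterations, n_runs and layer_max must be >= 1")
        if self.algorithm not in ("aos", "baos", "random"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")

    @property
    def budget(self) -> int:
        """Objective evaluations per run under greedy acceptance."""
        return self.m * (1 + self.max_iterations)


@dataclass(frozen=True)
class RunRecord:
    seed: int
    best_position: np.ndarray
    best_assignment: dict[str, Any]
    best_energy: float
    trace: list[float]
    evaluations: int


@dataclass(frozen=True)
class OptimizationResult:
    best_assignment: dict[str, Any]
    best_position: np.ndarray
    best_energy: float
    trace: list[float]
    evaluations: int
    per_run: list[RunRecord]


def _checked(objective: Callable[[np.ndarray], float], position: np.ndarray) -> float:
    value = float(objective(position))
    if not math.isfinite(value):
        raise ObjectiveError(value, position)
    return value


def initialize(space: SearchSpace, m: int, rng: np.random.Generator) -> Population:
    """Uniformly scatter ``m`` electrons over the space embedding."""
    if m < 1:
        raise ValueError("m must be >= 1")
    positions = space.sample_uniform(m, rng)
    return Population(electrons=[Electron(position=p) for p in positions])


def evaluate(population: Population, objective: Callable[[np.ndarray], float]) -> Population:
    """Set every electron's energy and update the best-so-far record."""
    for e in population.electrons:
        e.energy = _checked(objective, e.position)
        population.note(e.position, e.energy)
    return population


def assign_layers(
    population: Population, layer_max: int, rng: np.random.Generator
) -> LayerAssignment:
    """Partition the energy-sorted population into 1..layer_max contiguous
    layers with sizes proportional to a discretised standard-normal density
    over layer index, so inner (better) layers hold more electrons."""
    m = population.m
    n_layers = int(rng.integers(1, layer_max + 1))
    n_layers = min(n_layers, m)
    # density weights at equispaced points of [0, 2.4] over layer index
    z = np.arange(n_layers) * (2.4 / max(n_layers - 1, 1)) if n_layers > 1 else np.zeros(1)
    w = norm.pdf(z)
    sizes = np.maximum(1, np.floor(w / w.sum() * m).astype(int))
    # largest-remainder style fix-up to sum exactly to m, never emptying a layer
    while sizes.sum() > m:
        sizes[np.argmax(sizes)] -= 1
    while sizes.sum() < m:
        sizes[np.argmin(sizes)] += 1
    order = np.argsort([e.energy for e in population.electrons], kind="stable")
    layer_of = np.empty(m, dtype=int)
    start = 0
    for k, size in enumerate(sizes, start=1):
        layer_of[order[start : start + size]] = k
        start += size
    return LayerAssignment(n_layers=n_layers, layer_of=layer_of)


def binding(population: Population, layers: LayerAssignment) -> BindingRecord:
    """Per-layer and global binding states/energies plus the best-so-far."""
    positions = np.array([e.position for e in population.electrons])
    energies = np.array([e.energy for e in population.electrons], dtype=float)
    layer_bs, layer_be, layer_le, layer_le_energy = [], [], [], []
    for k in range(1, layers.n_layers + 1):
        member = layers.layer_of == k
        if not member.any():
            raise RuntimeError(f"layer {k} is empty")
        layer_bs.append(positions[member].mean(axis=0))
        layer_be.append(float(energies[member].mean()))
        j = np.flatnonzero(member)[np.argmin(energies[member])]
        layer_le.append(positions[j].copy())
        layer_le_energy.append(float(energies[j]))
    return BindingRecord(
        layer_bs=layer_bs,
        layer_be=layer_be,
        layer_le=layer_le,
        layer_le_energy=layer_le_energy,
        bs=positions.mean(axis=0),
        be=float(energies.mean()),
        le=population.best_position.copy(),
        le_energy=population.best_energy,
    )


@functools.lru_cache(maxsize=8)
def _pr_scale(beta: float) -> float:
    """Scale c with median(c * |Levy(beta)|) = DEFAULT_PHOTON_RATE.

    Calibrated once per beta from a fixed internal stream so BAOS photon
    rates fluctuate heavy-tailedly around the canonical AOS rate.
    """
    steps = sample_steps(200_000, beta, np.random.default_rng(987654321))
    return DEFAULT_PHOTON_RATE / float(np.median(np.abs(steps)))


def _fold(raw: np.ndarray, lo: np.ndarray, span: np.ndarray) -> np.ndarray:
    """Reflect out-of-bounds coordinates back into [lo, lo + span]."""
    period = 2.0 * span
    t = np.mod(raw - lo, period)
    return lo + np.minimum(t, period - t)


def _core_step(
    population: Population,
    bind: BindingRecord,
    layers: LayerAssignment,
    params: OptimizerParams,
    rng: np.random.Generator,
    space: SearchSpace,
    objective: Callable[[np.ndarray], float],
    levy_boost: bool,
) -> Population:
    d = space.d
    span = space.span
    lo, _ = space.embedded_bounds()
    pr_c = _pr_scale(params.levy.beta) if levy_boost and params.pr_update else None
    restarts_enabled = levy_boost and math.isfinite(params.limit_threshold)
    for i, e in enumerate(population.electrons):
        if pr_c is not None:
            step = sample_steps(1, params.levy.beta, rng)[0]
            e.photon_rate = float(np.clip(pr_c * abs(step), 0.0, 1.0))
        plateaued = e.ties > 0
        threshold = 0 if plateaued else params.limit_threshold
        if restarts_enabled and e.limit_counter > threshold:
            # stagnation restart: Lévy jump from the best-so-far, accepted
            # unconditionally; full-span folded jump on a detected plateau,
            # distance-annealed local jump otherwise
            if plateaued:
                scale = _PLATEAU_SCALE * span
            else:
                scale = np.maximum(np.abs(e.position - bind.le), _RESTART_FLOOR * span)
            raw = bind.le + levy_displacement(space, params.levy, rng, scale=scale)
            e.position = space.repair(_fold(raw, lo, span))
            e.energy = _checked(objective, e.position)
            e.limit_counter = 0
            population.note(e.position, e.energy)
            continue
        k = int(layers.layer_of[i])
        alpha = rng.random(d)
        beta = rng.random(d)
        gamma = rng.random(d)
        e.phi = float(rng.random())
        if e.phi >= e.photon_rate:
            if e.energy >= bind.layer_be[k - 1]:
                # above the layer's binding energy: pull towards the global
                # guide, damped by layer depth
                move = alpha * (beta * bind.le - gamma * bind.bs) / k
            else:
                move = alpha * (beta * bind.layer_le[k - 1] - gamma * bind.layer_bs[k - 1])
        else:
            move = rng.uniform(-_WALK_FRACTION, _WALK_FRACTION, size=d) * span
        candidate = space.repair(e.position + move)
        energy = _checked(objective, candidate)
        population.note(candidate, energy)
        if energy < e.energy:
            e.position = candidate
            e.energy = energy
            e.limit_counter = 0
            e.ties = 0
        else:
            if energy == e.energy:
                e.ties += 1
            e.limit_counter += 1
    return population


def aos_step(
    population: Population,
    bind: BindingRecord,
    layers: LayerAssignment,
    params: OptimizerParams,
    rng: np.random.Generator,
    space: SearchSpace,
    objective: Callable[[np.ndarray], float],
) -> Population:
    """One AOS iteration: move, repair, re-evaluate, greedily accept."""
    return _core_step(population, bind, layers, params, rng, space, objective, levy_boost=False)


def baos_step(
    population: Population,
    bind: BindingRecord,
    layers: LayerAssignment,
    params: OptimizerParams,
    rng: np.random.Generator,
    space: SearchSpace,
    objective: Callable[[np.ndarray], float],
) -> Population:
    """One BAOS iteration: AOS plus Lévy photon-rate updates and
    limit-counter restarts from the best-so-far position."""
    return _core_step(population, bind, layers, params, rng, space, objective, levy_boost=True)


class _CountingObjective:
    def __init__(self, objective: Callable[[np.ndarray], float]):
        self._objective = objective
        self.calls = 0

    def __call__(self, position: np.ndarray) -> float:
        self.calls += 1
        return self._objective(position)


def _single_run(
    objective: Callable[[np.ndarray], float],
    space: SearchSpace,
    params: OptimizerParams,
    run_seed: int,
) -> RunRecord:
    rng = np.random.default_rng(run_seed)
    counter = _CountingObjective(objective)
    step = baos_step if params.algorithm == "baos" else aos_step
    population = initialize(space, params.m, rng)
    evaluate(population, counter)
    trace = [population.best_energy]
    for _ in range(params.max_iterations):
        layers = assign_layers(population, params.layer_max, rng)
        bind = binding(population, layers)
        step(population, bind, layers, params, rng, space, counter)
        trace.append(population.best_energy)
    return RunRecord(
        seed=run_seed,
        best_position=population.best_position,
        best_assignment=space.decode(population.best_position),
        best_energy=population.best_energy,
        trace=trace,
        evaluations=counter.calls,
    )


def optimize(
    objective: Callable[[np.ndarray], float],
    space: SearchSpace,
    params: OptimizerParams,
) -> OptimizationResult:
    """Full protocol: ``n_runs`` independent restarts of init →
    [evaluate → assign layers → binding → step] × ``max_iterations``.

    Per-run seeds derive from the master seed by fixed unit increments.
    The ``random`` algorithm runs a budget-matched uniform search instead.
    """
    records = []
    for r in range(params.n_runs):
        run_seed = params.seed + r
        if params.algorithm == "random":
            result = random_search(
                objective, space, params.budget, np.random.default_rng(run_seed)
            )
            rec = result.per_run[0]
            records.append(
                RunRecord(
                    seed=run_seed,
                    best_position=rec.best_position,
                    best_assignment=rec.best_assignment,
                    best_energy=rec.best_energy,
                    trace=rec.trace,
                    evaluations=rec.evaluations,
                )
            )
        else:
            records.append(_single_run(objective, space, params, run_seed))
    best = min(records, key=lambda rec: rec.best_energy)
    return OptimizationResult(
        best_assignment=best.best_assignment,
        best_position=best.best_position,
        best_energy=best.best_energy,
        trace=best.trace,
        evaluations=sum(rec.evaluations for rec in records),
        per_run=records,
    )


def random_search(
    objective: Callable[[np.ndarray], float],
    space: SearchSpace,
    budget: int,
    rng: np.random.Generator,
) -> OptimizationResult:
    """Uniform sampling baseline spending exactly ``budget`` evaluations."""
    if budget < 1:
        raise ValueError("budget must be >= 1")
    counter = _CountingObjective(objective)
    best_energy = math.inf
    best_position = None
    trace = []
    for _ in range(budget):
        position = space.sample_uniform(1, rng)[0]
        energy = _checked(counter, position)
        if energy < best_energy:
            best_energy = energy
            best_position = position
        trace.append(best_energy)
    record = RunRecord(
        seed=-1,
        best_position=best_position,
        best_assignment=space.decode(best_position),
        best_energy=best_energy,
        trace=trace,
        evaluations=counter.calls,
    )
    return OptimizationResult(
        best_assignment=record.best_assignment,
        best_position=record.best_position,
        best_energy=record.best_energy,
        trace=record.trace,
        evaluations=record.evaluations,
        per_run=[record],
    )
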