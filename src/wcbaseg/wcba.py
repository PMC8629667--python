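"""Water-cycle / bat hybrid optimizer (WCBA).

A population of "raindrops" is ranked by cost: the best member is the
sea, the next ``n_sr - 1`` are rivers, the rest are streams.  Streams
flow toward their assigned river or sea; rivers flow toward the sea
with a bat-algorithm frequency/velocity blend; when a river (or a
sea-bound stream) comes within the evaporation radius ``b_max`` of the
sea, raining re-scatters the affected streams — uniformly over the box
for river-bound streams, or in a Gaussian cloud of spread ``delta``
around the sea for sea-bound ones.  ``b_max`` decays geometrically so
exploration gives way to local intensification.

All randomness is drawn from one seeded generator passed explicitly;
identical seeds give bit-identical runs.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "WCBAParams",
    "WCBAState",
    "OptimizeResult",
    "initialize",
    "flow_intensity",
    "update_stream",
    "bat_frequency",
    "update_river_wcba",
    "promote",
    "evaporation_check",
    "raining",
    "decay_bmax",
    "optimize",
    "BENCHMARKS",
]

_INIT_RETRIES = 100


@dataclasses.dataclass(frozen=True)
class WCBAParams:
    """Optimizer configuration.

    ``n_sr`` counts the sea plus the rivers; ``b_max0`` defaults to
    1e-2 times the box diagonal; ``z`` is the step-scale constant
    multiplying the uniform draw (canonical water-cycle choice 2);
    ``l_min``/``l_max`` bound the bat frequency.
    """

    n_vars: int
    lower: tuple[float, ...] | Sequence[float]
    upper: tuple[float, ...] | Sequence[float]
    pop_size: int = 30
    n_sr: int = 4
    max_iter: int = 300
    b_max0: float | None = None
    delta: float = 0.1
    l_min: float = 0.0
    l_max: float = 100.0
    z: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        lower = np.broadcast_to(np.asarray(self.lower, dtype=np.float64), (self.n_vars,)).copy()
        upper = np.broadcast_to(np.asarray(self.upper, dtype=np.float64), (self.n_vars,)).copy()
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if self.n_vars < 1:
            raise ValueError("n_vars must be >= 1")
        if self.pop_size < 4:
            raise ValueError("pop_size must be >= 4")
        if not 1 <= self.n_sr < self.pop_size:
            raise ValueError("need 1 <= n_sr < pop_size")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not np.all(lower < upper):
            raise ValueError("lower must be < upper componentwise")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.b_max0 is not None and self.b_max0 <= 0:
            raise ValueError("b_max0 must be > 0")

    @property
    def n_streams(self) -> int:
        return self.pop_size - self.n_sr

    def initial_bmax(self) -> float:
        if self.b_max0 is not None:
            return float(self.b_max0)
        return 1e-2 * float(np.linalg.norm(self.upper - self.lower))

    def clip(self, position: np.ndarray) -> np.ndarray:
        return np.clip(position, self.lower, self.upper)


@dataclasses.dataclass
class WCBAState:
    """Population arrays ordered [sea, rivers..., streams...].

    ``stream_assignment[i]`` is the guide index (0 for the sea,
    1..n_sr-1 for a river) of population member ``n_sr + i``.
    """

    positions: np.ndarray  # (pop, n_vars)
    costs: np.ndarray  # (pop,)
    velocities: np.ndarray  # (pop, n_vars)
    prev_positions: np.ndarray  # (pop, n_vars)
    stream_assignment: np.ndarray  # (n_streams,)
    b_max: float
    iteration: int = 0

    @property
    def sea_position(self) -> np.ndarray:
        return self.positions[0]

    @property
    def sea_cost(self) -> float:
        return float(self.costs[0])


@dataclasses.dataclass(frozen=True)
class OptimizeResult:
    best_position: np.ndarray
    best_cost: float
    best_cost_trace: np.ndarray
    state: WCBAState


def _evaluate(fitness: Callable[[np.ndarray], float], position: np.ndarray) -> float:
    return float(fitness(np.asarray(position, dtype=np.float64)))


def initialize(params: WCBAParams, fitness: Callable[[np.ndarray], float]) -> WCBAState:
    """Uniform random population, evaluated, sorted ascending by cost."""
    rng = np.random.default_rng(params.seed)
    positions = np.empty((params.pop_size, params.n_vars))
    costs = np.empty(params.pop_size)
    for i in range(params.pop_size):
        for attempt in range(_INIT_RETRIES + 1):
            pos = rng.uniform(params.lower, params.upper)
            cost = _evaluate(fitness, pos)
            if np.isfinite(cost):
                break
        else:  # pragma: no cover - exhausted retries
            raise RuntimeError("fitness returned non-finite values for all initial draws")
        positions[i], costs[i] = pos, cost
    order = np.argsort(costs, kind="stable")
    positions, costs = positions[order], costs[order]
    state = WCBAState(
        positions=positions,
        costs=costs,
        velocities=np.zeros_like(positions),
        prev_positions=positions.copy(),
        stream_assignment=np.zeros(params.n_streams, dtype=int),
        b_max=params.initial_bmax(),
    )
    state.stream_assignment = flow_intensity(state, params)
    return state


def flow_intensity(state: WCBAState, params: WCBAParams) -> np.ndarray:
    """Assign each stream to the sea or a river by shifted-cost share.

    Entity i (sea and rivers, ascending cost) receives
    ``round(|Cs_i| / Σ|Cs| · n_streams)`` streams with
    ``Cs_i = B_i - B_{n_sr+1}`` (the best stream's cost), so cheaper
    entities attract more streams; any rounding remainder is absorbed by
    the sea and the counts sum to the stream count exactly.
    """
    n_sr, n_streams = params.n_sr, params.n_streams
    costs = state.costs
    shifted = costs[:n_sr] - costs[n_sr]
    total = shifted.sum()
    if total == 0.0:
        counts = np.full(n_sr, n_streams // n_sr, dtype=int)
    else:
        counts = np.round(shifted / total * n_streams).astype(int)
        counts = np.maximum(counts, 0)
    counts[0] += n_streams - counts.sum()
    while counts[0] < 0:  # remainder absorption drove the sea negative
        donor = int(np.argmax(counts[1:])) + 1
        take = min(counts[donor], -counts[0])
        counts[donor] -= take
        counts[0] += take
    assignment = np.repeat(np.arange(n_sr), counts)
    return assignment


def update_stream(
    position: np.ndarray,
    guide_position: np.ndarray,
    rng: np.random.Generator,
    params: WCBAParams,
) -> np.ndarray:
    """Stream flow: position + rand·z·(guide − position), clipped."""
    rand = rng.uniform()
    new = position + rand * params.z * (guide_position - position)
    return params.clip(new)


def bat_frequency(k: float, params: WCBAParams) -> float:
    """Bat frequency l_b = l_min + (l_max − l_min)·k for k in [0, 1]."""
    if not 0.0 <= k <= 1.0:
        raise ValueError(f"k must be in [0, 1], got {k}")
    return params.l_min + (params.l_max - params.l_min) * k


def update_river_wcba(
    position: np.ndarray,
    prev_position: np.ndarray,
    velocity: np.ndarray,
    rng: np.random.Generator,
    params: WCBAParams,
    sea_position: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """River update blending the water-cycle flow with the bat frequency.

    new = position·(1 − rand·z·(2 − l_b)/l_b) + rand·z·(prev + velocity),
    followed by the velocity update Q ← new − position and clipping.
    A vanishing frequency (|l_b| < 1e-8) falls back to the plain
    water-cycle river step toward the sea.
    Returns ``(new_position, new_velocity)``.
    """
    rand = rng.uniform()
    l_b = bat_frequency(rng.uniform(), params)
    if abs(l_b) < 1e-8:
        if sea_position is None:
            new = position.copy()
        else:
            new = position + rand * params.z * (sea_position - position)
    else:
        new = position * (1.0 - rand * params.z * (2.0 - l_b) / l_b) + rand * params.z * (
            prev_position + velocity
        )
    new = params.clip(new)
    return new, new - position


def promote(state: WCBAState, params: WCBAParams) -> WCBAState:
    """Role swaps: streams cheaper than their guide swap with it, rivers
    cheaper than the sea swap with the sea; afterwards the sea holds the
    population's minimum cost."""

    def swap(i: int, j: int) -> None:
        for arr in (state.positions, state.costs, state.velocities, state.prev_positions):
            arr[[i, j]] = arr[[j, i]]

    n_sr = params.n_sr
    for s_idx, guide in enumerate(state.stream_assignment):
        i = n_sr + s_idx
        if state.costs[i] < state.costs[guide]:
            swap(i, int(guide))
    for r in range(1, n_sr):
        if state.costs[r] < state.costs[0]:
            swap(r, 0)
    best = int(np.argmin(state.costs))
    if best != 0:
        swap(best, 0)
    return state


def evaporation_check(
    river_position: np.ndarray, sea_position: np.ndarray, b_max: float
) -> bool:
    """True iff ‖sea − river‖ < b_max (the evaporation condition)."""
    return bool(np.linalg.norm(np.asarray(sea_position) - np.asarray(river_position)) < b_max)


def raining(
    entity_role: str,
    params: WCBAParams,
    sea_position: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """New stream position after evaporation.

    River-bound streams re-scatter uniformly over the box
    (LB + rand·(UB − LB)); sea-bound streams land in a Gaussian cloud
    sea + delta·randn around the sea, which concentrates the search.
    """
    if entity_role == "stream":
        new = params.lower + rng.uniform(size=params.n_vars) * (params.upper - params.lower)
    elif entity_role == "sea_stream":
        new = sea_position + params.delta * rng.standard_normal(params.n_vars)
    else:
        raise ValueError(f"unknown raining role {entity_role!r}")
    return params.clip(new)


def decay_bmax(b_max: float, max_iter: int) -> float:
    """Geometric decay b_max ← b_max − b_max / max_iter."""
    if max_iter == 0:
        raise ValueError("max_iter must be nonzero")
    return b_max - b_max / max_iter


def optimize(
    fitness: Callable[[np.ndarray], float], params: WCBAParams
) -> OptimizeResult:
    """Run the full water-cycle/bat loop for ``max_iter`` iterations.

    Per iteration: stream flows, river updates, promotion, evaporation
    and raining, threshold decay.  The sea is elitist (only replaced by
    a cheaper member), so the best-so-far trace is non-increasing.
    """
    rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(1)[0])
    state = initialize(params, fitness)
    n_sr = params.n_sr
    trace = np.empty(params.max_iter)
    for it in range(params.max_iter):
        # canonical ordering keeps the shifted-cost shares well defined
        order = np.argsort(state.costs, kind="stable")
        state.positions = state.positions[order]
        state.costs = state.costs[order]
        state.velocities = state.velocities[order]
        state.prev_positions = state.prev_positions[order]
        state.stream_assignment = flow_intensity(state, params)

        for s_idx, guide in enumerate(state.stream_assignment):
            i = n_sr + s_idx
            new = update_stream(state.positions[i], state.positions[int(guide)], rng, params)
            state.positions[i] = new
            state.costs[i] = _evaluate(fitness, new)

        for r in range(1, n_sr):
            prev = state.prev_positions[r].copy()
            cur = state.positions[r].copy()
            new, vel = update_river_wcba(
                cur, prev, state.velocities[r], rng, params, state.sea_position
            )
            state.positions[r] = new
            state.velocities[r] = vel
            state.prev_positions[r] = cur
            state.costs[r] = _evaluate(fitness, new)

        promote(state, params)

        for s_idx, guide in enumerate(state.stream_assignment):
            i = n_sr + s_idx
            if guide == 0:
                if evaporation_check(state.positions[i], state.sea_position, state.b_max):
                    new = raining("sea_stream", params, state.sea_position, rng)
                    state.positions[i] = new
                    state.costs[i] = _evaluate(fitness, new)
            else:
                if evaporation_check(state.positions[int(guide)], state.sea_position, state.b_max):
                    new = raining("stream", params, state.sea_position, rng)
                    state.positions[i] = new
                    state.costs[i] = _evaluate(fitness, new)

        best = int(np.argmin(state.costs))
        if best != 0:
            for arr in (state.positions, state.costs, state.velocities, state.prev_positions):
                arr[[0, best]] = arr[[best, 0]]

        state.b_max = decay_bmax(state.b_max, params.max_iter)
        state.iteration = it + 1
        trace[it] = state.sea_cost

    trace = np.minimum.accumulate(trace)
    return OptimizeResult(
        best_position=state.sea_position.copy(),
        best_cost=state.sea_cost,
        best_cost_trace=trace,
        state=state,
    )


def _sphere(x: np.ndarray) -> float:
    return float(np.sum(x**2))


def _rosenbrock(x: np.ndarray) -> float:
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))


def _rastrigin(x: np.ndarray) -> float:
    return float(10.0 * x.size + np.sum(x**2 - 10.0 * np.cos(2.0 * np.pi * x)))


#: named benchmark objectives runnable from the CLI
BENCHMARKS: dict[str, Callable[[np.ndarray], float]] = {
    "sphere": _sphere,
    "rosenbrock": _rosenbrock,
    "rastrigin": _rastrigin,
}
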