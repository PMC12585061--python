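"""Harmony Search with Opposition-Based Learning (HS-OBL).

A population ("harmony memory") of candidate hyperparameter vectors is
refined by improvisation: per dimension, with probability HMCR a value is
copied from a random memory member (then perturbed within a small
bandwidth with probability PAR), otherwise drawn uniformly from the
bounds. A strictly better candidate replaces the worst member. When the
best fitness stagnates, opposition-based learning reflects every member
through the box center (h' = x_min + x_max - h) and keeps the best HMS of
the union. HMCR and PAR decay linearly over iterations so the search
moves from exploration to exploitation.

Fitness is minimized. The default multi-objective scalarization for
model tuning combines (1 - validation accuracy), the generalization gap,
and normalized training time with weights (0.6, 0.3, 0.1).
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "Dimension", "SearchSpace", "Harmony", "HSConfig", "FitnessSpec",
    "initialize_memory", "improvise", "opposite", "update_memory",
    "adapt_parameters", "optimize", "scalarize_fitness", "OptimizeResult",
]


@dataclass
class Dimension:
    name: str
    low: float
    high: float
    scale: str = "linear"       # {"linear", "log"}
    kind: str = "continuous"    # {"continuous", "integer", "categorical"}

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"dimension {self.name}: require low < high")
        if self.scale == "log" and self.low <= 0:
            raise ValueError(f"dimension {self.name}: log scale needs positive bounds")

    def sample(self, rng: np.random.Generator) -> float:
        if self.scale == "log":
            return float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))
        return float(rng.uniform(self.low, self.high))

    def clip(self, value: float) -> float:
        return float(np.clip(value, self.low, self.high))

    def finalize(self, value: float) -> float:
        """Round relaxed integer/categorical dimensions at evaluation time."""
        if self.kind in ("integer", "categorical"):
            return float(int(round(value)))
        return value


@dataclass
class SearchSpace:
    dimensions: Sequence[Dimension]

    def __post_init__(self) -> None:
        if not self.dimensions:
            raise ValueError("search space must have at least one dimension")

    def __len__(self) -> int:
        return len(self.dimensions)

    def contains(self, vector: np.ndarray) -> bool:
        return all(d.low <= v <= d.high for d, v in zip(self.dimensions, vector))

    def as_dict(self, vector: np.ndarray) -> dict[str, float]:
        return {d.name: d.finalize(v) for d, v in zip(self.dimensions, vector)}

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SearchSpace":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls([Dimension(**d) for d in raw["dimensions"]])


@dataclass
class Harmony:
    vector: np.ndarray
    fitness: float = np.inf
    evaluated: bool = False

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=np.float64)


@dataclass
class HSConfig:
    hmcr: float = 0.9
    par: float = 0.3
    hms: int = 30
    max_iterations: int = 50
    opposition: bool = True
    decay: str = "linear"             # {"none", "linear"}
    hmcr_floor: float = 0.7
    par_floor: float = 0.1
    stagnation_window: int = 5
    bandwidth_fraction: float = 0.05   # initial pitch-adjust bandwidth (fraction of range)
    bandwidth_floor: float = 0.001     # final bandwidth after exponential decay
    improvisations_per_iteration: Optional[int] = None  # default: one per memory slot
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.par <= self.hmcr <= 1:
            raise ValueError("require 0 < PAR <= HMCR <= 1")
        if self.hms < 2:
            raise ValueError("harmony memory size must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "HSConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class FitnessSpec:
    """Objective contract: harmony dict -> components, scalarized here."""

    objective: Callable[[dict[str, float]], dict[str, float] | float]
    weights: tuple[float, float, float] = (0.6, 0.3, 0.1)
    budget_epochs: int = 5

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights) or not any(w > 0 for w in self.weights):
            raise ValueError("weights must be non-negative with at least one positive")

    def __call__(self, params: dict[str, float]) -> float:
        out = self.objective(params)
        if isinstance(out, dict):
            return scalarize_fitness(out, self.weights)
        return float(out)


def scalarize_fitness(components: dict[str, float],
                      weights: tuple[float, float, float] = (0.6, 0.3, 0.1)) -> float:
    """fitness = w1 (1 - val_accuracy) + w2 gap + w3 normalized_train_time."""
    w1, w2, w3 = weights
    return (w1 * (1.0 - components.get("val_accuracy", 0.0))
            + w2 * components.get("generalization_gap", 0.0)
            + w3 * components.get("normalized_train_time", 0.0))


def initialize_memory(space: SearchSpace, hms: int, seed: int) -> list[Harmony]:
    if hms < 2:
        raise ValueError("harmony memory size must be >= 2")
    rng = np.random.default_rng(seed)
    return [Harmony(np.array([d.sample(rng) for d in space.dimensions]))
            for _ in range(hms)]


def improvise(memory: Sequence[Harmony], space: SearchSpace, hmcr: float,
              par: float, bandwidth_fraction: float,
              rng: np.random.Generator) -> Harmony:
    """One new candidate from memory consideration + pitch adjustment."""
    if not memory:
        raise ValueError("harmony memory is empty")
    vec = np.empty(len(space))
    for j, dim in enumerate(space.dimensions):
        if rng.random() < hmcr:
            value = memory[rng.integers(len(memory))].vector[j]
            if rng.random() < par:
                value += rng.uniform(-1, 1) * bandwidth_fraction * (dim.high - dim.low)
            vec[j] = dim.clip(value)
        else:
            vec[j] = dim.sample(rng)
    return Harmony(vec)


def opposite(harmony: Harmony, space: SearchSpace) -> Harmony:
    """Componentwise reflection h' = x_min + x_max - h (an involution)."""
    vec = np.array([d.low + d.high - v
                    for d, v in zip(space.dimensions, harmony.vector)])
    return Harmony(vec)


def update_memory(memory: list[Harmony], candidate: Harmony) -> list[Harmony]:
    """Replace the worst member iff the candidate is strictly better."""
    if not candidate.evaluated:
        raise ValueError("candidate must be evaluated before memory update")
    worst = max(range(len(memory)), key=lambda i: memory[i].fitness)
    if candidate.fitness < memory[worst].fitness:
        memory[worst] = candidate
    return memory


def adapt_parameters(cfg: HSConfig, iteration: int) -> tuple[float, float]:
    """Linearly decayed (HMCR_t, PAR_t); constant when decay is 'none'."""
    if iteration > cfg.max_iterations:
        raise ValueError("iteration beyond max_iterations")
    if cfg.decay == "none" or cfg.max_iterations == 0:
        return cfg.hmcr, cfg.par
    frac = iteration / cfg.max_iterations
    hmcr = cfg.hmcr + (cfg.hmcr_floor - cfg.hmcr) * frac
    par = cfg.par + (cfg.par_floor - cfg.par) * frac
    return float(hmcr), float(par)


def adapt_bandwidth(cfg: HSConfig, iteration: int) -> float:
    """Exponentially decayed pitch-adjust bandwidth (exploration ->
    exploitation, matching the HMCR/PAR schedule)."""
    if cfg.decay == "none" or cfg.max_iterations == 0:
        return cfg.bandwidth_fraction
    frac = iteration / cfg.max_iterations
    return float(cfg.bandwidth_fraction *
                 (cfg.bandwidth_floor / cfg.bandwidth_fraction) ** frac)


@dataclass
class OptimizeResult:
    best: Harmony
    best_params: dict[str, float]
    history: list[dict]


def _evaluate(h: Harmony, fitness: Callable, space: SearchSpace) -> Harmony:
    try:
        h.fitness = float(fitness(space.as_dict(h.vector)))
    except Exception as exc:  # noqa: BLE001 — a failing trial must not kill the run
        warnings.warn(f"fitness evaluation failed ({exc}); recording +inf")
        h.fitness = np.inf
    h.evaluated = True
    return h


def optimize(space: SearchSpace, fitness: Callable[[dict[str, float]], float],
             cfg: Optional[HSConfig] = None,
             trace_path: Optional[str | os.PathLike] = None) -> OptimizeResult:
    """Run HS-OBL; returns the argmin harmony and the full iteration trace.

    Each iteration improvises and evaluates one candidate per memory slot
    (the per-iteration sweep of the whole memory); set
    ``improvisations_per_iteration`` to 1 for expensive objectives.
    """
    cfg = cfg or HSConfig()
    rng = np.random.default_rng(cfg.seed)
    memory = initialize_memory(space, cfg.hms, cfg.seed)
    for h in memory:
        _evaluate(h, fitness, space)
    n_improv = cfg.improvisations_per_iteration or cfg.hms
    history: list[dict] = []
    best_so_far = min(h.fitness for h in memory)
    stagnant = 0
    for it in range(1, cfg.max_iterations + 1):
        hmcr_t, par_t = adapt_parameters(cfg, it - 1)
        bw_t = adapt_bandwidth(cfg, it - 1)
        best_cand: Optional[Harmony] = None
        for _ in range(n_improv):
            cand = improvise(memory, space, hmcr_t, par_t, bw_t, rng)
            _evaluate(cand, fitness, space)
            update_memory(memory, cand)
            if best_cand is None or cand.fitness < best_cand.fitness:
                best_cand = cand
        new_best = min(h.fitness for h in memory)
        stagnant = stagnant + 1 if new_best >= best_so_far else 0
        opposition_event = False
        if cfg.opposition and stagnant >= cfg.stagnation_window:
            opposition_event = True
            stagnant = 0
            opposites = [_evaluate(opposite(h, space), fitness, space) for h in memory]
            union = memory + opposites
            union.sort(key=lambda h: h.fitness)
            memory = union[: cfg.hms]
            new_best = min(h.fitness for h in memory)
        best_so_far = min(best_so_far, new_best)
        history.append({
            "iteration": it, "hmcr": hmcr_t, "par": par_t,
            "candidate_fitness": best_cand.fitness, "best_fitness": best_so_far,
            "opposition": opposition_event,
            "candidate": best_cand.vector.tolist(),
        })
    best = min(memory, key=lambda h: h.fitness)
    if trace_path is not None:
        with open(os.fspath(trace_path), "w") as fh:
            for row in history:
                fh.write(json.dumps(row) + "\n")
    return OptimizeResult(best=best, best_params=space.as_dict(best.vector),
                          history=history)
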