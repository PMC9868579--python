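"""Genetic-algorithm refinement of named model parameters.

The calibration workflow fits free parameters (rate constants,
conductances, leak rates -- any dotted field of :class:`ModelParams`)
against waveform or endpoint features by minimizing a weighted sum of
squared relative errors.  The GA uses tournament selection, blend (BLX)
crossover, Gaussian mutation in log-space (all parameters are positive
rates), and elitism, with every stochastic draw flowing from one recorded
seed.  The operators are not sacred: they are a reasonable default for
bounded positive parameters and are replaceable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .engine import ModelParams


def get_param(params: ModelParams, dotted: str) -> float:
    obj = params
    *head, last = dotted.split(".")
    for h in head:
        obj = getattr(obj, h)
    return getattr(obj, last)


def set_params(params: ModelParams, values: dict[str, float]) -> ModelParams:
    """Return a copy of ``params`` with dotted fields replaced."""
    groups: dict[str, dict[str, float]] = {}
    top: dict[str, float] = {}
    for dotted, v in values.items():
        if "." in dotted:
            head, last = dotted.split(".", 1)
            groups.setdefault(head, {})[last] = v
        else:
            top[dotted] = v
    repl = dict(top)
    for head, sub in groups.items():
        repl[head] = dataclasses.replace(getattr(params, head), **sub)
    return dataclasses.replace(params, **repl)


@dataclass
class FitSpec:
    """Free parameters, bounds, objective features, and GA settings."""

    param_names: list[str]
    bounds: dict[str, tuple[float, float]]
    simulate: Callable[[dict[str, float]], dict]
    targets: dict[str, tuple[object, float]]   # feature -> (target, weight)
    population: int = 32
    generations: int = 40
    mutation_scale: float = 0.15   # sigma of the log-space Gaussian
    mutation_prob: float = 0.35
    crossover_alpha: float = 0.4
    tournament_k: int = 3
    elite: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise ValueError("population must be positive")
        for n in self.param_names:
            lo, hi = self.bounds[n]
            if not (np.isfinite(lo) and np.isfinite(hi) and 0 < lo < hi):
                raise ValueError(f"bounds for {n} must be finite, positive, ordered")
        for _, (tgt, w) in self.targets.items():
            if w < 0:
                raise ValueError("weights must be >= 0")


def objective(values: dict[str, float], spec: FitSpec) -> float:
    """Weighted sum of squared relative feature errors; large finite
    penalty (1e6) when the simulation fails."""
    for n in spec.param_names:
        lo, hi = spec.bounds[n]
        if not (lo <= values[n] <= hi):
            raise ValueError(f"parameter {n} outside bounds")
    try:
        feats = spec.simulate(values)
    except Exception:
        return 1.0e6
    loss = 0.0
    for name, (target, w) in spec.targets.items():
        f = feats[name]
        if isinstance(target, np.ndarray):
            scale = float(np.max(np.abs(target))) or 1.0
            loss += w * float(np.mean(((np.asarray(f) - target) / scale) ** 2))
        else:
            scale = abs(float(target)) or 1.0
            loss += w * ((float(f) - float(target)) / scale) ** 2
    if not np.isfinite(loss):
        return 1.0e6
    return loss


@dataclass
class FitResult:
    best: dict[str, float]
    best_loss: float
    trace: np.ndarray          # best loss per generation (non-increasing)
    seed: int


def fit(spec: FitSpec) -> FitResult:
    """Run the GA; reproducible for a fixed ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    names = spec.param_names
    lo = np.array([spec.bounds[n][0] for n in names])
    hi = np.array([spec.bounds[n][1] for n in names])
    log_lo, log_hi = np.log(lo), np.log(hi)

    pop = np.clip(
        np.exp(rng.uniform(log_lo, log_hi, size=(spec.population, len(names)))),
        lo, hi,
    )

    def evaluate(mat: np.ndarray) -> np.ndarray:
        return np.array(
            [objective(dict(zip(names, row)), spec) for row in mat]
        )

    losses = evaluate(pop)
    trace = []
    for _gen in range(spec.generations):
        order = np.argsort(losses)
        pop, losses = pop[order], losses[order]
        trace.append(losses[0])
        children = [pop[i].copy() for i in range(spec.elite)]
        while len(children) < spec.population:
            i = min(rng.integers(spec.population, size=spec.tournament_k))
            j = min(rng.integers(spec.population, size=spec.tournament_k))
            a, b = pop[i], pop[j]
            # BLX-alpha blend crossover in log space
            la, lb = np.log(a), np.log(b)
            span = np.abs(la - lb)
            child = rng.uniform(
                np.minimum(la, lb) - spec.crossover_alpha * span,
                np.maximum(la, lb) + spec.crossover_alpha * span,
            )
            mut = rng.random(len(names)) < spec.mutation_prob
            child = child + mut * rng.normal(0.0, spec.mutation_scale, len(names))
            children.append(np.clip(np.exp(child), lo, hi))
        pop = np.vstack(children)
        losses = np.concatenate([losses[: spec.elite], evaluate(pop[spec.elite :])])
    order = np.argsort(losses)
    pop, losses = pop[order], losses[order]
    trace.append(losses[0])
    return FitResult(
        best=dict(zip(names, pop[0])),
        best_loss=float(losses[0]),
        trace=np.minimum.accumulate(np.array(trace)),
        seed=spec.seed,
    )
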