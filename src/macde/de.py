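"""Differential evolution (rand/1/bin) for bounded real-vector minimization.

The engine follows the classical scheme: for each target individual X_i a
mutant V = X_r1 + F (X_r2 - X_r3) is built from three distinct other
population members, binomial crossover mixes V into X_i component-wise with
probability CR, an optional ``repair`` maps the trial back into the feasible
set, and greedy selection keeps the trial only when it strictly improves the
fitness.  Selection is elitist per individual, so the best-so-far fitness
never increases.

A ``repair`` hook applied to every trial vector before evaluation is part of
the contract: the polar-section segmenter uses it to restrict the search
space of each section, and the default repair clips to the box bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["DEConfig", "DEResult", "mutate", "crossover", "select", "run_de"]


@dataclass
class DEConfig:
    """Control parameters of the DE run.

    pop_size
        Population size Np; at least 4 so three mutually distinct donors
        different from the target always exist.
    generations
        Number of generations G (default 10).
    diff_factor
        Differentiation (scaling) factor F in (0, 2] (default 0.1).
    crossover_rate
        Crossover rate CR in [0, 1] (default 0.8).
    seed
        RNG seed; two runs with equal seed, config, init and fitness are
        bitwise identical.
    stability_window
        Early-stop patience: stop when the best fitness is unchanged for
        this many consecutive generations (0 disables; default).
    pure_binomial
        If True, use the literal binomial rule without the forced mutant
        component, so a trial may equal its target when every uniform draw
        exceeds CR.
    """

    pop_size: int = 15
    generations: int = 10
    diff_factor: float = 0.1
    crossover_rate: float = 0.8
    seed: int | None = None
    stability_window: int = 0
    pure_binomial: bool = False

    def __post_init__(self):
        if self.pop_size < 4:
            raise ValueError(f"pop_size must be >= 4, got {self.pop_size}")
        if self.generations < 1:
            raise ValueError(f"generations must be >= 1, got {self.generations}")
        if not 0.0 < self.diff_factor <= 2.0:
            raise ValueError(f"diff_factor must be in (0, 2], got {self.diff_factor}")
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise ValueError(
                f"crossover_rate must be in [0, 1], got {self.crossover_rate}"
            )
        if self.stability_window < 0:
            raise ValueError("stability_window must be >= 0")


@dataclass
class DEResult:
    """Outcome of a DE run."""

    best: np.ndarray
    best_fitness: float
    trace: np.ndarray  # rows (generation, best, mean); generation 0 = init
    population: np.ndarray
    fitnesses: np.ndarray
    n_generations: int

    def trace_csv(self, path) -> None:
        np.savetxt(
            path,
            self.trace,
            delimiter=",",
            header="generation,best,mean",
            comments="",
            fmt=("%d", "%.17g", "%.17g"),
        )


def mutate(individuals, i: int, cfg: DEConfig, rng: np.random.Generator) -> np.ndarray:
    """Mutant vector V = X_r1 + F (X_r2 - X_r3), r1 != r2 != r3 != i."""
    x = np.asarray(individuals, dtype=float)
    if len(x) < 4:
        raise ValueError("mutation needs a population of at least 4")
    others = np.delete(np.arange(len(x)), i)
    r1, r2, r3 = rng.choice(others, size=3, replace=False)
    return x[r1] + cfg.diff_factor * (x[r2] - x[r3])


def crossover(
    target, mutant, cfg: DEConfig, rng: np.random.Generator
) -> np.ndarray:
    """Binomial crossover: U_j = V_j where r_j <= CR, else X_j.

    Unless ``cfg.pure_binomial``, one component chosen uniformly at random
    always comes from the mutant, so the trial differs from the target
    whenever the mutant does.
    """
    x = np.asarray(target, dtype=float)
    v = np.asarray(mutant, dtype=float)
    if x.shape != v.shape:
        raise ValueError(f"dimensionality mismatch: {x.shape} vs {v.shape}")
    take = rng.random(x.shape[0]) <= cfg.crossover_rate
    if not cfg.pure_binomial:
        take[rng.integers(x.shape[0])] = True
    return np.where(take, v, x)


def _safe(value: float) -> float:
    return float(value) if np.isfinite(value) else np.inf


def select(target, trial, f) -> np.ndarray:
    """Greedy selection: return trial iff f(trial) < f(target) (strict).

    Non-finite fitness values are treated as +inf and never selected.
    """
    target = np.asarray(target, dtype=float)
    trial = np.asarray(trial, dtype=float)
    return trial if _safe(f(trial)) < _safe(f(target)) else target


def run_de(
    f,
    bounds,
    cfg: DEConfig,
    init=None,
    repair=None,
    rng: np.random.Generator | None = None,
) -> DEResult:
    """Minimize ``f`` over a box with rand/1/bin differential evolution.

    Parameters
    ----------
    f : callable
        Scalar fitness ``f(x) -> float``, minimized.  Non-finite values are
        treated as +inf.
    bounds : sequence of (lo, hi)
        Finite per-dimension intervals.
    init : (Np, d) array, optional
        Initial population; drawn uniformly inside the bounds when omitted.
    repair : callable, optional
        Mapping applied to every trial vector before evaluation; defaults
        to clipping onto the bounds.
    rng : numpy Generator, optional
        Overrides ``cfg.seed`` as the randomness source.
    """
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2 or bounds.shape[0] < 1:
        raise ValueError("bounds must be a non-empty sequence of (lo, hi) pairs")
    if not np.all(np.isfinite(bounds)):
        raise ValueError("bounds must be finite")
    lo, hi = bounds[:, 0], bounds[:, 1]
    if np.any(lo > hi):
        raise ValueError("each bound must satisfy lo <= hi")
    d = len(bounds)
    np_ = cfg.pop_size
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if repair is None:
        repair = lambda v: np.clip(v, lo, hi)  # noqa: E731

    if init is None:
        pop = lo + rng.random((np_, d)) * (hi - lo)
    else:
        pop = np.array(init, dtype=float)
        if pop.shape != (np_, d):
            raise ValueError(
                f"init must have shape ({np_}, {d}), got {pop.shape}"
            )
        if np.any(pop < lo) or np.any(pop > hi):
            raise ValueError("init population violates bounds")

    fit = np.array([_safe(f(x)) for x in pop])
    trace = [(0, float(fit.min()), float(fit.mean()))]
    stable = 0
    gens_run = 0
    for g in range(1, cfg.generations + 1):
        prev_best = fit.min()
        for i in range(np_):
            v = mutate(pop, i, cfg, rng)
            u = crossover(pop[i], v, cfg, rng)
            u = np.asarray(repair(u), dtype=float)
            fu = _safe(f(u))
            if fu < fit[i]:
                pop[i] = u
                fit[i] = fu
        trace.append((g, float(fit.min()), float(fit.mean())))
        gens_run = g
        if cfg.stability_window:
            stable = stable + 1 if fit.min() == prev_best else 0
            if stable >= cfg.stability_window:
                break

    best_i = int(np.argmin(fit))
    return DEResult(
        best=pop[best_i].copy(),
        best_fitness=float(fit[best_i]),
        trace=np.asarray(trace, dtype=float),
        population=pop,
        fitnesses=fit,
        n_generations=gens_run,
    )


def spawn_config(cfg: DEConfig, **overrides) -> DEConfig:
    """Copy a config with field overrides (convenience for callers)."""
    return replace(cfg, **overrides)
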