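"""Genetic-algorithm estimation of the 16 conductance multipliers.

The GA matches a candidate cell's simulated AP/CaT traces to target
recordings of a candidate protocol by summed mean-squared error, evaluated
on the common 0.1 ms grid over the included channels and conditions.  A
generational GA with tournament selection, blend crossover and Gaussian
mutation in log-multiplier space searches the multiplier box [0.1, 10];
elitism makes the best-so-far fitness non-increasing.  The best individual
of the final population is the calibrated parameter set.

Degenerate candidates (quiescent traces, integrator failures, wall-clock
timeouts) receive a sentinel worst fitness instead of raising, keeping the
GA loop total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np

from .constants import CONDUCTANCE_NAMES
from .model_core import ConductanceSet, ModelError, SolverSettings
from .protocols import (
    DegenerateSignalError,
    Protocol,
    Recording,
    normalize,
    run_protocol,
)

__all__ = [
    "GAConfig", "CalibrationResult", "ConfigurationError",
    "WORST_FITNESS", "fitness", "run_ga", "run_replicates",
]

log = logging.getLogger(__name__)

#: sentinel fitness for candidates that cannot be evaluated
WORST_FITNESS = 1e12


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class GAConfig:
    """GA settings; the defaults are standard robust choices for a
    ~16-dimensional continuous search."""

    population_size: int = 200
    generations: int = 20
    bounds: tuple[float, float] = (0.1, 10.0)
    tournament_size: int = 3
    crossover_rate: float = 0.9
    crossover_alpha: float = 0.5
    mutation_rate: float = 0.1
    mutation_sigma: float = 0.1  # in natural-log multiplier units
    elite_count: int = 2
    replicate_count: int = 10
    base_seed: int = 0
    #: subset of parameters searched; the rest are clamped to the base cell
    free_parameters: tuple[str, ...] = CONDUCTANCE_NAMES
    n_jobs: int = 1

    def __post_init__(self):
        if self.generations < 1:
            raise ConfigurationError("generations must be >= 1")
        lo, hi = self.bounds
        if not (0 < lo < hi):
            raise ConfigurationError("bounds must be positive with lo < hi")
        if self.replicate_count < 1:
            raise ConfigurationError("replicate count must be >= 1")
        if self.population_size < 1:
            raise ConfigurationError("population size must be >= 1")
        unknown = set(self.free_parameters) - set(CONDUCTANCE_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown parameters: {sorted(unknown)}")
        if not self.free_parameters:
            raise ConfigurationError("at least one free parameter required")

    def replace(self, **kw) -> "GAConfig":
        return _dc_replace(self, **kw)


@dataclass
class CalibrationResult:
    """One GA run: the fitted cell plus its convergence trajectory."""

    fitted: ConductanceSet
    final_fitness: float
    best_fitness_per_generation: list[float]
    mean_fitness_per_generation: list[float]
    seed: int
    protocol_name: str
    channels: tuple[str, ...]
    flags: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# fitness
# ---------------------------------------------------------------------------

def _align_lag_samples(target_v: np.ndarray, cand_v: np.ndarray) -> int:
    """Circular lag (in samples) maximizing cross-correlation of the voltage
    channels, on a 10x decimated grid for speed."""
    step = 10
    a = target_v[::step] - target_v[::step].mean()
    b = cand_v[::step] - cand_v[::step].mean()
    n = min(a.size, b.size)
    a, b = a[:n], b[:n]
    fa = np.fft.rfft(a)
    fb = np.fft.rfft(b)
    xc = np.fft.irfft(fa * np.conj(fb), n)
    return int(np.argmax(xc)) * step


def _mse_pair(target: Recording, cand: Recording,
              channels: tuple[str, ...]) -> float:
    if target.n_samples != cand.n_samples:
        raise ValueError("target and candidate grids differ")
    # spontaneous phase is arbitrary: circularly align on the V channel
    if not (target.pacing is not None and target.pacing.is_paced):
        lag = _align_lag_samples(target.vm, cand.vm)
        vm = np.roll(cand.vm, lag)
        cai = np.roll(cand.cai, lag)
    else:
        vm, cai = cand.vm, cand.cai
    total = 0.0
    for ch in channels:
        x = target.vm if ch == "v" else target.cai
        y = vm if ch == "v" else cai
        total += float(np.mean((x - y) ** 2))
    return total


def _check_channels(channels) -> tuple[str, ...]:
    channels = tuple(channels)
    if not channels:
        raise ConfigurationError("channel subset must not be empty")
    bad = set(channels) - {"v", "ca"}
    if bad:
        raise ConfigurationError(f"unknown channels {sorted(bad)}")
    return channels


def fitness(candidate: ConductanceSet, target: list[Recording], p: Protocol,
            channels=("v", "ca"), normalized: bool | None = None,
            solver: SolverSettings | None = None) -> float:
    """Summed MSE between the candidate's simulated protocol traces and the
    target recordings.

    ``normalized=None`` follows the targets' own flag.  Simulation failure,
    timeout or a degenerate (flat) candidate trace yields
    :data:`WORST_FITNESS`.
    """
    channels = _check_channels(channels)
    if len(target) != len(p.conditions):
        raise ValueError("target recordings do not align with the protocol")
    if normalized is None:
        normalized = bool(target[0].normalized)
    solver = solver or SolverSettings()
    try:
        recs = run_protocol(candidate, p, solver=solver)
        total = 0.0
        for tgt, rec in zip(target, recs):
            # degenerate-trace policy: a quiescent candidate (no AP-scale
            # voltage excursion in the raw mV trace) is worst, not an error
            if float(np.ptp(rec.vm)) < 10.0:
                return WORST_FITNESS
            if normalized:
                rec = normalize(rec)
            total += _mse_pair(tgt, rec, channels)
        return total
    except (ModelError, DegenerateSignalError):
        return WORST_FITNESS


# ---------------------------------------------------------------------------
# the genetic algorithm
# ---------------------------------------------------------------------------

def _genome_to_cell(genome: np.ndarray, free: tuple[str, ...],
                    base: ConductanceSet) -> ConductanceSet:
    return base.replace(**{name: float(np.exp(g))
                           for name, g in zip(free, genome)})


def run_ga(target: list[Recording], p: Protocol, channels, cfg: GAConfig,
           seed: int, base: ConductanceSet | None = None,
           solver: SolverSettings | None = None,
           normalized: bool | None = None,
           initial_population: np.ndarray | None = None) -> CalibrationResult:
    """One GA run, reproducible from ``seed``.

    ``base`` supplies the values of clamped (non-free) parameters, defaulting
    to the baseline cell.  ``initial_population`` (log-multiplier genomes,
    shape ``(population_size, n_free)``) overrides the random log-uniform
    initialization.  Fitness evaluations are independent of evaluation
    order.
    """
    channels = _check_channels(channels)
    base = base or ConductanceSet.baseline()
    rng = np.random.default_rng(seed)
    free = tuple(cfg.free_parameters)
    ndim = len(free)
    log_lo, log_hi = np.log(cfg.bounds[0]), np.log(cfg.bounds[1])

    def evaluate(pop: np.ndarray) -> np.ndarray:
        cells = [_genome_to_cell(g, free, base) for g in pop]
        if cfg.n_jobs != 1:
            from joblib import Parallel, delayed

            vals = Parallel(n_jobs=cfg.n_jobs)(
                delayed(fitness)(c, target, p, channels, normalized, solver)
                for c in cells)
        else:
            vals = [fitness(c, target, p, channels, normalized, solver)
                    for c in cells]
        return np.asarray(vals, dtype=float)

    if initial_population is not None:
        pop = np.array(initial_population, dtype=float)
        if pop.shape != (cfg.population_size, ndim):
            raise ConfigurationError(
                f"initial population must be {(cfg.population_size, ndim)}")
    else:
        pop = rng.uniform(log_lo, log_hi, size=(cfg.population_size, ndim))
    fit = evaluate(pop)
    if np.all(fit >= WORST_FITNESS):
        raise RuntimeError(
            "every individual of the initial population evaluated to the "
            "sentinel worst fitness; check search bounds, protocol duration "
            "and target/protocol consistency")

    best_per_gen, mean_per_gen = [], []
    n_worst = int(np.sum(fit >= WORST_FITNESS))
    elite_n = min(cfg.elite_count, cfg.population_size)
    for gen in range(cfg.generations):
        order = np.argsort(fit, kind="stable")
        pop, fit = pop[order], fit[order]
        best_per_gen.append(float(fit[0]))
        mean_per_gen.append(float(np.mean(fit)))
        log.info("GA seed=%d gen=%d best=%.6g mean=%.6g", seed, gen,
                 best_per_gen[-1], mean_per_gen[-1])
        if gen == cfg.generations - 1:
            break

        def tournament() -> np.ndarray:
            idx = rng.integers(0, cfg.population_size, cfg.tournament_size)
            return pop[idx[np.argmin(fit[idx])]].copy()

        children = []
        while len(children) < cfg.population_size - elite_n:
            p1, p2 = tournament(), tournament()
            if rng.random() < cfg.crossover_rate:
                # per-gene blend (BLX-alpha) in log space
                lo = np.minimum(p1, p2)
                hi = np.maximum(p1, p2)
                span = hi - lo
                c1 = rng.uniform(lo - cfg.crossover_alpha * span,
                                 hi + cfg.crossover_alpha * span)
                c2 = rng.uniform(lo - cfg.crossover_alpha * span,
                                 hi + cfg.crossover_alpha * span)
            else:
                c1, c2 = p1, p2
            for child in (c1, c2):
                mask = rng.random(ndim) < cfg.mutation_rate
                child = child + mask * rng.normal(0, cfg.mutation_sigma, ndim)
                children.append(np.clip(child, log_lo, log_hi))
        offspring = np.asarray(children[:cfg.population_size - elite_n])
        off_fit = evaluate(offspring)
        n_worst += int(np.sum(off_fit >= WORST_FITNESS))
        pop = np.vstack([pop[:elite_n], offspring])
        fit = np.concatenate([fit[:elite_n], off_fit])

    order = np.argsort(fit, kind="stable")
    best = pop[order[0]]
    return CalibrationResult(
        fitted=_genome_to_cell(best, free, base),
        final_fitness=float(fit[order[0]]),
        best_fitness_per_generation=best_per_gen,
        mean_fitness_per_generation=mean_per_gen,
        seed=seed,
        protocol_name=p.name,
        channels=channels,
        flags={"worst_fitness_evaluations": n_worst},
    )


def run_replicates(target: list[Recording], p: Protocol, channels,
                   cfg: GAConfig, base: ConductanceSet | None = None,
                   solver: SolverSettings | None = None,
                   normalized: bool | None = None) -> list[CalibrationResult]:
    """``cfg.replicate_count`` independent GA runs; replicate k uses seed
    ``cfg.base_seed + k`` and therefore an independent initial population."""
    return [
        run_ga(target, p, channels, cfg, seed=cfg.base_seed + k, base=base,
               solver=solver, normalized=normalized)
        for k in range(cfg.replicate_count)
    ]
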