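"""Objective function over the measured metabolite set and its GA minimizer.

The objective compares model steady states against experimental (or
synthetic) metabolite concentrations for the five measured species
M = {AA, 5-HPETE, 15-HPETE, 15-HETE, PGD2}, summed over the control and the
DDC-treated condition of one strain:

    f(p) = sum_{x in M} (ec_x - sc_x(p))^2 + (ed_x - sd_x(p))^2

where ec/ed are experimental and sc/sd simulated steady-state
concentrations.  f is minimized with a seeded genetic algorithm over
log-scaled kinetic parameters: tournament selection (k=2), uniform
crossover (rate 0.7), per-gene log-normal mutation (rate 0.1), elitism of
one.  Population 50 and 500 generations mirror the published optimization
settings; smaller runs are supported for quick studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import KineticModel, StrainCondition, build_paper_model
from .simulate import DEFAULT_TOL, simulate_condition, steady_state

__all__ = [
    "METABOLITE_SET_M",
    "ObjectiveSpec",
    "FitResult",
    "FitError",
    "default_parameter_space",
    "objective",
    "fit_genetic",
]

#: the five measured metabolites entering the objective
METABOLITE_SET_M = ("AA", "5-HPETE", "15-HPETE", "15-HETE", "PGD2")

#: finite penalty returned when a candidate's steady state does not converge
NONCONVERGENCE_PENALTY = 1e12

#: parameters excluded from fitting by default (literature-sourced)
_EXCLUDED = {("R1", "k_m")}


class FitError(RuntimeError):
    """No candidate in the population produced a convergent steady state."""


@dataclass(frozen=True)
class ObjectiveSpec:
    experimental_control: Mapping[str, float]  # ec, nM
    experimental_ddc: Mapping[str, float]      # ed, nM
    control_condition: StrainCondition
    ddc_condition: StrainCondition
    parameter_space: tuple[tuple[str, str, float, float], ...]  # (rxn, name, lo, hi)
    metabolite_set: tuple[str, ...] = METABOLITE_SET_M

    def __post_init__(self) -> None:
        if tuple(self.metabolite_set) != METABOLITE_SET_M:
            raise ValueError(
                f"the objective is defined over {METABOLITE_SET_M}, got {self.metabolite_set}"
            )
        for table, label in ((self.experimental_control, "control"),
                             (self.experimental_ddc, "DDC")):
            missing = set(self.metabolite_set) - set(table)
            if missing:
                raise ValueError(f"{label} data lacks metabolites {sorted(missing)}")
        for rxn, name, lo, hi in self.parameter_space:
            if not (0 < lo < hi):
                raise ValueError(f"bad bounds for {rxn}.{name}: [{lo}, {hi}]")


@dataclass(frozen=True)
class FitResult:
    best_parameters: Mapping[tuple[str, str], float]
    best_objective: float
    generation_trace: tuple[float, ...]  # best-so-far objective per generation
    seed: int

    def __post_init__(self) -> None:
        tr = np.asarray(self.generation_trace)
        if tr.size and np.any(np.diff(tr) > 0):
            raise ValueError("generation trace must be non-increasing (elitist GA)")


def default_parameter_space(
    model: KineticModel | None = None,
    span: float = 100.0,
) -> tuple[tuple[str, str, float, float], ...]:
    """Bounds [value/span, value*span] around every fitted kinetic constant.

    R1's Michaelis constant is literature-sourced and excluded by default.
    """
    model = build_paper_model() if model is None else model
    space = []
    for rxn in model.reactions:
        rl = rxn.rate_law
        for name in ("v_max", "k_m", "k_i", "k_cat"):
            v = getattr(rl, name)
            if v is None or (rxn.id, name) in _EXCLUDED:
                continue
            space.append((rxn.id, name, v / span, v * span))
    return tuple(space)


def _apply(model: KineticModel, spec: ObjectiveSpec, values: Sequence[float]) -> KineticModel:
    if len(values) != len(spec.parameter_space):
        raise ValueError("parameter vector length does not match parameter space")
    out = model
    for (rxn, name, lo, hi), v in zip(spec.parameter_space, values):
        if not (lo * (1 - 1e-9) <= v <= hi * (1 + 1e-9)):
            raise ValueError(f"{rxn}.{name}={v} outside bounds [{lo}, {hi}]")
        out = out.with_parameter(rxn, name, float(min(max(v, lo), hi)))
    return out


def objective(
    parameters: Sequence[float],
    spec: ObjectiveSpec,
    model: KineticModel | None = None,
    tol: float = DEFAULT_TOL,
    _warm: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """Sum of squared steady-state residuals over both conditions.

    Non-convergence of either steady state yields a large finite penalty so
    a population-based optimizer can keep going.
    """
    base = build_paper_model() if model is None else model
    candidate = _apply(base, spec, parameters)
    total = 0.0
    warm_c, warm_d = _warm if _warm is not None else (None, None)
    for cond, data, warm in (
        (spec.control_condition, spec.experimental_control, warm_c),
        (spec.ddc_condition, spec.experimental_ddc, warm_d),
    ):
        res = steady_state(
            candidate, tol=tol,
            activities=cond.activity_ratios, pc_nM=cond.pc_nM,
            _newton_start=warm, fast=_warm is not None,
        )
        if not res.converged:
            return NONCONVERGENCE_PENALTY
        for m in spec.metabolite_set:
            total += (data[m] - res.concentrations[m]) ** 2
    return total


def fit_genetic(
    spec: ObjectiveSpec,
    population_size: int = 50,
    generations: int = 500,
    seed: int = 0,
    model: KineticModel | None = None,
    crossover_rate: float = 0.7,
    mutation_rate: float = 0.1,
    mutation_sigma: float | tuple[float, float] = (0.5, 1e-3),
    immigrant_fraction: float = 0.1,
    initial_population: Sequence[Sequence[float]] | None = None,
    tol: float = DEFAULT_TOL,
) -> FitResult:
    """Minimize the objective with an elitist genetic algorithm.

    Genes are log10-transformed parameter values, clipped to the declared
    bounds.  Deterministic for a fixed seed.  `initial_population` rows (raw
    parameter values) seed part of the first generation, e.g. to inject a
    known candidate.

    `mutation_sigma` is the standard deviation of the log-normal mutation
    step; a (start, end) pair anneals it geometrically over the
    generations, so the search is exploratory early and refining late.
    `immigrant_fraction` of each generation is replaced by fresh uniform
    draws (random immigrants), which guards against premature convergence
    into secondary basins while elitism retains the incumbent best.
    """
    if population_size < 2:
        raise ValueError("population_size must be >= 2")
    if generations < 1:
        raise ValueError("generations must be >= 1")
    rng = np.random.default_rng(seed)
    base = build_paper_model() if model is None else model
    lo = np.log10([b[2] for b in spec.parameter_space])
    hi = np.log10([b[3] for b in spec.parameter_space])
    ngene = len(spec.parameter_space)

    # warm starts: solve both conditions once at the base parameterization
    warm = []
    for cond in (spec.control_condition, spec.ddc_condition):
        r = simulate_condition(base, cond, tol=tol)
        warm.append(r.vector(base.state_ids) if r.converged else None)
    warm = tuple(warm)

    pop = rng.uniform(lo, hi, size=(population_size, ngene))
    if initial_population is not None:
        injected = np.log10(np.asarray(initial_population, dtype=float))
        k = min(len(injected), population_size)
        pop[:k] = np.clip(injected[:k], lo, hi)

    def evaluate(genes: np.ndarray) -> float:
        return objective(10.0 ** genes, spec, model=base, tol=tol, _warm=warm)

    fitness = np.array([evaluate(g) for g in pop])
    if np.all(fitness >= NONCONVERGENCE_PENALTY):
        raise FitError("no convergent candidate in the initial population")
    best_idx = int(np.argmin(fitness))
    best_genes, best_f = pop[best_idx].copy(), float(fitness[best_idx])
    trace = [best_f]

    if isinstance(mutation_sigma, (int, float)):
        sigma_start = sigma_end = float(mutation_sigma)
    else:
        sigma_start, sigma_end = map(float, mutation_sigma)

    for gen in range(generations - 1):
        frac = gen / max(generations - 2, 1)
        sigma = sigma_start * (sigma_end / sigma_start) ** frac
        children = np.empty_like(pop)
        children[0] = best_genes  # elitism of 1
        for j in range(1, population_size):
            # tournament selection, k=2
            a, b = rng.integers(population_size, size=2)
            p1 = pop[a] if fitness[a] <= fitness[b] else pop[b]
            a, b = rng.integers(population_size, size=2)
            p2 = pop[a] if fitness[a] <= fitness[b] else pop[b]
            child = p1.copy()
            if rng.random() < crossover_rate:  # uniform crossover
                mask = rng.random(ngene) < 0.5
                child[mask] = p2[mask]
            mut = rng.random(ngene) < mutation_rate  # log-normal mutation
            child[mut] += rng.normal(0.0, sigma, size=int(mut.sum()))
            children[j] = np.clip(child, lo, hi)
        n_imm = int(round(immigrant_fraction * population_size))
        if n_imm and population_size > 1 + n_imm:
            children[-n_imm:] = rng.uniform(lo, hi, size=(n_imm, ngene))
        pop = children
        fitness = np.array([evaluate(g) for g in pop])
        gen_best = int(np.argmin(fitness))
        if fitness[gen_best] < best_f:
            best_f = float(fitness[gen_best])
            best_genes = pop[gen_best].copy()
        trace.append(best_f)

    params = {
        (rxn, name): float(v)
        for (rxn, name, _, _), v in zip(spec.parameter_space, 10.0 ** best_genes)
    }
    return FitResult(params, best_f, tuple(trace), seed)
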