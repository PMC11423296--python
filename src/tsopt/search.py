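"""Recursive subset search over candidate training sets.

A single fixed-size-subset genetic algorithm (tournament selection,
union-repair crossover, swap mutation, elitism) serves every criterion.
Because the search is stochastic, the composition of the best subset can
vary between runs; :func:`consensus_select` repeats the search many times
(50 by default) with split seeds and keeps the candidates most frequently
included across runs.  :func:`core_collection` runs the same machinery on
the entry-to-nearest-entry objective and reports the diversity statistics
of the selected core.
"""

from __future__ import annotations

import dataclasses
import itertools
from math import comb

import numpy as np

from .criteria import CriterionContext, evaluate, signed_score
from .genotypes import GenotypeMatrix
from .kinship import allele_coverage, expected_heterozygosity

__all__ = [
    "GAConfig",
    "ConsensusResult",
    "ga_optimize",
    "exhaustive_optimize",
    "consensus_select",
    "core_collection",
]


@dataclasses.dataclass
class GAConfig:
    population_size: int = 100
    n_generations: int = 300
    mutation_rate: float = 0.3
    elitism: int = 2
    n_runs: int = 50
    convergence_window: int = 50
    tournament_size: int = 3
    n_immigrants: int = 2
    local_search_limit: int = 4000  # max size*(pool-size) for the final polish
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.mutation_rate < 1.0:
            raise ValueError("mutation_rate must lie in (0, 1)")
        if self.elitism >= self.population_size:
            raise ValueError("elitism must be smaller than population_size")


@dataclasses.dataclass
class ConsensusResult:
    criterion: str
    frequency: np.ndarray  # per-candidate inclusion count across runs
    final_set: np.ndarray
    per_run_best: list[float]
    traces: list[np.ndarray]
    consistency: float  # mean frequency of the final set / n_runs
    candidates: np.ndarray


def _subset_key(s: np.ndarray) -> tuple:
    return tuple(np.sort(s))


def ga_optimize(
    criterion: str,
    size: int,
    candidates,
    test,
    ctx: CriterionContext,
    config: GAConfig | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Genetic-algorithm search for the best fixed-size training subset.

    Returns the best subset found (sorted candidate indices) and the
    per-generation trace of the best value seen so far on the signed
    to-maximize scale (minimize criteria are negated, so the trace is
    always non-decreasing).  The search stops early after
    ``convergence_window`` generations without improvement.  Deterministic
    for a fixed seed.
    """
    config = config or GAConfig()
    candidates = np.asarray(candidates, dtype=int)
    if size >= candidates.size:
        raise ValueError("subset size must be smaller than the candidate pool")
    if size < 2:
        raise ValueError("subset size must be at least 2")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    def score(sub: np.ndarray) -> float:
        # canonical (sorted) order so the value is independent of encoding
        return signed_score(criterion, candidates[np.sort(sub)], ctx, test)

    pop = [rng.permutation(candidates.size)[:size] for _ in range(config.population_size)]
    fitness = np.array([score(s) for s in pop])
    best_i = int(fitness.argmax())
    best, best_fit = pop[best_i].copy(), float(fitness[best_i])
    trace = [best_fit]
    stagnant = 0

    for _ in range(config.n_generations):
        order = np.argsort(fitness)[::-1]
        new_pop = [pop[i].copy() for i in order[: config.elitism]]
        for _ in range(config.n_immigrants):
            if len(new_pop) < config.population_size:
                new_pop.append(rng.permutation(candidates.size)[:size])
        while len(new_pop) < config.population_size:
            a = _tournament(rng, fitness, config.tournament_size)
            b = _tournament(rng, fitness, config.tournament_size)
            child = _crossover(rng, pop[a], pop[b], size)
            if rng.random() < config.mutation_rate:
                _swap_mutate(rng, child, candidates.size)
            new_pop.append(child)
        pop = new_pop
        fitness = np.array([score(s) for s in pop])
        gen_best = int(fitness.argmax())
        if fitness[gen_best] > best_fit:
            best_fit = float(fitness[gen_best])
            best = pop[gen_best].copy()
            stagnant = 0
        else:
            stagnant += 1
        trace.append(best_fit)
        if stagnant >= config.convergence_window:
            break

    if size * (candidates.size - size) <= config.local_search_limit:
        best, best_fit = _polish(best, best_fit, score, candidates.size, rng)
        trace[-1] = best_fit

    if not np.isfinite(best_fit):
        raise RuntimeError(
            f"no feasible subset found for criterion {criterion!r} "
            "(e.g. empty multiple-design band)"
        )
    return np.sort(candidates[best]), np.asarray(trace)


def _local_search(best: np.ndarray, best_fit: float, score, n: int):
    """First-improvement swap descent until no swap improves the subset."""
    improved = True
    while improved:
        improved = False
        outside = np.setdiff1d(np.arange(n), best)
        for i in range(best.size):
            for c in outside:
                probe = best.copy()
                probe[i] = c
                val = score(probe)
                if val > best_fit + 1e-15:
                    best, best_fit = probe, val
                    improved = True
                    break  # neighborhood is stale: restart the pass
            if improved:
                break
    return best, best_fit


def _polish(best, best_fit, score, n: int, rng, n_restarts: int = 50):
    """Memetic refinement: iterated local search around the GA optimum.

    Swap descent alone can stall in a local optimum of the one-swap
    neighborhood, so the descent is repeated from double-swap
    perturbations of the incumbent, keeping the best subset seen.
    """
    best, best_fit = _local_search(best, best_fit, score, n)
    for _ in range(n_restarts):
        probe = best.copy()
        for _ in range(2):
            _swap_mutate(rng, probe, n)
        probe, probe_fit = _local_search(probe, score(probe), score, n)
        if probe_fit > best_fit:
            best, best_fit = probe, probe_fit
    return best, best_fit


def _tournament(rng, fitness: np.ndarray, k: int) -> int:
    contenders = rng.integers(0, fitness.size, size=k)
    return int(contenders[np.argmax(fitness[contenders])])


def _crossover(rng, a: np.ndarray, b: np.ndarray, size: int) -> np.ndarray:
    union = np.union1d(a, b)
    return rng.choice(union, size=size, replace=False)


def _swap_mutate(rng, sub: np.ndarray, n: int) -> None:
    outside = np.setdiff1d(np.arange(n), sub, assume_unique=False)
    if outside.size:
        sub[rng.integers(sub.size)] = outside[rng.integers(outside.size)]


def exhaustive_optimize(
    criterion: str, size: int, candidates, test, ctx: CriterionContext
) -> tuple[np.ndarray, float]:
    """Enumerate every subset; the oracle for small instances."""
    candidates = np.asarray(candidates, dtype=int)
    best, best_val = None, -np.inf
    for combo in itertools.combinations(range(candidates.size), size):
        val = signed_score(criterion, candidates[list(combo)], ctx, test)
        if val > best_val:
            best_val, best = val, np.array(combo)
    if best is None or not np.isfinite(best_val):
        raise RuntimeError(f"no feasible subset for criterion {criterion!r}")
    return np.sort(candidates[best]), best_val


def consensus_select(
    criterion: str,
    size: int,
    candidates,
    test,
    ctx: CriterionContext,
    config: GAConfig | None = None,
) -> ConsensusResult:
    """Multi-run consensus: repeat the search and keep frequent members.

    The search runs ``config.n_runs`` times with seeds split from the
    master seed; each candidate's inclusion count across runs is tallied
    and the final set is the ``size`` most frequent candidates.  Ties at
    the cutoff frequency are broken by (1) the higher criterion value of
    the above-cutoff members plus the tied candidate, then (2) the lower
    candidate index.  The consistency score is the mean frequency of the
    final set divided by the number of runs.
    """
    config = config or GAConfig()
    if config.n_runs < 2:
        raise ValueError("consensus requires n_runs >= 2")
    candidates = np.asarray(candidates, dtype=int)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_runs)
    counts = np.zeros(candidates.size, dtype=int)
    pos = {c: i for i, c in enumerate(candidates)}
    per_run_best, traces = [], []
    for ss in seeds:
        best, trace = ga_optimize(
            criterion, size, candidates, test, ctx, config, seed=ss
        )
        for c in best:
            counts[pos[c]] += 1
        per_run_best.append(float(trace[-1]))
        traces.append(trace)

    final = _by_frequency(criterion, size, candidates, counts, test, ctx)
    consistency = float(counts[[pos[c] for c in final]].mean() / config.n_runs)
    return ConsensusResult(
        criterion=criterion,
        frequency=counts,
        final_set=final,
        per_run_best=per_run_best,
        traces=traces,
        consistency=consistency,
        candidates=candidates,
    )


def _by_frequency(criterion, size, candidates, counts, test, ctx) -> np.ndarray:
    order = np.argsort(-counts, kind="stable")
    cutoff = counts[order[size - 1]]
    sure = candidates[counts > cutoff]
    tied = candidates[counts == cutoff]
    n_need = size - sure.size
    if tied.size > n_need:
        # rank tied candidates by the criterion value of sure + candidate
        def tie_value(c: int) -> float:
            probe = np.concatenate([sure, [c]])
            if probe.size < 2:
                probe = np.concatenate([probe, tied[tied != c][:1]])
            try:
                return signed_score(criterion, probe, ctx, test)
            except (ValueError, np.linalg.LinAlgError):
                return -np.inf

        ranked = sorted(tied, key=lambda c: (-tie_value(int(c)), int(c)))
        tied = np.array(ranked[:n_need], dtype=int)
    return np.sort(np.concatenate([sure, tied[:n_need]]).astype(int))


def core_collection(
    size: int,
    candidates,
    ctx: CriterionContext,
    genotypes: GenotypeMatrix | None = None,
    config: GAConfig | None = None,
    exhaustive_limit: int = 20000,
) -> tuple[np.ndarray, float | None, float | None]:
    """Select a maximally diverse core by the entry-to-nearest-entry rule.

    Maximizes the mean distance from each selected entry to its nearest
    selected neighbour (exhaustively when the instance is small enough,
    by GA otherwise).  When the genotype matrix is supplied, the expected
    heterozygosity and the allele-coverage percentage of the core are
    reported alongside.  A targeted scenario is expressed by restricting
    ``candidates`` to the non-excluded group.
    """
    candidates = np.asarray(candidates, dtype=int)
    if size == candidates.size:
        core = np.sort(candidates)
    elif comb(candidates.size, size) <= exhaustive_limit:
        core, _ = exhaustive_optimize("ene", size, candidates, None, ctx)
    else:
        core, _ = ga_optimize("ene", size, candidates, None, ctx, config)
    he = cv = None
    if genotypes is not None:
        he = expected_heterozygosity(genotypes, core)
        cv = allele_coverage(genotypes, core)
    return core, he, cv
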