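"""Genetic-algorithm search for composite value ratios.

Each candidate biomarker is a genome: one code per atlas region, 0/1/2 for
numerator/excluded/denominator. The fitness of a genome is

    fitness = min(t_AB, t_cap) / SSE

where t_AB is the amyloid group-separation t-statistic from the all-data
model fit and SSE the (pre-ceiling) per-arm sample-size estimate from a fit
to the target subgroup (amyloid-positive, cognitively impaired or
unimpaired) under that group's trial design. The cap (default 2.6, the
upper 0.5% tail of a standard normal) stops the search trading group
separation against SSE along a Pareto front once separation is convincing.

The search is a generational GA with elitism, tournament selection, uniform
crossover and single-gene mutation; it is restarted from several seeds and
the best result kept. ``region_stability`` repeats the whole search on
random half-cohorts to measure how consistently each region is selected.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import RegionAtlas
from .biomarkers import DEN, EXC, NUM, CVRSpec, compute_cvr
from .model import AtrophyLMM
from .trial import DESIGN_CI, DESIGN_CU, TrialDesign, sample_size_estimate

WORST_FITNESS = -np.inf


@dataclass(frozen=True)
class GAConfig:
    """Search hyperparameters (defaults follow the standard configuration:
    population 32, elitism 2, mutation probability 0.5, at most 600
    generations with early stopping after 100 without improvement, three
    restarts, fitness cap 2.6)."""

    population_size: int = 32
    elitism: int = 2
    mutation_prob: float = 0.5
    max_generations: int = 600
    patience: int = 100
    n_restarts: int = 3
    t_cap: float = 2.6
    target_group: str = "CI"
    crossover_rate: float = 0.5
    tournament_size: int = 2
    init_probs: tuple[float, float, float] = (0.15, 0.70, 0.15)
    min_subjects: int = 10

    def __post_init__(self) -> None:
        if self.elitism >= self.population_size:
            raise ValueError("elitism must be < population_size")
        for name in ("population_size", "max_generations", "patience",
                     "n_restarts", "tournament_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.elitism < 0:
            raise ValueError("elitism must be >= 0")
        if self.t_cap <= 0:
            raise ValueError("t_cap must be > 0")
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation_prob must be in [0, 1]")
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise ValueError("crossover_rate must be in [0, 1]")
        if self.target_group not in ("CI", "CU"):
            raise ValueError("target_group must be 'CI' or 'CU'")
        if abs(sum(self.init_probs) - 1.0) > 1e-9:
            raise ValueError("init_probs must sum to 1")

    @property
    def target_dx(self) -> int:
        return 1 if self.target_group == "CI" else 0

    @property
    def design(self) -> TrialDesign:
        return DESIGN_CI if self.target_group == "CI" else DESIGN_CU


@dataclass(frozen=True)
class FitnessResult:
    """Evaluation of one genome."""

    genome: tuple[int, ...]
    spec: CVRSpec | None
    fitness: float
    t_ab: float | None = None
    sse: float | None = None
    t_converged: bool = False
    s_converged: bool = False

    def to_dict(self) -> dict:
        return {
            "genome": list(self.genome),
            "spec": None if self.spec is None else
            {"numerator": list(self.spec.numerator),
             "denominator": list(self.spec.denominator)},
            "fitness": None if not np.isfinite(self.fitness) else self.fitness,
            "t_ab": self.t_ab, "sse": self.sse,
            "t_converged": self.t_converged, "s_converged": self.s_converged,
        }


def _genome_valid(genome: np.ndarray) -> bool:
    return bool((genome == NUM).any() and (genome == DEN).any())


def capped_fitness(t_ab: float, sse: float, t_cap: float = 2.6) -> float:
    """The fitness rule: min(t_AB, cap) / SSE.

    The cap bounds the reward for group separation; there is no floor, so
    a separation in the wrong direction is penalised proportionally.
    """
    if sse <= 0:
        raise ValueError(f"sse must be > 0, got {sse}")
    return min(t_ab, t_cap) / sse


def fitness(
    genome,
    table: pd.DataFrame,
    atlas: RegionAtlas,
    config: GAConfig,
    cache: dict | None = None,
) -> FitnessResult:
    """Evaluate one genome; invalid genomes or failed fits get the
    worst-possible fitness so the search continues."""
    genome = np.asarray(genome, dtype=np.int8)
    key_genome = tuple(int(g) for g in genome)
    try:
        spec = CVRSpec.decode(genome, atlas)
    except (ValueError, KeyError):
        return FitnessResult(key_genome, None, WORST_FITNESS)

    cache_key = (spec.numerator, spec.denominator)
    if cache is not None and cache_key in cache:
        cached = cache[cache_key]
        return dataclasses.replace(cached, genome=key_genome)

    result = _evaluate_spec(spec, key_genome, table, config)
    if cache is not None:
        cache[cache_key] = result
    return result


def _evaluate_spec(
    spec: CVRSpec, key_genome, table: pd.DataFrame, config: GAConfig
) -> FitnessResult:
    try:
        series = compute_cvr(table, spec)
        full = AtrophyLMM(
            series, include_dx=True, include_ab=True,
            min_subjects=config.min_subjects,
        ).fit()
        t_ab = float(full.tvalues["time:AB"])
        sub = series[(series["AB"] == 1) & (series["DX"] == config.target_dx)]
        reduced = AtrophyLMM(
            sub, include_dx=False, include_ab=False,
            min_subjects=config.min_subjects,
        ).fit()
        sse = sample_size_estimate(reduced, config.design, ceiling=False)
    except (ValueError, KeyError, RuntimeError, np.linalg.LinAlgError):
        return FitnessResult(key_genome, spec, WORST_FITNESS)
    if not (full.converged and reduced.converged) or not np.isfinite(t_ab):
        return FitnessResult(
            key_genome, spec, WORST_FITNESS, t_ab=t_ab, sse=sse,
            t_converged=full.converged, s_converged=reduced.converged,
        )
    return FitnessResult(
        key_genome, spec, float(capped_fitness(t_ab, sse, config.t_cap)),
        t_ab=t_ab, sse=float(sse), t_converged=True, s_converged=True,
    )


def _random_genome(rng: np.random.Generator, size: int,
                   probs: tuple[float, float, float]) -> np.ndarray:
    # init_probs are (NUM, EXC, DEN) selection probabilities per gene
    return rng.choice(
        np.array([NUM, EXC, DEN], dtype=np.int8), size=size,
        p=[probs[0], probs[1], probs[2]],
    )


def _repair(genome: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Flip a random excluded gene into the missing composite; genomes
    that cannot be repaired are returned as-is (they draw the sentinel)."""
    for code in (NUM, DEN):
        if not (genome == code).any():
            exc_idx = np.flatnonzero(genome == EXC)
            if exc_idx.size == 0:
                return genome
            genome = genome.copy()
            genome[rng.choice(exc_idx)] = code
    return genome


def _tournament(rng: np.random.Generator, results: list[FitnessResult],
                k: int) -> np.ndarray:
    idx = rng.integers(0, len(results), size=k)
    best = max(idx, key=lambda i: (results[i].fitness, -i))
    return np.asarray(results[best].genome, dtype=np.int8)


def evolve(
    table: pd.DataFrame,
    atlas: RegionAtlas,
    config: GAConfig,
    seed: int,
    cache: dict | None = None,
    init_population: list | None = None,
    checkpoint_path=None,
) -> tuple[FitnessResult, list[dict]]:
    """Run one GA search; returns (best result, per-generation history).

    ``init_population`` overrides the random initial population (used for
    reproducibility tests); ``cache`` memoises fitness across generations
    and restarts keyed on the decoded composite sets.
    """
    rng = np.random.default_rng(seed)
    if cache is None:
        cache = {}
    size = len(atlas)

    if init_population is not None:
        population = [np.asarray(g, dtype=np.int8) for g in init_population]
        if len(population) != config.population_size:
            raise ValueError("init_population size must match population_size")
    else:
        population = []
        for _ in range(config.population_size):
            for _attempt in range(1000):
                g = _random_genome(rng, size, config.init_probs)
                if _genome_valid(g):
                    break
            else:
                raise RuntimeError(
                    "could not draw a valid genome; check init_probs/atlas size"
                )
            population.append(g)

    results = [fitness(g, table, atlas, config, cache) for g in population]
    if all(r.fitness == WORST_FITNESS for r in results):
        raise RuntimeError(
            "entire initial population evaluated to the worst sentinel; "
            "the table may lack the required groups or visits"
        )

    history: list[dict] = []
    best = max(results, key=lambda r: r.fitness)
    stale = 0
    generation = 0
    history.append({"generation": 0, "best_fitness": best.fitness})

    while generation < config.max_generations and stale < config.patience:
        generation += 1
        order = sorted(range(len(results)),
                       key=lambda i: (-results[i].fitness, i))
        elites = [np.asarray(results[i].genome, dtype=np.int8)
                  for i in order[: config.elitism]]
        offspring = list(elites)
        while len(offspring) < config.population_size:
            p1 = _tournament(rng, results, config.tournament_size)
            p2 = _tournament(rng, results, config.tournament_size)
            child = p1.copy()
            take2 = rng.random(size) < config.crossover_rate
            child[take2] = p2[take2]
            if rng.random() < config.mutation_prob:
                pos = rng.integers(0, size)
                choices = [c for c in (NUM, EXC, DEN) if c != child[pos]]
                child[pos] = choices[rng.integers(0, 2)]
            if not _genome_valid(child):
                child = _repair(child, rng)
            offspring.append(child)
        population = offspring
        results = [fitness(g, table, atlas, config, cache) for g in population]
        gen_best = max(results, key=lambda r: r.fitness)
        if gen_best.fitness > best.fitness:
            best = gen_best
            stale = 0
        else:
            stale += 1
        history.append({"generation": generation, "best_fitness": best.fitness})

    if checkpoint_path is not None:
        _write_checkpoint(checkpoint_path, config, seed, generation,
                          results, best)
    return best, history


def _write_checkpoint(path, config, seed, generation, results, best) -> None:
    payload = {
        "config": dataclasses.asdict(config),
        "seed": int(seed),
        "generation": int(generation),
        "population": [r.to_dict() for r in results],
        "best": best.to_dict(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def multistart(
    table: pd.DataFrame,
    atlas: RegionAtlas,
    config: GAConfig,
    seed: int,
    seeds: list[int] | None = None,
    cache: dict | None = None,
) -> FitnessResult:
    """Best-of-``n_restarts`` GA runs; ties broken by earliest seed."""
    if seeds is None:
        seeds = [int(seed) + i for i in range(config.n_restarts)]
    if cache is None:
        cache = {}
    best = None
    for s in seeds:
        result, _ = evolve(table, atlas, config, s, cache=cache)
        if best is None or result.fitness > best.fitness:
            best = result
    return best


def region_stability(
    table: pd.DataFrame,
    atlas: RegionAtlas,
    config: GAConfig,
    n_repeats: int = 100,
    frac: float = 0.5,
    seed: int = 0,
    max_redraws: int = 20,
) -> pd.DataFrame:
    """Selection frequency of each region over repeated half-cohort searches.

    Each repeat draws a stratified (by DX x AB) random ``frac`` of the
    subjects, reruns the multistart search, and records every region's
    assignment. Returns a frame indexed by region with columns
    ``NUM``/``DEN``/``EXC`` summing to 1 across each row.
    """
    if not 0 < frac <= 1:
        raise ValueError(f"frac must be in (0, 1], got {frac}")
    rng = np.random.default_rng(seed)
    subj = table.drop_duplicates("subject_id")[["subject_id", "DX", "AB"]]
    counts = pd.DataFrame(
        0.0, index=list(atlas.region_names), columns=["NUM", "DEN", "EXC"]
    )
    for _rep in range(n_repeats):
        for _try in range(max_redraws):
            chosen = []
            for _, grp in subj.groupby(["DX", "AB"]):
                k = max(1, int(round(frac * len(grp))))
                chosen.append(
                    grp["subject_id"].to_numpy()[
                        rng.choice(len(grp), size=k, replace=False)
                    ]
                )
            ids = np.concatenate(chosen)
            sub = table[table["subject_id"].isin(ids)]
            has_groups = (
                sub["AB"].nunique() == 2
                and ((sub["AB"] == 1) & (sub["DX"] == config.target_dx)).any()
            )
            if has_groups:
                break
        else:
            raise RuntimeError(
                "could not draw a subsample containing the required groups"
            )
        result = multistart(
            sub, atlas, config, seed=int(rng.integers(0, 2**31 - 1))
        )
        assignment = result.spec.assignment(atlas)
        for region, code in assignment.items():
            counts.loc[region, code] += 1.0
    return counts / n_repeats
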