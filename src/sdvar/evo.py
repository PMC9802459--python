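"""Forward Monte Carlo simulation of sex-specific stabilizing selection.

A diploid, dioecious, randomly mating population of fixed census size
evolves a quantitative trait (expression level) determined additively by
three unlinked loci — one shared between the sexes and one specific to each
sex (the opposite-sex locus is carried silently) — plus a standard-normal
environmental deviate redrawn each generation. Fitness is Gaussian
stabilizing selection around zero,

    w = exp(-s * P**2),  P = G + E,

with a sex-specific selection coefficient s acting on viability only.
Each generation: viability selection, then random sampling (with
replacement) of parent pairs that each produce a fixed number of offspring,
Mendelian transmission of one allele per parent per locus with free
recombination, and mutation that adds a standard-normal increment to one
allele of a locus at a fixed per-locus per-individual rate.

Recorded every few generations: phenotypic variance among males and among
females, and the variance of the shared-locus allelic effects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["EvoParams", "Population", "phenotype", "fitness", "viability_select",
           "reproduce", "mutate", "run_replicate", "run_replicates"]

SHARED, MALE_LOCUS, FEMALE_LOCUS = 0, 1, 2


@dataclass
class EvoParams:
    """Defaults are the study conditions: census 500, 100 pairs x 5 offspring,
    mutation 5e-3 per locus per individual per generation, 2000 generations,
    30 replicates; s = 0.005 in both sexes (equal condition) or 0.005/0.05
    male/female (sex-specific condition)."""

    pop_size: int = 500
    s_male: float = 0.005
    s_female: float = 0.005
    mut_rate: float = 5e-3
    n_parent_pairs: int = 100
    offspring_per_pair: int = 5
    n_generations: int = 2000
    record_every: int = 10
    n_replicates: int = 30
    seed: int = 0

    def validate(self) -> None:
        if self.n_parent_pairs * self.offspring_per_pair != self.pop_size:
            raise ValueError("n_parent_pairs * offspring_per_pair must equal pop_size")
        if not 0.0 <= self.mut_rate <= 1.0:
            raise ValueError("mut_rate must lie in [0, 1]")
        if self.s_male < 0 or self.s_female < 0:
            raise ValueError("selection coefficients must be nonnegative")


@dataclass
class Population:
    alleles: np.ndarray  # (N, 3, 2) allelic effects: shared, male, female locus
    male: np.ndarray  # (N,) bool
    E: np.ndarray  # (N,) environmental deviates


def init_population(params: EvoParams, rng) -> Population:
    N = params.pop_size
    male = np.zeros(N, dtype=bool)
    male[: N // 2] = True  # deterministic even split at initialization
    return Population(
        alleles=rng.standard_normal((N, 3, 2)),
        male=male,
        E=rng.standard_normal(N),
    )


def phenotype(pop: Population) -> np.ndarray:
    """P = shared-locus sum + own-sex-locus sum + E; the opposite-sex locus is silent."""
    shared = pop.alleles[:, SHARED, :].sum(axis=1)
    own = np.where(
        pop.male,
        pop.alleles[:, MALE_LOCUS, :].sum(axis=1),
        pop.alleles[:, FEMALE_LOCUS, :].sum(axis=1),
    )
    return shared + own + pop.E


def fitness(s, P) -> np.ndarray:
    """Gaussian stabilizing selection around an optimum of zero."""
    s = np.asarray(s, dtype=np.float64)
    if np.any(s < 0):
        raise ValueError("s must be nonnegative")
    return np.exp(-s * np.asarray(P, dtype=np.float64) ** 2)


def viability_select(pop: Population, params: EvoParams, rng, max_redraws: int = 100):
    """Bernoulli(w) survival with sex-specific s; redraw if a sex dies out."""
    P = phenotype(pop)
    s = np.where(pop.male, params.s_male, params.s_female)
    w = fitness(s, P)
    for _ in range(max_redraws + 1):
        alive = rng.random(len(w)) < w
        if (alive & pop.male).any() and (alive & ~pop.male).any():
            return np.flatnonzero(alive)
    raise RuntimeError("one sex repeatedly went extinct under selection; population not viable")


def reproduce(survivor_alleles_m, survivor_alleles_f, params: EvoParams, rng) -> Population:
    """Random pairing with replacement; Mendelian transmission, free recombination."""
    if len(survivor_alleles_m) < 1 or len(survivor_alleles_f) < 1:
        raise ValueError("need at least one surviving parent of each sex")
    npairs, k = params.n_parent_pairs, params.offspring_per_pair
    N = npairs * k
    fathers = rng.integers(0, len(survivor_alleles_m), size=npairs)
    mothers = rng.integers(0, len(survivor_alleles_f), size=npairs)
    fa = survivor_alleles_m[np.repeat(fathers, k)]  # (N, 3, 2)
    mo = survivor_alleles_f[np.repeat(mothers, k)]
    pat_pick = rng.integers(0, 2, size=(N, 3))
    mat_pick = rng.integers(0, 2, size=(N, 3))
    alleles = np.empty((N, 3, 2))
    alleles[:, :, 0] = np.take_along_axis(fa, pat_pick[:, :, None], axis=2)[:, :, 0]
    alleles[:, :, 1] = np.take_along_axis(mo, mat_pick[:, :, None], axis=2)[:, :, 0]
    return Population(
        alleles=alleles,
        male=rng.random(N) < 0.5,
        E=rng.standard_normal(N),
    )


def mutate(pop: Population, params: EvoParams, rng) -> Population:
    """With probability mut_rate per individual x locus, one random allele
    receives a standard-normal increment."""
    if params.mut_rate == 0:
        return pop
    N = len(pop.male)
    hit = rng.random((N, 3)) < params.mut_rate
    which = rng.integers(0, 2, size=(N, 3))
    incr = rng.standard_normal((N, 3))
    delta = np.zeros((N, 3, 2))
    np.put_along_axis(delta, which[:, :, None], (hit * incr)[:, :, None], axis=2)
    pop.alleles = pop.alleles + delta
    return pop


def _record(pop: Population, gen: int, rep: int) -> dict:
    P = phenotype(pop)
    return {
        "replicate": rep,
        "generation": gen,
        "var_pheno_male": float(P[pop.male].var()),
        "var_pheno_female": float(P[~pop.male].var()),
        "var_shared_locus": float(pop.alleles[:, SHARED, :].ravel().var()),
    }


def run_replicate(params: EvoParams, rep: int, rng) -> list[dict]:
    pop = init_population(params, rng)
    records = [_record(pop, 0, rep)]
    for gen in range(1, params.n_generations + 1):
        alive = viability_select(pop, params, rng)
        am = alive[pop.male[alive]]
        af = alive[~pop.male[alive]]
        pop = reproduce(pop.alleles[am], pop.alleles[af], params, rng)
        pop = mutate(pop, params, rng)
        if gen % params.record_every == 0:
            records.append(_record(pop, gen, rep))
    return records


def run_replicates(params: EvoParams) -> pd.DataFrame:
    """Independent replicate trajectories; deterministic given params.seed."""
    params.validate()
    root = np.random.SeedSequence(params.seed)
    out = []
    for rep, child in enumerate(root.spawn(params.n_replicates)):
        out.extend(run_replicate(params, rep, np.random.default_rng(child)))
    return pd.DataFrame(out)


def sex_specific_params(params: EvoParams | None = None) -> EvoParams:
    """The increased-female-constraint condition (s_f = 0.05, s_m = 0.005)."""
    base = params or EvoParams()
    return replace(base, s_female=0.05)
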