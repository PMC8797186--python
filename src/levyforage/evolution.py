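"""Lineage-based evolutionary dynamics of the foraging exponent.

Each generation a fresh landscape is built, all K organisms live out their
lifespans, search cost is applied post hoc, and organisms with fitness <= 0
die.  The survivors, in descending fitness order, receive offspring by the
ceiling rule

    omega_i = ceil(K * f_i / sum_j f_j),

allocated greedily until the carrying capacity K is exactly filled (later
parents may receive fewer, or zero).  Offspring inherit their parent's
exponent plus Gaussian noise with standard deviation ``sigma_sv`` (the
standing variation; sigma_sv = 0 means perfect heritability).  If no one
survives, the population is extinct and the run ends.

Competition assays pit two equal-sized lineages with fixed exponents
(sigma_sv = 0) against each other and track lineage fractions to fixation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np

from . import energetics
from .environment import make_environment
from .movement import MOVE_TABLE_SIZE, DigitalOrganism, MoveLengthDistribution, run_lifespan


class ExtinctionError(Exception):
    """Raised when offspring are requested for an empty parent list."""


@dataclass
class EvolutionConfig:
    """Study conditions for a multi-generation run."""

    K: int = 1500                 # population size = carrying capacity
    G: int = 100                  # generations
    chi: float = 0.0              # search cost per cell
    lam: int = 1_000_000          # lifespan in timesteps
    s: int = 1                    # speed, cells per timestep
    n: int = 1000                 # landscape side length
    n_deposits: int | None = None  # None -> floor(n^2 * 1e-4)
    recipe: str = "uniform_random"
    dust_u: float | None = None
    mu: float = 2.0               # founder mean exponent
    sigma_sv: float = 0.5         # standing variation (mutation SD)
    metric: str = "aol"

    def validate(self) -> "EvolutionConfig":
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")
        if self.G < 1:
            raise ValueError(f"G must be >= 1, got {self.G}")
        if self.chi < 0:
            raise ValueError(f"chi must be >= 0, got {self.chi}")
        if self.lam < 1:
            raise ValueError(f"lam must be >= 1, got {self.lam}")
        if self.s < 1:
            raise ValueError(f"s must be >= 1, got {self.s}")
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if self.sigma_sv < 0:
            raise ValueError(f"sigma_sv must be >= 0, got {self.sigma_sv}")
        if self.metric.lower() not in ("aol", "eol"):
            raise ValueError(f"metric must be 'aol' or 'eol', got {self.metric!r}")
        if self.recipe.lower() in ("levy_dust", "ld", "dust") and self.dust_u is None:
            raise ValueError("dust_u is required for a levy_dust recipe")
        return self


@dataclass
class ParentTriple:
    """Survivor bookkeeping: exponent, fitness, offspring count."""

    u: float
    f: float
    omega: int = 0
    lineage: int | None = None


@dataclass
class GenerationSummary:
    """Per-generation population statistics."""

    generation: int
    population: int
    survivors: int
    mean_u: float
    sd_u: float
    mean_fitness: float
    levy_fraction: float
    extinct: bool = False
    lineage_fractions: dict[int, float] | None = None


def assign_offspring(fitnesses: Sequence[float], K: int) -> list[int]:
    """Ceiling-based relative-fitness offspring allocation.

    ``fitnesses`` must be positive and sorted in descending order (ties keep
    their stable order).  Traversing in order, parent i receives
    ``ceil(K * f_i / sum f)`` offspring, capped so the running total never
    exceeds K; once K is reached, remaining parents receive zero.  The total
    is exactly K.
    """
    if len(fitnesses) == 0:
        raise ExtinctionError("no surviving parents: population is extinct")
    if K < 1:
        raise ValueError(f"carrying capacity K must be >= 1, got {K}")
    if any(f <= 0 for f in fitnesses):
        raise ValueError("all parent fitnesses must be > 0 (dead are removed first)")
    if any(fitnesses[i] < fitnesses[i + 1] for i in range(len(fitnesses) - 1)):
        raise ValueError("fitnesses must be sorted in descending order")
    # exact rational arithmetic so the ceiling never suffers float round-off
    total = sum(Fraction(f) for f in fitnesses)
    omegas = []
    allocated = 0
    for f in fitnesses:
        if allocated >= K:
            omegas.append(0)
            continue
        share = Fraction(f) * K / total
        w = int(math.ceil(share))
        w = min(w, K - allocated)
        omegas.append(w)
        allocated += w
    return omegas


def mutate_exponent(u_parent: float, sigma_sv: float, rng: np.random.Generator) -> float:
    """Offspring exponent: parent's value plus N(0, sigma_sv); unbounded."""
    if sigma_sv < 0:
        raise ValueError(f"sigma_sv must be >= 0, got {sigma_sv}")
    if sigma_sv == 0:
        return float(u_parent)
    return float(u_parent + rng.normal(0.0, sigma_sv))


def levy_fraction(exponents: Sequence[float]) -> float:
    """Fraction of exponents strictly inside the Lévy-like zone (1, 3)."""
    exponents = np.asarray(exponents, dtype=float)
    if exponents.size == 0:
        raise ValueError("levy_fraction of an empty exponent list is undefined")
    return float(np.mean((exponents > 1.0) & (exponents < 3.0)))


def _summarize(
    generation: int,
    exponents: np.ndarray,
    lineages: np.ndarray | None,
    survivor_fitness: np.ndarray,
    K: int,
    extinct: bool,
) -> GenerationSummary:
    frac = None
    if lineages is not None:
        labels = np.unique(lineages)
        frac = {int(l): float(np.mean(lineages == l)) for l in labels}
    return GenerationSummary(
        generation=generation,
        population=len(exponents),
        survivors=len(survivor_fitness),
        mean_u=float(np.mean(exponents)),
        sd_u=float(np.std(exponents, ddof=1)) if len(exponents) > 1 else 0.0,
        mean_fitness=float(np.mean(survivor_fitness)) if len(survivor_fitness) else float("nan"),
        levy_fraction=levy_fraction(exponents),
        extinct=extinct,
        lineage_fractions=frac,
    )


def _evolve(
    config: EvolutionConfig,
    exponents: np.ndarray,
    lineages: np.ndarray | None,
    rng: np.random.Generator,
    keep_exponents: bool,
    stop_at_fixation: bool,
):
    """Shared engine behind :func:`run_evolution` and :func:`run_competition`."""
    config.validate()
    metric = config.metric.lower()
    energy = energetics.energy_aol if metric == "aol" else energetics.energy_eol
    summaries: list[GenerationSummary] = []
    history: list[np.ndarray] = []
    for g in range(1, config.G + 1):
        env = make_environment(
            config.recipe, config.n, config.n_deposits, config.dust_u, rng
        )
        fitness = np.empty(len(exponents))
        for k, u in enumerate(exponents):
            dist = MoveLengthDistribution.build(u, env.n, MOVE_TABLE_SIZE, rng)
            org = DigitalOrganism(dist=dist, lam=config.lam, s=config.s)
            rec = run_lifespan(org, env, rng)
            fitness[k] = energy(rec, config.chi)
        alive = fitness > 0
        if keep_exponents:
            history.append(exponents.copy())
        if not np.any(alive):
            summaries.append(_summarize(g, exponents, lineages, fitness[:0], config.K, True))
            break
        # random permutation before the stable sort: equal-fitness ties carry
        # no positional (hence no lineage) bias
        perm = rng.permutation(np.flatnonzero(alive))
        order = perm[np.argsort(-fitness[perm], kind="stable")]
        omegas = assign_offspring(fitness[order].tolist(), config.K)
        child_u = np.empty(config.K)
        child_lin = np.empty(config.K, dtype=np.int64) if lineages is not None else None
        pos = 0
        for parent_idx, w in zip(order, omegas):
            for _ in range(w):
                child_u[pos] = mutate_exponent(exponents[parent_idx], config.sigma_sv, rng)
                if child_lin is not None:
                    child_lin[pos] = lineages[parent_idx]
                pos += 1
        summaries.append(_summarize(g, exponents, lineages, fitness[alive], config.K, False))
        exponents = child_u
        lineages = child_lin
        if stop_at_fixation and lineages is not None and len(np.unique(lineages)) == 1:
            summaries.append(_summarize(g + 1, exponents, lineages, fitness[:0], config.K, False))
            break
    if keep_exponents:
        return summaries, history
    return summaries


def run_evolution(
    config: EvolutionConfig,
    rng: np.random.Generator,
    keep_exponents: bool = False,
):
    """Run the full selection–inheritance–mutation loop for G generations.

    Founders draw exponents from N(mu, sigma_sv).  Returns the list of
    :class:`GenerationSummary` (and, with ``keep_exponents``, the list of
    per-generation exponent arrays).  Extinction ends the run early and is a
    recorded outcome, not an error.
    """
    config.validate()
    founders = config.mu + (
        rng.normal(0.0, config.sigma_sv, size=config.K)
        if config.sigma_sv > 0 else np.zeros(config.K)
    )
    return _evolve(config, founders, None, rng, keep_exponents, stop_at_fixation=False)


def run_competition(
    config: EvolutionConfig,
    u_a: float,
    u_b: float,
    rng: np.random.Generator,
    stop_at_fixation: bool = True,
):
    """Two fixed-exponent lineages compete for the carrying capacity.

    Starts with K/2 organisms of exponent ``u_a`` (lineage 0) and K/2 of
    ``u_b`` (lineage 1); sigma_sv is forced to 0 so lineages breed true.
    Returns per-generation summaries whose ``lineage_fractions`` track the
    share of K held by each lineage until fixation, extinction, or G.
    """
    config.validate()
    if config.K % 2 != 0:
        raise ValueError(f"competition needs an even K, got {config.K}")
    config = replace_sigma_zero(config)
    half = config.K // 2
    exponents = np.concatenate([np.full(half, float(u_a)), np.full(half, float(u_b))])
    lineages = np.concatenate([np.zeros(half, dtype=np.int64), np.ones(half, dtype=np.int64)])
    return _evolve(config, exponents, lineages, rng, keep_exponents=False,
                   stop_at_fixation=stop_at_fixation)


def replace_sigma_zero(config: EvolutionConfig) -> EvolutionConfig:
    from dataclasses import replace

    return replace(config, sigma_sv=0.0)


def evolved_exponent_vs_dust_correlation(
    mean_exponents: Sequence[float], dust_dimensions: Sequence[float]
) -> tuple[float, float, int]:
    """Pearson correlation between evolved exponents and dust dimensions.

    Returns ``(r, t, df)`` with t = r * sqrt(df) / sqrt(1 - r^2), df = n - 2.
    A positive r would support the extrinsic (emergentist) reading of
    Lévy-like movement; the intrinsic hypothesis predicts no positive trend.
    """
    x = np.asarray(mean_exponents, dtype=float)
    y = np.asarray(dust_dimensions, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired lists of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: an input has zero variance")
    import scipy.stats

    r = float(scipy.stats.pearsonr(x, y).statistic)
    df = len(x) - 2
    if r * r >= 1.0:
        t = math.inf if r > 0 else -math.inf
    else:
        t = r * math.sqrt(df) / math.sqrt(1 - r * r)
    return r, float(t), df
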