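"""Wright-Fisher evolution on static and shifting empirical landscapes.

A haploid population of fixed size ``N`` evolves over discrete generations
on the 512-genotype space.  Each generation the next population is a
multinomial draw with per-genotype reproduction probability proportional
to ``n_g * exp(c * S_g)`` -- selection rates are measured per 4-hour
competition (about two infection cycles), so the default exponent scale
``c = 0.5`` converts them to per-generation growth -- followed by
bidirectional per-site mutation at rate ``mu`` per site per replication.

Three landscape regimes are available:

* ``static_X``: one fixed landscape (X in A..E) for the whole run;
* ``discrete_shifting``: each generation uses the measured landscape whose
  axis coordinate is nearest the current population SI (the
  abundance-weighted mean specialization index);
* ``continuous_shifting``: a linear interpolation between the two
  landscapes bracketing the population SI on the landscape axis.

Replicate runs perturb every landscape value once per simulation with
Gaussian noise calibrated so that two independent draws correlate like
experimental replicates (r ~ 0.96); EvoC stays exactly 0 (it is the
reference), and genotypes never observed in an environment receive a
floor rate of -10 (effectively lethal rather than undefined).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace
from typing import Mapping, Sequence

import numpy as np

from .core import (
    ENVIRONMENTS,
    N_GENOTYPES,
    N_SITES,
    FitnessLandscape,
    ValidationError,
    fill_missing,
)
from .phenotyping import (
    DEFAULT_SI_THRESHOLD,
    classify_phenotype,
    specialization_index,
)

MODELS = (
    "static_A",
    "static_B",
    "static_C",
    "static_D",
    "static_E",
    "discrete_shifting",
    "continuous_shifting",
)

# landscape axis, ascending coordinate order
_AXIS_ORDER = ("E", "D", "C", "B", "A")
_AXIS_COORDS = np.array([ENVIRONMENTS[e].axis_coordinate for e in _AXIS_ORDER])

_CLASS_ABBREV = {
    "O_specialist": "O",
    "L_specialist": "L",
    "generalist": "G",
    "undefined": "U",
}
_CLASS_ORDER = ("O", "L", "G", "U")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulation run.

    ``N``: particles (5e9 matches the experimental flask scale);
    ``mu``: per-site per-replication substitution probability;
    ``c``: generations per competition unit for the fitness exponent;
    ``target_r``: replicate correlation the landscape noise is calibrated
    to (1.0 disables noise); ``floor``: selection rate assigned to
    unobserved genotypes; ``min_phenotype_fraction``: endpoint abundance
    cutoff for counting a phenotype as present.
    """

    N: int = 5_000_000_000
    generations: int = 500
    mu: float = 7.7e-8
    model: str = "continuous_shifting"
    c: float = 0.5
    floor: float = -10.0
    target_r: float = 0.96
    min_phenotype_fraction: float = 0.025
    si_threshold: float = DEFAULT_SI_THRESHOLD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValidationError("population size N must be >= 1")
        if not 0 <= self.mu <= 1:
            raise ValidationError("mutation rate mu must lie in [0, 1]")
        if self.generations < 0:
            raise ValidationError("generations must be >= 0")
        if self.model not in MODELS:
            raise ValidationError(f"unknown model {self.model!r}")


@dataclass
class SimulationTrajectory:
    """Per-generation summaries plus the endpoint state of one run."""

    config: SimulationConfig
    entropy: np.ndarray  # (generations+1,) nats
    population_si: np.ndarray  # (generations+1,)
    active_landscape: list[str]  # per generation (label or interpolation)
    final_abundances: np.ndarray  # (512,)
    genotype_si: np.ndarray  # (512,) SI used for phenotyping in this run
    endpoint_label: str = ""


def calibrate_noise(values: np.ndarray, target_r: float) -> float:
    """Noise s.d. giving replicate landscape draws correlated ~ target_r.

    With signal variance v and independent Normal(0, sigma^2) noise on two
    copies, corr = v / (v + sigma^2); inverting gives
    sigma = sqrt(v * (1/target_r - 1)).
    """
    if not 0 < target_r <= 1:
        raise ValidationError("target_r must lie in (0, 1]")
    v = float(np.nanvar(np.asarray(values, dtype=float)))
    return math.sqrt(v * (1.0 / target_r - 1.0))


def perturb_landscape(
    landscape: FitnessLandscape,
    sigma: float,
    rng: np.random.Generator | int = 0,
) -> FitnessLandscape:
    """Add independent Gaussian noise to every observed value except EvoC's.

    EvoC is the reference all rates are measured against, so its rate stays
    exactly 0; missing values stay missing.
    """
    if sigma < 0:
        raise ValidationError("sigma must be non-negative")
    rng = np.random.default_rng(rng)
    values = landscape.values.copy()
    mask = np.isfinite(values)
    mask[0] = False  # EvoC untouched
    values[mask] += rng.normal(0.0, sigma, int(mask.sum()))
    return dc_replace(landscape, values=values)


def population_si(abundances: np.ndarray, genotype_si: np.ndarray) -> float:
    """Abundance-weighted mean SI of the population."""
    abundances = np.asarray(abundances, dtype=float)
    total = abundances.sum()
    if total <= 0:
        raise ValidationError("total abundance is zero")
    return float(abundances @ np.asarray(genotype_si, dtype=float) / total)


def effective_landscape(
    pop_si: float, landscape_stack: np.ndarray, model: str
) -> tuple[np.ndarray, str]:
    """Fitness vector governing the next generation, plus a label.

    ``landscape_stack`` holds the five floor-filled landscapes as rows in
    ascending axis order (E, D, C, B, A).  The population SI is clamped to
    [-1, 1] before lookup.  The discrete model breaks an exact midpoint
    tie toward the node with the smaller |coordinate|.
    """
    x = min(1.0, max(-1.0, pop_si))
    if model.startswith("static_"):
        env = model.removeprefix("static_")
        return landscape_stack[_AXIS_ORDER.index(env)], env
    dist = np.abs(_AXIS_COORDS - x)
    if model == "discrete_shifting":
        best = dist == dist.min()
        candidates = np.nonzero(best)[0]
        pick = candidates[np.argmin(np.abs(_AXIS_COORDS[candidates]))]
        return landscape_stack[pick], _AXIS_ORDER[pick]
    if model == "continuous_shifting":
        hi = int(np.searchsorted(_AXIS_COORDS, x))
        if hi == 0:
            return landscape_stack[0], _AXIS_ORDER[0]
        if hi >= len(_AXIS_COORDS):
            return landscape_stack[-1], _AXIS_ORDER[-1]
        lo = hi - 1
        span = _AXIS_COORDS[hi] - _AXIS_COORDS[lo]
        w = (x - _AXIS_COORDS[lo]) / span
        vec = (1.0 - w) * landscape_stack[lo] + w * landscape_stack[hi]
        return vec, f"{_AXIS_ORDER[lo]}:{_AXIS_ORDER[hi]}@{w:.3f}"
    raise ValidationError(f"unknown model {model!r}")


def reproduce(
    abundances: np.ndarray,
    fitness: np.ndarray,
    N: int,
    c: float = 0.5,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Multinomial reproduction with weights n_g * exp(c * S_g)."""
    rng = np.random.default_rng(rng)
    abundances = np.asarray(abundances, dtype=np.int64)
    weights = abundances * np.exp(c * np.asarray(fitness, dtype=float))
    total = weights.sum()
    if not total > 0:
        raise ValidationError("all reproduction weights are zero")
    return rng.multinomial(N, weights / total)


def mutate(
    abundances: np.ndarray,
    mu: float,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Toggle each site independently with probability mu per individual.

    For each genotype with n_g individuals, Binomial(n_g, mu) individuals
    per site move to the single-site neighbour (forward and back mutation
    at the same rate).  Population size is conserved exactly.
    """
    if not 0 <= mu <= 1:
        raise ValidationError("mu must lie in [0, 1]")
    abundances = np.asarray(abundances, dtype=np.int64)
    out = abundances.copy()
    if mu == 0:
        return out
    rng = np.random.default_rng(rng)
    nz = np.nonzero(abundances)[0]
    if len(nz) == 0:
        return out
    n = abundances[nz]
    events = rng.binomial(n[:, None], mu, size=(len(nz), N_SITES))
    totals = events.sum(axis=1)
    over = totals > n
    if over.any():
        # pathological at toy-scale mu: re-draw jointly so moves can't
        # exceed the genotype's abundance
        for row in np.nonzero(over)[0]:
            p = [mu] * N_SITES + [max(0.0, 1.0 - N_SITES * mu)]
            events[row] = rng.multinomial(n[row], np.array(p) / np.sum(p))[:N_SITES]
        totals = events.sum(axis=1)
    out[nz] -= totals
    for site in range(N_SITES):
        moved = events[:, site]
        if moved.any():
            np.add.at(out, nz ^ (1 << site), moved)
    return out


def shannon_entropy(abundances: np.ndarray) -> float:
    """Shannon entropy of the genotype abundance distribution, in nats."""
    abundances = np.asarray(abundances, dtype=float)
    total = abundances.sum()
    if total <= 0:
        raise ValidationError("total abundance is zero")
    p = abundances[abundances > 0] / total
    return float(-(p * np.log(p)).sum())


def endpoint_phenotypes(
    abundances: np.ndarray,
    genotype_classes: Sequence[str],
    min_fraction: float = 0.025,
) -> str:
    """Combination label of phenotype classes at >= ``min_fraction`` abundance.

    Classes are abbreviated (O/L/G/U) and joined in the fixed order
    O, L, G, U; e.g. a mixed endpoint of an O-specialist and a generalist
    is labelled ``"O+G"``.
    """
    abundances = np.asarray(abundances, dtype=float)
    total = abundances.sum()
    if total <= 0:
        raise ValidationError("total abundance is zero")
    present = abundances / total >= min_fraction
    classes = {
        _CLASS_ABBREV[genotype_classes[g]] for g in np.nonzero(present)[0]
    }
    return "+".join(c for c in _CLASS_ORDER if c in classes)


def prepare_landscapes(
    landscapes: Mapping[str, FitnessLandscape],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-run noisy, floor-filled landscape stack in axis order (E..A)."""
    stack = []
    for env in _AXIS_ORDER:
        if env not in landscapes:
            raise ValidationError(f"landscape for environment {env} missing")
        landscape = landscapes[env]
        if config.target_r < 1.0:
            sigma = calibrate_noise(landscape.values, config.target_r)
            landscape = perturb_landscape(landscape, sigma, rng)
        stack.append(fill_missing(landscape, config.floor).values)
    return np.vstack(stack)


def run_simulation(
    config: SimulationConfig,
    landscapes: Mapping[str, FitnessLandscape],
    initial_abundances: np.ndarray | None = None,
) -> SimulationTrajectory:
    """Evolve a population under the configured landscape regime.

    All five measured landscapes are required (the single-host landscapes
    A and E define each genotype's SI even in static runs).  The
    simulation starts from a homogeneous EvoC population unless
    ``initial_abundances`` is given, and is fully reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    stack = prepare_landscapes(landscapes, config, rng)
    s_o = stack[_AXIS_ORDER.index("A")]
    s_l = stack[_AXIS_ORDER.index("E")]
    genotype_si = specialization_index(s_l, s_o)
    genotype_classes = classify_phenotype(genotype_si, config.si_threshold)

    if initial_abundances is None:
        abund = np.zeros(N_GENOTYPES, dtype=np.int64)
        abund[0] = config.N
    else:
        abund = np.asarray(initial_abundances, dtype=np.int64).copy()
        if abund.sum() != config.N:
            raise ValidationError("initial abundances must sum to N")

    n_steps = config.generations
    entropy = np.empty(n_steps + 1)
    pop_si = np.empty(n_steps + 1)
    active: list[str] = []
    entropy[0] = shannon_entropy(abund)
    pop_si[0] = population_si(abund, genotype_si)

    for gen in range(1, n_steps + 1):
        fitness_vec, label = effective_landscape(pop_si[gen - 1], stack, config.model)
        active.append(label)
        abund = reproduce(abund, fitness_vec, config.N, config.c, rng)
        abund = mutate(abund, config.mu, rng)
        entropy[gen] = shannon_entropy(abund)
        pop_si[gen] = population_si(abund, genotype_si)

    trajectory = SimulationTrajectory(
        config=config,
        entropy=entropy,
        population_si=pop_si,
        active_landscape=active,
        final_abundances=abund,
        genotype_si=genotype_si,
        endpoint_label=endpoint_phenotypes(
            abund, list(genotype_classes), config.min_phenotype_fraction
        ),
    )
    return trajectory


def replay_generation_count(generations_per_day: int = 8, days: int = 35) -> int:
    """Generations spanned by the speciation replay experiment.

    Eight-hour culture days at ~60-minute generations give 8 generations
    per day over the 35-day experiment.
    """
    return generations_per_day * days
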