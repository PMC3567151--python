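"""Population engine: encounters, mating, selection, reproduction, mutation.

A population of ``N`` diploid individuals (half female, half male) carries
two alleles at each of four loci — male-expressed ligand, female-expressed
receptor, female-expressed decoy, and a neutral control with no effect on
mating rate.  Each generation every female encounters ``n_encounters``
males drawn uniformly with replacement; each encounter results in mating
with probability equal to the pair's (decoy-modified) mating rate.  Mothers
of the next generation are sampled proportional to their fecundity
``W_f(realized rate)`` among mated females; each offspring's sire is drawn
uniformly from its mother's mate multiset; each parent transmits one
uniformly chosen allele per locus, mutating with probability ``mu`` by a
stepwise +-1 move (or, rarely, a larger step) with reflecting boundaries.
Population size and sex ratio are held constant.

Two interchangeable engines execute this life cycle:

* ``engine="fast"`` — a compiled single-function loop
  (:mod:`decoysim._engine`), used by default;
* ``engine="reference"`` — the stage functions in this module
  (:func:`encounter_and_mate`, :func:`reproduce`, :func:`mutate_gametes`)
  composed generation by generation.

The two use different random streams, so trajectories agree statistically,
not bitwise; each engine is individually deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import conflict_model as cm
from ._engine import run_replicate_compiled
from .errors import ConfigurationError, SimulationError

__all__ = [
    "LOCI",
    "SimConfig",
    "Population",
    "MatingOutcome",
    "Trajectory",
    "initialize_population",
    "encounter_and_mate",
    "reproduce",
    "mutate_gametes",
    "run_simulation",
    "run_replicates",
    "replicate_seed",
]

LOCI = ("male", "female", "decoy", "neutral")

_DEFAULT_INITIAL = {"male": 0, "female": 5, "decoy": 16, "neutral": 30}


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings.

    Defaults are the published study conditions: N = 10,000 diploid
    individuals, 15,000 generations, 20 male encounters per female per
    generation, mutation rate 5e-5 per locus per transmitted gamete,
    initial allelic values male 0 / female 5 / decoy 16 / neutral 30,
    20 replicates, and 500-generation rate windows.
    """

    N: int = 10_000
    generations: int = 15_000
    n_encounters: int = 20
    mu: float = 5.0e-5
    jump_prob: float = 0.01
    initial_alleles: dict = field(default_factory=lambda: dict(_DEFAULT_INITIAL))
    seed: int = 1
    n_replicates: int = 20
    window: int = 500
    decoy_enabled: bool = True

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)

    def validate(self, params: Optional[cm.ModelParams] = None) -> "SimConfig":
        if self.N <= 0 or self.N % 2 != 0:
            raise ConfigurationError("N must be positive and even")
        if self.generations <= 0:
            raise ConfigurationError("generations must be positive")
        if self.window <= 0 or self.generations % self.window != 0:
            raise ConfigurationError("generations must be divisible by window")
        if not (0.0 <= self.mu <= 1.0):
            raise ConfigurationError("mu must lie in [0, 1]")
        if not (0.0 <= self.jump_prob <= 1.0):
            raise ConfigurationError("jump_prob must lie in [0, 1]")
        if self.n_encounters <= 0:
            raise ConfigurationError("n_encounters must be positive")
        if self.n_replicates <= 0:
            raise ConfigurationError("n_replicates must be positive")
        if set(self.initial_alleles) != set(LOCI):
            raise ConfigurationError(
                f"initial_alleles must name exactly the loci {LOCI}"
            )
        allele_max = params.allele_max if params is not None else 50
        for locus, value in self.initial_alleles.items():
            if not (0 <= value <= allele_max):
                raise ConfigurationError(
                    f"initial allele for locus '{locus}' ({value}) outside "
                    f"allele space [0, {allele_max}]"
                )
        return self


@dataclass
class Population:
    """``alleles[i, locus, copy]`` for individual i; females first.

    ``is_female`` marks the first N/2 individuals; locus order follows
    :data:`LOCI`.
    """

    alleles: np.ndarray  # (N, 4, 2) integer
    is_female: np.ndarray  # (N,) bool

    @property
    def size(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_females(self) -> int:
        return int(self.is_female.sum())

    def phenotypes(self, params: cm.ModelParams) -> np.ndarray:
        """(N, 4) additive phenotypes, normalized per ``params``."""
        z = self.alleles.mean(axis=2)
        if params.normalize:
            z = z / params.allele_max
        return z

    def locus_means(self) -> np.ndarray:
        """(4,) mean allelic value per locus over all 2N copies."""
        return self.alleles.mean(axis=(0, 2))


@dataclass
class MatingOutcome:
    """Result of one round of encounters for every female.

    ``mates[i, :n_mates[i]]`` are male indices (into the male subarray)
    the i-th female mated with, possibly with repeats; ``realized_rate`` is
    matings / encounters.
    """

    mates: np.ndarray  # (F, n_encounters) int
    n_mates: np.ndarray  # (F,) int
    realized_rate: np.ndarray  # (F,) float


@dataclass
class Trajectory:
    """Per-generation mean allelic value per locus for one replicate."""

    means: np.ndarray  # (generations + 1, 4)
    replicate: int
    seed: int
    mean_mating_rate: Optional[np.ndarray] = None  # (generations,) diagnostics
    failed: bool = False

    @property
    def generations(self) -> int:
        return self.means.shape[0] - 1

    def locus(self, name: str) -> np.ndarray:
        return self.means[:, LOCI.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.means, columns=[f"mean_{locus}" for locus in LOCI]
        )
        df.insert(0, "generation", np.arange(self.means.shape[0]))
        df["replicate"] = self.replicate
        df["seed"] = self.seed
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Trajectory":
        required = ["generation"] + [f"mean_{l}" for l in LOCI]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ConfigurationError(f"trajectory table missing columns {missing}")
        means = df[[f"mean_{l}" for l in LOCI]].to_numpy(dtype=float)
        rep = int(df["replicate"].iloc[0]) if "replicate" in df.columns else 0
        seed = int(df["seed"].iloc[0]) if "seed" in df.columns else 0
        return cls(means=means, replicate=rep, seed=seed)


def replicate_seed(base_seed: int, k: int) -> int:
    """Deterministic per-replicate seed (independent of other replicates)."""
    return int(np.random.SeedSequence([int(base_seed), int(k)]).generate_state(1)[0] % (2**31))


def initialize_population(
    config: SimConfig, params: Optional[cm.ModelParams] = None
) -> Population:
    """Monomorphic starting population: every individual homozygous for the
    configured initial value at every locus; first half female."""
    params = params or cm.ModelParams()
    config.validate(params)
    N = config.N
    alleles = np.empty((N, 4, 2), dtype=np.int64)
    for l, locus in enumerate(LOCI):
        alleles[:, l, :] = config.initial_alleles[locus]
    is_female = np.zeros(N, dtype=bool)
    is_female[: N // 2] = True
    return Population(alleles=alleles, is_female=is_female)


def pair_mating_rates(
    z_m: np.ndarray,
    z_f: np.ndarray,
    z_d: np.ndarray,
    params: cm.ModelParams,
    decoy_enabled: bool = True,
) -> np.ndarray:
    """Vectorized mating rate for arrays of (male, female, decoy) phenotypes.

    Same algebra as :func:`decoysim.conflict_model.decoy_modified_rate`,
    elementwise over broadcastable arrays.
    """
    z_m = np.asarray(z_m, dtype=float)
    z_f = np.asarray(z_f, dtype=float)
    z_d = np.asarray(z_d, dtype=float)
    D = np.abs(z_m - z_f)
    P = np.exp(-((D / params.s_p) ** params.x_p))
    if not decoy_enabled:
        return P
    theta = (z_d > np.minimum(z_m, z_f)) & (z_d < np.maximum(z_m, z_f))
    dev = np.abs(D - params.D_opt)
    pdev = np.minimum(1.0, (dev / params.sd) ** params.xd)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(D > 0, np.abs(z_f - z_d) / np.where(D > 0, D, 1.0), 1.0)
    q = np.maximum(0.0, 1.0 - (rho / params.si) ** params.xi)
    Pi = params.P_opt * np.minimum(
        params.c0 * q + pdev, np.minimum(1.0, pdev + params.c0)
    )
    P_mod = np.clip(np.minimum(P, params.P_opt) - Pi, 0.0, 1.0)
    return np.where(theta, P_mod, P)


def encounter_and_mate(
    pop: Population,
    params: cm.ModelParams,
    config: SimConfig,
    rng: np.random.Generator,
) -> MatingOutcome:
    """One round of encounters: every female meets ``n_encounters`` males
    drawn uniformly with replacement and mates with probability equal to
    the pair's mating rate (modified by the female's own decoy genotype)."""
    female_idx = np.flatnonzero(pop.is_female)
    male_idx = np.flatnonzero(~pop.is_female)
    if male_idx.size == 0:
        raise SimulationError("population has no males")
    F, n = female_idx.size, config.n_encounters

    z = pop.phenotypes(params)
    z_f = z[female_idx, 1]
    z_d = z[female_idx, 2]
    z_m_all = z[male_idx, 0]

    draws = rng.integers(0, male_idx.size, size=(F, n))
    P = pair_mating_rates(
        z_m_all[draws], z_f[:, None], z_d[:, None], params, config.decoy_enabled
    )
    mated = rng.random((F, n)) < P

    # pack mated male indices to the front of each row
    order = np.argsort(~mated, axis=1, kind="stable")
    mates = np.take_along_axis(draws, order, axis=1)
    n_mates = mated.sum(axis=1)
    return MatingOutcome(
        mates=mates,
        n_mates=n_mates,
        realized_rate=n_mates / n,
    )


def mutate_gametes(
    gametes: np.ndarray,
    mu: float,
    rng: np.random.Generator,
    allele_max: int = 50,
    jump_prob: float = 0.1,
) -> np.ndarray:
    """Mutation of transmitted alleles.

    Each allele independently mutates with probability ``mu``.  A mutation
    is a +-1 step or, with probability ``jump_prob``, a large-effect
    step of magnitude 2..4 (uniform), with reflecting boundaries at 0 and
    ``allele_max``.  Returns a new array; the input is not modified.
    """
    if not (0.0 <= mu <= 1.0):
        raise ConfigurationError("mu must lie in [0, 1]")
    if not (0.0 <= jump_prob <= 1.0):
        raise ConfigurationError("jump_prob must lie in [0, 1]")
    g = np.array(gametes, copy=True)
    hit = rng.random(g.shape) < mu
    jump = rng.random(g.shape) < jump_prob
    sign = np.where(rng.random(g.shape) < 0.5, 1, -1)
    magnitude = np.where(jump, rng.integers(2, 5, size=g.shape), 1)
    moved = g + sign * magnitude
    moved = np.where(moved < 0, -moved, moved)
    moved = np.where(moved > allele_max, 2 * allele_max - moved, moved)
    return np.where(hit, moved, g)


def reproduce(
    pop: Population,
    outcome: MatingOutcome,
    params: cm.ModelParams,
    config: SimConfig,
    rng: np.random.Generator,
) -> Population:
    """Next generation of exactly N individuals.

    Mothers are sampled proportional to fecundity ``W_f`` of their realized
    mating rate, restricted to mated females; sires uniform over each
    mother's mate multiset; one uniformly chosen allele per locus per
    parent, then mutation.  Sex is reassigned as an even split.
    """
    N = pop.size
    female_idx = np.flatnonzero(pop.is_female)
    male_idx = np.flatnonzero(~pop.is_female)

    mated = outcome.n_mates > 0
    if not mated.any():
        raise SimulationError("no female mated; population cannot reproduce")
    W = np.where(mated, female_fitness(outcome.realized_rate, params), 0.0)

    mothers = rng.choice(female_idx.size, size=N, p=W / W.sum())
    sire_pick = (rng.random(N) * outcome.n_mates[mothers]).astype(np.int64)
    sires = outcome.mates[mothers, sire_pick]

    maternal = pop.alleles[female_idx[mothers]]  # (N, 4, 2)
    paternal = pop.alleles[male_idx[sires]]
    pick_m = rng.integers(0, 2, size=(N, 4))
    pick_p = rng.integers(0, 2, size=(N, 4))
    gam_m = np.take_along_axis(maternal, pick_m[:, :, None], axis=2)[:, :, 0]
    gam_p = np.take_along_axis(paternal, pick_p[:, :, None], axis=2)[:, :, 0]

    gam_m = mutate_gametes(gam_m, config.mu, rng, params.allele_max, config.jump_prob)
    gam_p = mutate_gametes(gam_p, config.mu, rng, params.allele_max, config.jump_prob)

    alleles = np.stack([gam_m, gam_p], axis=2)
    is_female = np.zeros(N, dtype=bool)
    is_female[: N // 2] = True
    return Population(alleles=alleles, is_female=is_female)


def female_fitness(realized_rate: np.ndarray, params: cm.ModelParams) -> np.ndarray:
    """Fecundity of mated females at their realized mating rate (vectorized)."""
    r = np.asarray(realized_rate, dtype=float)
    return params.B_max * np.exp(-((np.abs(r - params.P_opt) / params.s_w) ** params.x_w))


def run_simulation(
    config: SimConfig,
    params: Optional[cm.ModelParams] = None,
    replicate: int = 0,
    seed: Optional[int] = None,
    engine: str = "fast",
    two_locus: bool = False,
) -> Trajectory:
    """Run one replicate and return its trajectory of per-locus means.

    ``seed`` defaults to the replicate seed derived from ``config.seed``
    and ``replicate``.  Identical seed (per engine) gives an identical
    trajectory.  ``two_locus=True`` routes the fast engine through the
    decoy-free code path (the original two-locus conflict); with
    ``config.decoy_enabled`` False the three-locus path runs with decoy
    activity clamped off, which is bit-identical to the two-locus path
    under the same seed.  If every female fails to mate in some generation
    the run aborts: the partial trajectory is returned with
    ``failed=True``.
    """
    params = cm.validate_params(params or cm.ModelParams())
    config.validate(params)
    if seed is None:
        seed = replicate_seed(config.seed, replicate)

    if engine == "fast":
        if two_locus:
            mode = 0
        else:
            mode = 1 if config.decoy_enabled else 2
        traj, rates, flag = run_replicate_compiled(seed, config, params, mode)
        return Trajectory(
            means=traj,
            replicate=replicate,
            seed=seed,
            mean_mating_rate=rates,
            failed=(flag != 0),
        )
    if engine != "reference":
        raise ConfigurationError(f"unknown engine '{engine}'")

    rng = np.random.default_rng(seed)
    pop = initialize_population(config, params)
    means = np.empty((config.generations + 1, 4))
    rates = np.empty(config.generations)
    means[0] = pop.locus_means()
    for g in range(config.generations):
        try:
            outcome = encounter_and_mate(pop, params, config, rng)
            rates[g] = outcome.realized_rate.mean()
            pop = reproduce(pop, outcome, params, config, rng)
        except SimulationError:
            return Trajectory(
                means=means[: g + 1],
                replicate=replicate,
                seed=seed,
                mean_mating_rate=rates[:g],
                failed=True,
            )
        means[g + 1] = pop.locus_means()
    return Trajectory(
        means=means, replicate=replicate, seed=seed, mean_mating_rate=rates
    )


def run_replicates(
    config: SimConfig,
    params: Optional[cm.ModelParams] = None,
    engine: str = "fast",
) -> list[Trajectory]:
    """Run ``config.n_replicates`` independent replicates.

    Replicate ``k``'s seed depends only on the base seed and ``k``, so any
    single replicate can be reproduced in isolation.
    """
    return [
        run_simulation(config, params, replicate=k, engine=engine)
        for k in range(config.n_replicates)
    ]
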