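"""Finite-population Monte Carlo simulator.

Implements the three experimental protocols on top of the generation
kernel in :mod:`reciprosim._kernels`:

* stationary cooperation -- strategies (ALLC/ALLD/DISC) evolve by
  pairwise-comparison imitation with mutation; the mean cooperation rate
  over the post-burn-in generations is averaged across replicates;
* invasion of institutional adherence -- an all-DISC population of private
  assessors equilibrates its reputations, a single adherent (or a chosen
  number) is introduced, and the adherence trait evolves with mutation off
  until it fixes or goes extinct;
* stability / mixed-composition runs -- the same absorbing-chain protocol
  started from all-adherent populations (private invader) or from
  ALLC/ALLD/DISC mixtures where the heritable trait is the full
  (strategy, adherence) type.

Replicate seeds are spawned deterministically from a master seed, so every
result is bit-reproducible.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .core import GameParams, Institution, SimulationParams, SocialNorm, Strategy

__all__ = [
    "StationaryResult",
    "FixationResult",
    "simulate_stationary_cooperation",
    "estimate_fixation_probability",
    "mean_good_frequency",
    "run_generation",
    "PopulationState",
]


def _replicate_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)


@dataclass
class PopulationState:
    """Mutable agent-population state (mainly for unit-level testing; the
    experiment drivers keep state inside the kernels)."""

    strategies: np.ndarray  # (N,) int8, values of core.Strategy
    adherent: np.ndarray  # (N,) bool
    img: np.ndarray  # (N, N) uint8, [observer, member] private images
    pub: np.ndarray  # (N,) uint8 public broadcasts
    payoffs: np.ndarray  # (N,) float64, last generation totals
    generation: int = 0

    @classmethod
    def random(cls, N: int, seed: int, *, random_strategies: bool = True) -> "PopulationState":
        strategies, adherent, img, pub = K.random_state_init(N, np.uint32(seed), random_strategies)
        return cls(
            strategies=strategies,
            adherent=adherent,
            img=img,
            pub=pub,
            payoffs=np.zeros(N),
        )

    @property
    def N(self) -> int:
        return self.strategies.shape[0]


def run_generation(
    state: PopulationState,
    norm: SocialNorm,
    game: GameParams,
    sim: SimulationParams,
    inst: Institution,
    *,
    evolve: str = "strategy",
    seed: int | None = None,
) -> float:
    """Advance ``state`` by one generation in place; returns the fraction
    of cooperative donor decisions (out of N^2 ordered pairs incl. self).

    ``evolve`` is one of 'none', 'strategy', 'adherence', 'type'.  If
    ``seed`` is given the kernel RNG is reseeded first (otherwise the
    stream continues from previous calls).
    """
    mode = {"none": K.EVOLVE_NONE, "strategy": K.EVOLVE_STRATEGY,
            "adherence": K.EVOLVE_ADHERENCE, "type": K.EVOLVE_TYPE}[evolve]
    if seed is not None:
        K.seed_rng(np.uint32(seed))
    coop = np.zeros(1)
    gens, _ = K.run_generations(
        state.strategies, state.adherent, state.img, state.pub,
        norm.as_array(), game.e1, game.e2, sim.E, game.b, game.c, sim.w, sim.mu,
        inst.Q, inst.k_min, inst.board == "internal",
        1, mode, False, coop, state.payoffs,
    )
    state.generation += gens
    return float(coop[0])


@dataclass(frozen=True)
class StationaryResult:
    """Replicate-mean stationary cooperation rate with a +/- 2 SE interval."""

    mean: float
    se: float
    per_replicate: np.ndarray
    replicates: int

    @property
    def ci(self) -> tuple[float, float]:
        return (self.mean - 2.0 * self.se, self.mean + 2.0 * self.se)


def simulate_stationary_cooperation(
    norm: SocialNorm,
    game: GameParams,
    sim: SimulationParams,
    inst: Institution,
) -> StationaryResult:
    """Stationary mean cooperation under evolving strategies.

    Each replicate starts from uniformly random strategies and fair-coin
    reputations, runs ``sim.generations`` generations with strategy
    imitation and mutation rate ``sim.mu``, and reports the mean
    cooperation rate over the generations after ``sim.burn_in``.
    """
    seeds = _replicate_seeds(sim.seed, sim.replicates)
    norm_arr = norm.as_array()
    internal = inst.board == "internal"
    per_rep = np.empty(sim.replicates)
    coop = np.zeros(sim.generations)
    payoff = np.zeros(sim.N)
    for r, s in enumerate(seeds):
        strategies, adherent, img, pub = K.random_state_init(sim.N, s, True)
        adherent[:] = True  # complete adherence to the institution
        K.run_generations(
            strategies, adherent, img, pub, norm_arr,
            game.e1, game.e2, sim.E, game.b, game.c, sim.w, sim.mu,
            inst.Q, inst.k_min, internal,
            sim.generations, K.EVOLVE_STRATEGY, False, coop, payoff,
        )
        per_rep[r] = coop[sim.burn_in:].mean()
    mean = float(per_rep.mean())
    se = float(per_rep.std(ddof=1) / math.sqrt(sim.replicates)) if sim.replicates > 1 else math.nan
    return StationaryResult(mean=mean, se=se, per_replicate=per_rep, replicates=sim.replicates)


def simulate_private_stationary_cooperation(
    norm: SocialNorm,
    game: GameParams,
    sim: SimulationParams,
) -> StationaryResult:
    """Same protocol with purely private assessment (no adherents); empathy
    ``sim.E`` applies to the private observations."""
    seeds = _replicate_seeds(sim.seed, sim.replicates)
    norm_arr = norm.as_array()
    per_rep = np.empty(sim.replicates)
    coop = np.zeros(sim.generations)
    payoff = np.zeros(sim.N)
    for r, s in enumerate(seeds):
        strategies, adherent, img, pub = K.random_state_init(sim.N, s, True)
        K.run_generations(
            strategies, adherent, img, pub, norm_arr,
            game.e1, game.e2, sim.E, game.b, game.c, sim.w, sim.mu,
            1, 1, False,
            sim.generations, K.EVOLVE_STRATEGY, False, coop, payoff,
        )
        per_rep[r] = coop[sim.burn_in:].mean()
    mean = float(per_rep.mean())
    se = float(per_rep.std(ddof=1) / math.sqrt(sim.replicates)) if sim.replicates > 1 else math.nan
    return StationaryResult(mean=mean, se=se, per_replicate=per_rep, replicates=sim.replicates)


def mean_good_frequency(img: np.ndarray, pub: np.ndarray | None = None) -> float:
    """Mean frequency of good reputations averaged over all subjective
    (observer, member) perspectives; pass ``pub`` to additionally weight in
    the broadcast as one more perspective."""
    m = float(np.asarray(img, dtype=float).mean())
    if pub is None:
        return m
    N = img.shape[0]
    return (m * N + float(np.asarray(pub, dtype=float).mean())) / (N + 1)


@dataclass(frozen=True)
class FixationResult:
    """Fixation proportion of the invading trait with a 95% binomial CI."""

    probability: float
    ci: tuple[float, float]
    n_fixed: int
    replicates: int
    mean_good_at_intro: float
    mean_generations: float


def _binomial_ci(k: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    # Wilson score interval
    if n == 0:
        return (math.nan, math.nan)
    p = k / n
    denom = 1.0 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return (max(0.0, center - half), min(1.0, center + half))


def estimate_fixation_probability(
    norm: SocialNorm,
    game: GameParams,
    sim: SimulationParams,
    inst: Institution,
    *,
    initial_adherents: int | str = 1,
    invader: str = "adherence",
    background_mix: tuple[int, int, int] | None = None,
    equilibration: int = 100,
    max_generations: int = 2_000_000,
) -> FixationResult:
    """Fixation proportion of an invading trait in an absorbing chain.

    ``invader='adherence'`` introduces ``initial_adherents`` adherents
    (or a uniform-random count in [1, N-1] with 'uniform-random') into an
    otherwise non-adherent population; ``invader='private'`` introduces
    non-adherents into an all-adherent population.  In both cases the
    reported probability is the *invader's* fixation proportion, so the
    neutral benchmark is k/N.  With ``background_mix`` = (n_X, n_Y, n_Zn)
    the population
    starts from that ALLC/ALLD/DISC composition and the heritable trait is
    the full (strategy, adherence) type; one DISC-PRIVATE individual is
    switched to DISC-ADHERE after equilibration.

    Mutation is off; replicates run until the adherence trait fixes or goes
    extinct (a generous ``max_generations`` cap guards against
    non-termination and raises if ever hit).
    """
    if sim.mu != 0.0 and background_mix is None:
        raise ValueError("fixation experiments require mu = 0")
    N = sim.N
    seeds = _replicate_seeds(sim.seed, sim.replicates)
    norm_arr = norm.as_array()
    internal = inst.board == "internal"
    coop = np.zeros(max_generations)
    payoff = np.zeros(N)
    n_fixed = 0
    good_at_intro = np.empty(sim.replicates)
    gens_used = np.empty(sim.replicates)
    rng = np.random.default_rng(np.random.SeedSequence(sim.seed).spawn(1)[0])
    for r, s in enumerate(seeds):
        strategies, adherent, img, pub = K.random_state_init(N, s, False)
        evolve_mode = K.EVOLVE_ADHERENCE
        if background_mix is not None:
            n_x, n_y, n_zn = background_mix
            if n_x + n_y + n_zn != N:
                raise ValueError("background_mix must sum to N")
            comp = np.repeat(
                np.array([Strategy.ALLC, Strategy.ALLD, Strategy.DISC], dtype=np.int8),
                np.array([n_x, n_y, n_zn]),
            )
            rng.shuffle(comp)
            strategies[:] = comp
            evolve_mode = K.EVOLVE_TYPE
        if invader == "private":
            adherent[:] = True
        # reputation equilibration without trait evolution
        K.run_generations(
            strategies, adherent, img, pub, norm_arr,
            game.e1, game.e2, sim.E, game.b, game.c, sim.w, 0.0,
            inst.Q, inst.k_min, internal,
            equilibration, K.EVOLVE_NONE, False, coop, payoff,
        )
        good_at_intro[r] = mean_good_frequency(img)
        # introduce the invader(s)
        if initial_adherents == "uniform-random":
            k = int(rng.integers(1, N))
        else:
            k = int(initial_adherents)
        if background_mix is not None:
            disc = np.flatnonzero(strategies == Strategy.DISC)
            pick = rng.choice(disc, size=k, replace=False)
        else:
            pick = rng.choice(N, size=k, replace=False)
        if invader == "private":
            adherent[pick] = False
        else:
            adherent[pick] = True
        gens, absorb = K.run_generations(
            strategies, adherent, img, pub, norm_arr,
            game.e1, game.e2, sim.E, game.b, game.c, sim.w, 0.0,
            inst.Q, inst.k_min, internal,
            max_generations, evolve_mode, True, coop, payoff,
        )
        if absorb == K.ABSORB_NONE:
            raise RuntimeError(
                f"fixation replicate {r} did not absorb within {max_generations} generations"
            )
        gens_used[r] = gens
        invader_fixed = absorb == (
            K.ABSORB_EXTINCT if invader == "private" else K.ABSORB_FIXED
        )
        if invader_fixed:
            n_fixed += 1
    p = n_fixed / sim.replicates
    return FixationResult(
        probability=p,
        ci=_binomial_ci(n_fixed, sim.replicates),
        n_fixed=n_fixed,
        replicates=sim.replicates,
        mean_good_at_intro=float(good_at_intro.mean()),
        mean_generations=float(gens_used.mean()),
    )
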