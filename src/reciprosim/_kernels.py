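"""Numba kernels for the finite-population Monte Carlo simulator.

The per-generation schedule (all arrays mutated in place):

1. game phase: every ordered donor-recipient pair, including self, plays
   one donation game; intents follow the donor's strategy and her operative
   view of the recipient (broadcast if adherent, private image otherwise),
   cooperative intents slip to defection with probability e1; self-pairs
   contribute no net payoff but remain observable;
2. observation phase: every individual privately re-assesses every donor
   from one uniformly sampled interaction of that donor (with probability E
   the donor's own operative view of the recipient is adopted -- empathy);
   each of the Q institutional voters does the same using the broadcast
   view (external board, or adherent internal member) or her own image
   (non-adherent internal member); every verdict flips with probability e2;
3. broadcast phase: a member's new public reputation is good iff at least
   k_min votes are good; new images and broadcasts take effect next
   generation;
4. imitation phase: one random ordered pair (i, j); i adopts j's heritable
   trait with the Fermi probability 1/(1+exp(-w (Pi_j - Pi_i))) on average
   payoffs (total / N);
5. mutation phase (strategy evolution only): with probability mu one random
   individual switches to a uniformly random strategy.

Seeding uses numba's per-thread numpy legacy RNG: identical seed and
parameters give bit-identical trajectories.
"""
from __future__ import annotations

import numpy as np
from numba import njit

# evolve modes
EVOLVE_NONE = 0
EVOLVE_STRATEGY = 1
EVOLVE_ADHERENCE = 2
EVOLVE_TYPE = 3  # strategy + adherence copied together

# absorption states for the adherence trait
ABSORB_NONE = -1
ABSORB_EXTINCT = 0
ABSORB_FIXED = 1


@njit(cache=True)
def _play_games(strategies, adherent, img, pub, e1, b, c, A, payoff):
    N = strategies.shape[0]
    coop = 0
    for d in range(N):
        adh = adherent[d]
        s = strategies[d]
        for r in range(N):
            if s == 0:  # ALLC
                intent = 1
            elif s == 1:  # ALLD
                intent = 0
            else:  # DISC
                if adh:
                    intent = pub[r]
                else:
                    intent = img[d, r]
            act = intent
            if intent == 1 and np.random.random() < e1:
                act = 0
            A[d, r] = act
            if act == 1:
                coop += 1
                if d != r:
                    payoff[d] -= c
                    payoff[r] += b
    return coop


@njit(cache=True)
def _observe(strategies, adherent, img, pub, A, norm, e2, E, new_img):
    N = strategies.shape[0]
    for o in range(N):
        for d in range(N):
            s = np.random.randint(0, N)
            if E > 0.0 and np.random.random() < E:
                if adherent[d]:
                    v = pub[s]
                else:
                    v = img[d, s]
            else:
                v = img[o, s]
            gval = norm[A[d, s], v]
            if np.random.random() < e2:
                gval = 1 - gval
            new_img[o, d] = gval


@njit(cache=True)
def _vote_and_broadcast(adherent, img, pub, A, norm, e2, Q, k_min, internal, new_pub):
    N = pub.shape[0]
    for d in range(N):
        votes = 0
        for v_idx in range(Q):
            s = np.random.randint(0, N)
            if internal and not adherent[v_idx]:
                v = img[v_idx, s]
            else:
                v = pub[s]
            gval = norm[A[d, s], v]
            if np.random.random() < e2:
                gval = 1 - gval
            votes += gval
        if votes >= k_min:
            new_pub[d] = 1
        else:
            new_pub[d] = 0


@njit(cache=True)
def _imitate_and_mutate(strategies, adherent, payoff, N, w, mu, evolve_mode):
    i = np.random.randint(0, N)
    j = np.random.randint(0, N)
    while j == i:
        j = np.random.randint(0, N)
    p = 1.0 / (1.0 + np.exp(-w * (payoff[j] - payoff[i]) / N))
    if np.random.random() < p:
        if evolve_mode == EVOLVE_STRATEGY:
            strategies[i] = strategies[j]
        elif evolve_mode == EVOLVE_ADHERENCE:
            adherent[i] = adherent[j]
        else:
            strategies[i] = strategies[j]
            adherent[i] = adherent[j]
    if (evolve_mode == EVOLVE_STRATEGY or evolve_mode == EVOLVE_TYPE) and mu > 0.0:
        if np.random.random() < mu:
            k = np.random.randint(0, N)
            strategies[k] = np.random.randint(0, 3)


@njit(cache=True)
def run_generations(
    strategies,
    adherent,
    img,
    pub,
    norm,
    e1,
    e2,
    E,
    b,
    c,
    w,
    mu,
    Q,
    k_min,
    internal,
    n_generations,
    evolve_mode,
    stop_on_adherence_absorb,
    coop_out,
    payoff_out,
):
    """Run up to ``n_generations`` generations in place.

    Returns (generations_run, absorb_state).  ``coop_out`` (length >=
    n_generations) receives the per-generation fraction of cooperative
    donor decisions (out of N*N); ``payoff_out`` the last generation's
    total payoffs.
    """
    N = strategies.shape[0]
    A = np.zeros((N, N), dtype=np.uint8)
    new_img = np.zeros((N, N), dtype=np.uint8)
    new_pub = np.zeros(N, dtype=np.uint8)
    absorb = ABSORB_NONE
    gens = 0
    for gen in range(n_generations):
        payoff_out[:] = 0.0
        coop = _play_games(strategies, adherent, img, pub, e1, b, c, A, payoff_out)
        _observe(strategies, adherent, img, pub, A, norm, e2, E, new_img)
        _vote_and_broadcast(adherent, img, pub, A, norm, e2, Q, k_min, internal, new_pub)
        img[:, :] = new_img
        pub[:] = new_pub
        if evolve_mode != EVOLVE_NONE:
            _imitate_and_mutate(strategies, adherent, payoff_out, N, w, mu, evolve_mode)
        coop_out[gen] = coop / (N * N)
        gens = gen + 1
        if stop_on_adherence_absorb:
            n_adh = 0
            for idx in range(N):
                if adherent[idx]:
                    n_adh += 1
            if n_adh == 0:
                absorb = ABSORB_EXTINCT
                break
            if n_adh == N:
                absorb = ABSORB_FIXED
                break
    return gens, absorb


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def random_state_init(N, seed, random_strategies):
    """Fresh population state: uniform random strategies (optional) and
    fair-coin private images and broadcasts."""
    np.random.seed(seed)
    strategies = np.empty(N, dtype=np.int8)
    for i in range(N):
        if random_strategies:
            strategies[i] = np.random.randint(0, 3)
        else:
            strategies[i] = 2  # DISC
    adherent = np.zeros(N, dtype=np.bool_)
    img = np.empty((N, N), dtype=np.uint8)
    for i in range(N):
        for j in range(N):
            img[i, j] = 1 if np.random.random() < 0.5 else 0
    pub = np.empty(N, dtype=np.uint8)
    for i in range(N):
        pub[i] = 1 if np.random.random() < 0.5 else 0
    return strategies, adherent, img, pub
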