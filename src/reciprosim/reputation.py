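"""Equilibrium reputation frequencies under public and mixed assessment.

Two fixed-point systems are solved here, both under the timescale-separation
assumption that reputations equilibrate before strategy frequencies move:

* **Full adherence** -- everyone acts on the institutional broadcast.  The
  per-observer good-fractions ``g_i`` of the three strategies (ALLC, ALLD,
  DISC) satisfy a norm-specific linear system in the population broadcast
  fraction ``G``, closed by the binomial vote-aggregation rule of the
  institution.

* **Mixed adherence** -- the population contains institutional adherents
  (DISC-ADHERE, acting on broadcasts) and non-adherents (DISC-PRIVATE,
  acting on private images), plus optionally ALLC and ALLD.  The unknowns
  are the cross-class good-fractions ``g[i][j]`` (donor class i as seen by
  observer class j), coupled through the agreement aggregates
  ``G, g_dot, gamma2, g2``.

For ``e1, e2 > 0`` every right-hand side is a convex combination of values
in (0, 1) and each system has a unique feasible solution, reached here by
damped fixed-point iteration from any interior start.  (The *undamped* map
can oscillate in a 2-cycle for Q >= 2 institutions at some frequency mixes;
the default damping of 0.5 averages the cycle away.)

A modelling assumption baked into the aggregates and the binomial vote
counts: two distinct observers' views of the same individual are
conditionally independent given that individual's class (the "independence
closure").
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core import Action, GameParams, Institution, Rep, SocialNorm, Strategy, intended_action, assessment_probability

__all__ = [
    "ConvergenceError",
    "FullAdherenceReputations",
    "MixedReputations",
    "institutional_aggregate",
    "solve_full_adherence",
    "donor_good_probability",
    "solve_mixed_equilibrium",
    "MIXED_CLASSES",
]

#: Class labels of the four-type competition model, in canonical order.
MIXED_CLASSES = ("X", "Y", "Za", "Zn")
_CLASS_INDEX = {name: k for k, name in enumerate(MIXED_CLASSES)}
_OBSERVER_INDEX = {"Za": 0, "Zn": 1}


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed to reach tolerance."""

    def __init__(self, message: str, residual: float, iterations: int):
        super().__init__(f"{message} (residual={residual:.3e} after {iterations} iterations)")
        self.residual = residual
        self.iterations = iterations


def _warn_zero_errors(params: GameParams) -> None:
    if params.e1 == 0.0 or params.e2 == 0.0:
        warnings.warn(
            "e1 = 0 or e2 = 0: the contraction guarantee for the reputation "
            "fixed point requires strictly positive error rates",
            stacklevel=3,
        )


def _norm_probs(norm: SocialNorm, params: GameParams) -> tuple[tuple[float, float], tuple[float, float]]:
    """P[view][intent]: probability the donor is assessed good, given the
    observer's view of the recipient (0=bad, 1=good) and the donor's intent
    (0=defect, 1=cooperate)."""
    return tuple(
        tuple(assessment_probability(norm, view, intent, params) for intent in (0, 1))
        for view in (0, 1)
    )  # type: ignore[return-value]


def institutional_aggregate(g_member: float, inst: Institution) -> float:
    """Probability of a good broadcast when each of Q independent votes is
    good with probability ``g_member``: the upper binomial tail at k_min.

    Reduces to ``1-(1-g)**Q`` for tolerant institutions, ``g**Q`` for
    strict ones, and to the identity for Q=1.
    """
    if not (0.0 <= g_member <= 1.0):
        raise ValueError(f"g_member must lie in [0, 1], got {g_member}")
    Q, k_min = inst.Q, inst.k_min
    if k_min <= 0:
        return 1.0
    # small Q: direct sum is exact and fast
    g = g_member
    return float(
        sum(math.comb(Q, k) * g**k * (1.0 - g) ** (Q - k) for k in range(k_min, Q + 1))
    )


def _binomial_pmf(n: int, p: float) -> np.ndarray:
    k = np.arange(n + 1)
    comb = np.array([math.comb(n, int(i)) for i in k], dtype=float)
    return comb * p**k * (1.0 - p) ** (n - k)


@dataclass(frozen=True)
class FullAdherenceReputations:
    """Equilibrium good-fractions under complete institutional adherence.

    ``g_i`` is the probability a random observer views a member of strategy
    i as good; ``G_i`` the probability the institution broadcasts them as
    good; ``G`` the frequency-weighted mean broadcast.
    """

    g_X: float
    g_Y: float
    g_Z: float
    G_X: float
    G_Y: float
    G_Z: float
    G: float
    residual: float
    iterations: int

    @property
    def g(self) -> tuple[float, float, float]:
        return (self.g_X, self.g_Y, self.g_Z)

    @property
    def G_by_strategy(self) -> tuple[float, float, float]:
        return (self.G_X, self.G_Y, self.G_Z)


def _check_simplex(freqs, n: int, tol: float = 1e-9):
    f = np.asarray(freqs, dtype=float)
    if f.shape != (n,):
        raise ValueError(f"expected a {n}-vector of frequencies, got shape {f.shape}")
    if (f < -tol).any() or abs(f.sum() - 1.0) > max(tol, 1e-9):
        raise ValueError(f"frequencies must be nonnegative and sum to 1, got {f!r}")
    return np.clip(f, 0.0, None) / np.clip(f, 0.0, None).sum()


def solve_full_adherence(
    norm: SocialNorm,
    params: GameParams,
    inst: Institution,
    freqs,
    *,
    tol: float = 1e-12,
    max_iter: int = 100_000,
    damping: float = 0.5,
    init=None,
) -> FullAdherenceReputations:
    """Solve the per-strategy good-fraction fixed point under full adherence.

    ``freqs`` = (f_X, f_Y, f_Z) on the simplex.  The map re-expresses each
    ``g_i`` through the broadcast mean ``G``: an ALLC donor is judged as a
    cooperator against a G/(1-G) mixture of good/bad recipients, an ALLD
    donor as a defector, and a DISC donor cooperates with good-broadcast
    recipients and defects against the rest.

    ``damping`` in (0, 1] blends old and new iterates; the default 0.5
    suppresses the 2-cycles the undamped map can fall into when the
    institutional aggregation is steep (Q >= 2).
    """
    f = _check_simplex(freqs, 3)
    _warn_zero_errors(params)
    P = _norm_probs(norm, params)
    C, D = Action.COOPERATE, Action.DEFECT

    g = np.full(3, 0.5) if init is None else np.clip(np.asarray(init, dtype=float), 0.0, 1.0)
    lam = float(damping)
    residual = math.inf
    for it in range(1, max_iter + 1):
        G_i = np.array([institutional_aggregate(gi, inst) for gi in g])
        G = float(f @ G_i)
        new = np.array(
            [
                G * P[Rep.GOOD][C] + (1.0 - G) * P[Rep.BAD][C],
                G * P[Rep.GOOD][D] + (1.0 - G) * P[Rep.BAD][D],
                G * P[Rep.GOOD][C] + (1.0 - G) * P[Rep.BAD][D],
            ]
        )
        residual = float(np.max(np.abs(new - g)))
        g = (1.0 - lam) * g + lam * new
        if residual < tol:
            break
    else:
        raise ConvergenceError("full-adherence reputation solve did not converge", residual, max_iter)

    G_i = np.array([institutional_aggregate(gi, inst) for gi in g])
    G = float(f @ G_i)
    return FullAdherenceReputations(
        g_X=float(g[0]), g_Y=float(g[1]), g_Z=float(g[2]),
        G_X=float(G_i[0]), G_Y=float(G_i[1]), G_Z=float(G_i[2]),
        G=G, residual=residual, iterations=it,
    )


@dataclass(frozen=True)
class MixedReputations:
    """Equilibrium cross-class good-fractions for adherent/non-adherent mix.

    ``g_mat[i, j]`` is the probability an observer of class j (0=Za, 1=Zn)
    privately views a member of donor class i (order X, Y, Za, Zn) as good;
    ``G_i`` are the broadcast good-fractions.  Aggregates:

    * ``G``      -- population broadcast good-fraction, sum f_i G_i
    * ``g_dot``  -- fraction a non-adherent sees as good, sum f_i g[i][Zn]
    * ``gamma2`` -- P(adherent and non-adherent agree someone is good)
    * ``g2``     -- P(two non-adherents agree someone is good)
    """

    freqs: tuple[float, float, float, float]
    g_mat: np.ndarray  # (4, 2)
    G_i: np.ndarray  # (4,)
    G: float
    g_dot: float
    gamma2: float
    g2: float
    residual: float
    iterations: int

    def g(self, donor: str, observer: str) -> float:
        """Good-fraction of donor class as seen by observer class,
        e.g. ``reps.g("Za", "Zn")``."""
        return float(self.g_mat[_CLASS_INDEX[donor], _OBSERVER_INDEX[observer]])

    def G_of(self, donor: str) -> float:
        return float(self.G_i[_CLASS_INDEX[donor]])

    def aggregates(self) -> dict[str, float]:
        return {"G": self.G, "g_dot": self.g_dot, "gamma2": self.gamma2, "g2": self.g2}

    def to_dict(self) -> dict[str, float]:
        out = {}
        for i, donor in enumerate(MIXED_CLASSES):
            for observer, j in _OBSERVER_INDEX.items():
                out[f"g_{donor}_{observer}"] = float(self.g_mat[i, j])
            out[f"G_{donor}"] = float(self.G_i[i])
        out.update(self.aggregates())
        return out


def _pair_joint(donor_class: str, observer_class: str, agg: dict[str, float]):
    """Joint distribution of (observer view, donor view) of a random
    recipient, for a (donor, observer) class pair, under the independence
    closure.  Returns entries ((obs_bad,don_bad), (obs_bad,don_good),
    (obs_good,don_bad), (obs_good,don_good)) as a 2x2 nested tuple
    [obs_view][donor_view].

    For ALLC/ALLD donors the donor's view is irrelevant; the marginal
    observer view is used with the donor view collapsed.
    """
    G, g_dot, gamma2, g2 = agg["G"], agg["g_dot"], agg["gamma2"], agg["g2"]
    if donor_class in ("X", "Y"):
        p = G if observer_class == "Za" else g_dot
        # donor view set arbitrarily to bad with the full marginal mass
        return ((1.0 - p, 0.0), (p, 0.0))
    if donor_class == "Za" and observer_class == "Za":
        # both consult the same broadcast: perfectly correlated
        return ((1.0 - G, 0.0), (0.0, G))
    if donor_class == "Za" and observer_class == "Zn":
        return (
            (1.0 - G - g_dot + gamma2, G - gamma2),
            (g_dot - gamma2, gamma2),
        )
    if donor_class == "Zn" and observer_class == "Za":
        return (
            (1.0 - G - g_dot + gamma2, g_dot - gamma2),
            (G - gamma2, gamma2),
        )
    # Zn donor, Zn observer: two exchangeable private views
    return (
        (1.0 - 2.0 * g_dot + g2, g_dot - g2),
        (g_dot - g2, g2),
    )


_CLASS_STRATEGY = {"X": Strategy.ALLC, "Y": Strategy.ALLD, "Za": Strategy.DISC, "Zn": Strategy.DISC}


def donor_good_probability(
    norm: SocialNorm,
    params: GameParams,
    donor_class: str,
    observer_class: str,
    aggregates: dict[str, float],
    *,
    literal_eq16: bool = False,
) -> float:
    """Probability one observed interaction leaves the observer class
    viewing the donor class as good.

    Enumerates the (observer view, donor view) configurations of a random
    recipient, takes the donor's intent from her strategy and *her own*
    operative view, and weights the norm's assessment probability by each
    configuration's probability.

    ``literal_eq16`` switches the (Y donor, Zn observer) entry under Stern
    Judging to a variant with epsilon in place of e2 in the good-view
    branch, retained for comparison; the generic construction is the
    default.
    """
    if donor_class not in _CLASS_INDEX or observer_class not in _OBSERVER_INDEX:
        raise ValueError(f"unknown class pair ({donor_class!r}, {observer_class!r})")
    if literal_eq16 and donor_class == "Y" and observer_class == "Zn" and norm.name == "stern_judging":
        g_dot = aggregates["g_dot"]
        return g_dot * params.epsilon + (1.0 - g_dot) * (1.0 - params.e2)
    P = _norm_probs(norm, params)
    joint = _pair_joint(donor_class, observer_class, aggregates)
    strategy = _CLASS_STRATEGY[donor_class]
    total = 0.0
    for obs_view in (0, 1):
        for donor_view in (0, 1):
            w = joint[obs_view][donor_view]
            if w == 0.0:
                continue
            intent = intended_action(strategy, donor_view)
            total += w * P[obs_view][intent]
    return total


def _mixed_broadcasts(g_mat: np.ndarray, freqs: np.ndarray, inst: Institution) -> np.ndarray:
    """Broadcast good-fraction per donor class, given per-observer-class
    private good-fractions and the board composition rule."""
    Q, k_min = inst.Q, inst.k_min
    if inst.board == "external":
        # external board members assess like adherent observers
        return np.array([institutional_aggregate(g_mat[i, 0], inst) for i in range(4)])
    f_Za, f_Zn = freqs[2], freqs[3]
    denom = f_Za + f_Zn
    if denom <= 0.0:
        raise ValueError("internal board requires f_Za + f_Zn > 0 (no one to staff the board)")
    w_a = f_Za / denom
    out = np.empty(4)
    for i in range(4):
        ga, gn = g_mat[i, 0], g_mat[i, 1]
        if k_min <= 0:
            out[i] = 1.0
            continue
        acc = 0.0
        for k in range(Q + 1):  # k non-adherent members
            w = math.comb(Q, k) * w_a ** (Q - k) * (1.0 - w_a) ** k
            if w == 0.0:
                continue
            pmf = np.convolve(_binomial_pmf(Q - k, ga), _binomial_pmf(k, gn))
            acc += w * float(pmf[k_min:].sum())
        out[i] = acc
    return np.clip(out, 0.0, 1.0)


def _mixed_aggregates(g_mat: np.ndarray, G_i: np.ndarray, freqs: np.ndarray) -> dict[str, float]:
    g_n = g_mat[:, 1]
    return {
        "G": float(freqs @ G_i),
        "g_dot": float(freqs @ g_n),
        "gamma2": float(freqs @ (G_i * g_n)),
        "g2": float(freqs @ (g_n**2)),
    }


def solve_mixed_equilibrium(
    norm: SocialNorm,
    params: GameParams,
    inst: Institution,
    freqs,
    *,
    tol: float = 1e-12,
    max_iter: int = 100_000,
    damping: float = 0.5,
    init=None,
    literal_eq16: bool = False,
) -> MixedReputations:
    """Solve the cross-class reputation fixed point for a four-class
    population (X=ALLC, Y=ALLD, Za=DISC-ADHERE, Zn=DISC-PRIVATE).

    ``freqs`` = (f_X, f_Y, f_Za, f_Zn) on the simplex.  With f_Za = 1 the
    solution coincides with :func:`solve_full_adherence` at (0, 0, 1); with
    f_Zn = 1 it reduces to the classic non-empathetic private-assessment
    model.
    """
    f = _check_simplex(freqs, 4)
    _warn_zero_errors(params)
    if inst.board == "internal" and f[2] + f[3] <= 0.0:
        raise ValueError("internal board requires f_Za + f_Zn > 0 (no one to staff the board)")

    g = np.full((4, 2), 0.5) if init is None else np.clip(np.asarray(init, dtype=float).reshape(4, 2), 0.0, 1.0)
    lam = float(damping)
    residual = math.inf
    for it in range(1, max_iter + 1):
        G_i = _mixed_broadcasts(g, f, inst)
        agg = _mixed_aggregates(g, G_i, f)
        new = np.empty_like(g)
        for i, donor in enumerate(MIXED_CLASSES):
            for observer, j in _OBSERVER_INDEX.items():
                new[i, j] = donor_good_probability(
                    norm, params, donor, observer, agg, literal_eq16=literal_eq16
                )
        residual = float(np.max(np.abs(new - g)))
        g = (1.0 - lam) * g + lam * new
        if residual < tol:
            break
    else:
        raise ConvergenceError("mixed-adherence reputation solve did not converge", residual, max_iter)

    G_i = _mixed_broadcasts(g, f, inst)
    agg = _mixed_aggregates(g, G_i, f)
    return MixedReputations(
        freqs=tuple(float(x) for x in f),
        g_mat=g.copy(),
        G_i=G_i,
        G=agg["G"],
        g_dot=agg["g_dot"],
        gamma2=agg["gamma2"],
        g2=agg["g2"],
        residual=residual,
        iterations=it,
    )
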