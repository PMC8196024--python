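"""Replicator dynamics of strategies and of institutional adherence.

Payoffs come from the donation game played against the whole (infinite)
population at reputation equilibrium; frequencies then follow the standard
replicator equation f_i' = f_i (Pi_i - mean(Pi)).  Every evaluation of the
derivative re-solves the reputation fixed point at the current frequencies
(timescale separation), warm-started from the previous solution.

Three assessment modes are supported for three-strategy dynamics:

* ``institution`` -- complete adherence to a public institution (the
  classic public-reputation model when Q=1);
* ``private``     -- non-empathetic private assessment, realized as the
  mixed adherent/non-adherent model at f_Za = 0.

Competition between adherents and non-adherents is analyzed through the
adherent growth rate and the critical benefit-to-cost ratio rho at which
selection on adherence changes sign.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .core import GameParams, Institution, SocialNorm
from .reputation import (
    FullAdherenceReputations,
    MixedReputations,
    solve_full_adherence,
    solve_mixed_equilibrium,
)

__all__ = [
    "PayoffVector",
    "payoffs_full_adherence",
    "payoffs_mixed",
    "replicator_rhs",
    "Trajectory",
    "integrate_trajectory",
    "Equilibrium",
    "EquilibriumReport",
    "EquilibriumClassification",
    "classify_equilibrium",
    "find_equilibria_and_basins",
    "cooperation_rate",
    "GrowthRate",
    "adherent_growth_rate",
    "CriticalRatio",
    "critical_ratio",
    "InstitutionEconomics",
    "institution_economics",
    "simplex_grid",
]


@dataclass(frozen=True)
class PayoffVector:
    """Per-class mean payoffs and their frequency-weighted mean."""

    values: tuple[float, ...]
    mean: float
    labels: tuple[str, ...]

    def __getitem__(self, key):
        if isinstance(key, str):
            return self.values[self.labels.index(key)]
        return self.values[key]


def payoffs_full_adherence(freqs, reps: FullAdherenceReputations, params: GameParams) -> PayoffVector:
    """Mean payoffs of ALLC (X), ALLD (Y), DISC (Z) under full adherence.

    A class earns b from every ALLC partner and from every DISC partner who
    sees it as good (broadcast G_i); ALLC always pays the cost, DISC pays
    it toward the good-broadcast fraction G of the population; all terms
    are discounted by the execution success 1 - e1.
    """
    f = np.asarray(freqs, dtype=float)
    b, c, s = params.b, params.c, 1.0 - params.e1
    pi = (
        s * b * (f[0] + f[2] * reps.G_X) - s * c,
        s * b * (f[0] + f[2] * reps.G_Y),
        s * b * (f[0] + f[2] * reps.G_Z) - s * c * reps.G,
    )
    return PayoffVector(values=pi, mean=float(f @ np.array(pi)), labels=("X", "Y", "Z"))


def payoffs_mixed(freqs, reps: MixedReputations, params: GameParams) -> PayoffVector:
    """Mean payoffs of X, Y, Za, Zn in the mixed-adherence model.

    Non-adherent discriminators cooperate toward the fraction g_dot they
    privately see as good; adherents cooperate toward the broadcast
    fraction G.  Benefits received depend on how each donor class is seen
    by the discriminators doing the giving.
    """
    f = np.asarray(freqs, dtype=float)
    b, c, s = params.b, params.c, 1.0 - params.e1
    g = reps.g
    pi = (
        s * b * (f[0] + f[3] * g("X", "Zn") + f[2] * reps.G_of("X")) - s * c,
        s * b * (f[0] + f[3] * g("Y", "Zn") + f[2] * reps.G_of("Y")),
        s * b * (f[0] + f[3] * g("Za", "Zn") + f[2] * reps.G_of("Za")) - s * c * reps.G,
        s * b * (f[0] + f[3] * g("Zn", "Zn") + f[2] * reps.G_of("Zn")) - s * c * reps.g_dot,
    )
    return PayoffVector(values=pi, mean=float(f @ np.array(pi)), labels=("X", "Y", "Za", "Zn"))


def replicator_rhs(freqs, payoffs: PayoffVector) -> np.ndarray:
    """f_i (Pi_i - mean payoff); components sum to zero on the simplex."""
    f = np.asarray(freqs, dtype=float)
    pi = np.asarray(payoffs.values, dtype=float)
    return f * (pi - payoffs.mean)


def cooperation_rate(freqs, reps, params: GameParams) -> float:
    """Fraction of donor decisions realized as cooperation.

    ALLC always intends to cooperate; discriminators intend to cooperate
    toward the fraction of the population their operative view marks good
    (broadcast G for adherents, private g_dot for non-adherents); the
    execution error discounts everything by 1 - e1.
    """
    f = np.asarray(freqs, dtype=float)
    s = 1.0 - params.e1
    if isinstance(reps, FullAdherenceReputations):
        return float(s * (f[0] + f[2] * reps.G))
    return float(s * (f[0] + f[3] * reps.g_dot + f[2] * reps.G))


class _RepCache:
    """Warm-started reputation solves keyed by assessment mode."""

    def __init__(self, norm, params, inst, mode: str, tol: float = 1e-12):
        if mode not in ("institution", "private"):
            raise ValueError(f"mode must be 'institution' or 'private', got {mode!r}")
        if mode == "institution" and inst is None:
            raise ValueError("mode='institution' requires an Institution")
        self.norm, self.params, self.inst, self.mode, self.tol = norm, params, inst, mode, tol
        self._init = None
        # private mode never consults the board; any placeholder works
        self._dummy = inst if inst is not None else Institution(Q=1, q=0.5)

    def solve(self, f3):
        if self.mode == "institution":
            reps = solve_full_adherence(
                self.norm, self.params, self.inst, f3, tol=self.tol, init=self._init
            )
            self._init = np.array(reps.g)
        else:
            f4 = (f3[0], f3[1], 0.0, f3[2])
            reps = solve_mixed_equilibrium(
                self.norm, self.params, self._dummy, f4, tol=self.tol, init=self._init
            )
            self._init = reps.g_mat
        return reps

    def payoffs(self, f3, reps):
        if self.mode == "institution":
            return payoffs_full_adherence(f3, reps, self.params)
        pv = payoffs_mixed((f3[0], f3[1], 0.0, f3[2]), reps, self.params)
        return PayoffVector(
            values=(pv["X"], pv["Y"], pv["Zn"]), mean=pv.mean, labels=("X", "Y", "Z")
        )

    def coop(self, f3, reps):
        if self.mode == "institution":
            return cooperation_rate(f3, reps, self.params)
        return cooperation_rate((f3[0], f3[1], 0.0, f3[2]), reps, self.params)


def _project(f):
    f = np.clip(np.asarray(f, dtype=float), 0.0, None)
    return f / f.sum()


@dataclass(frozen=True)
class Trajectory:
    t: np.ndarray
    states: np.ndarray  # (len(t), 3)
    converged: bool
    terminal_rhs_norm: float

    @property
    def terminal(self) -> np.ndarray:
        return self.states[-1]


def integrate_trajectory(
    initial,
    norm: SocialNorm,
    params: GameParams,
    inst: Institution | None = None,
    *,
    mode: str = "institution",
    t_max: float = 20_000.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    eq_tol: float = 1e-9,
    chunk: float = 500.0,
) -> Trajectory:
    """Integrate three-strategy replicator dynamics from ``initial``.

    Integration proceeds in chunks of time ``chunk`` with an adaptive RK45
    scheme and stops early once the derivative norm falls below ``eq_tol``.
    States are renormalized onto the simplex between chunks (drift is at
    the solver-tolerance level).
    """
    cache = _RepCache(norm, params, inst, mode)

    def rhs(_t, f):
        f = _project(f)
        reps = cache.solve(f)
        return replicator_rhs(f, cache.payoffs(f, reps))

    f0 = _project(initial)
    t_all = [np.array([0.0])]
    y_all = [f0.reshape(1, 3)]
    t0 = 0.0
    f = f0
    converged = False
    while t0 < t_max:
        t1 = min(t0 + chunk, t_max)
        sol = solve_ivp(rhs, (t0, t1), f, method="RK45", rtol=rtol, atol=atol)
        if not sol.success:  # pragma: no cover - defensive
            raise RuntimeError(f"replicator integration failed: {sol.message}")
        t_all.append(sol.t[1:])
        y_all.append(sol.y.T[1:])
        f = _project(sol.y[:, -1])
        t0 = t1
        if float(np.linalg.norm(rhs(t0, f))) < eq_tol:
            converged = True
            break
    states = np.vstack(y_all)
    states = states / states.sum(axis=1, keepdims=True)
    return Trajectory(
        t=np.concatenate(t_all),
        states=states,
        converged=converged,
        terminal_rhs_norm=float(np.linalg.norm(rhs(t0, f))),
    )


def simplex_grid(resolution: int, interior_shift: float = 1e-4) -> np.ndarray:
    """Barycentric lattice on the 2-simplex with ``resolution`` steps per
    edge, shifted slightly inward so no start lies exactly on an invariant
    boundary face."""
    pts = []
    for i in range(resolution + 1):
        for j in range(resolution + 1 - i):
            k = resolution - i - j
            pts.append((i / resolution, j / resolution, k / resolution))
    pts = np.asarray(pts, dtype=float)
    pts = pts * (1.0 - 3.0 * interior_shift) + interior_shift
    return pts / pts.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class Equilibrium:
    freqs: tuple[float, float, float]
    stable: bool
    cooperation: float
    basin_fraction: float


@dataclass(frozen=True)
class EquilibriumReport:
    equilibria: tuple[Equilibrium, ...]
    unclassified_fraction: float
    n_starts: int

    @property
    def stable(self) -> tuple[Equilibrium, ...]:
        return tuple(e for e in self.equilibria if e.stable)


def _stability(f_eq, cache: _RepCache, h: float = 1e-6) -> bool:
    """Stability from eigenvalues of the central-finite-difference Jacobian
    of the reduced (f_X, f_Y) system on the simplex."""

    def rhs2(x):
        f = _project((x[0], x[1], max(1.0 - x[0] - x[1], 0.0)))
        reps = cache.solve(f)
        return replicator_rhs(f, cache.payoffs(f, reps))[:2]

    x0 = np.array(f_eq[:2])
    J = np.empty((2, 2))
    for k in range(2):
        dx = np.zeros(2)
        dx[k] = h
        J[:, k] = (rhs2(np.clip(x0 + dx, 0, 1)) - rhs2(np.clip(x0 - dx, 0, 1))) / (2 * h)
    eig = np.linalg.eigvals(J)
    return bool(np.all(eig.real < 1e-7))


def find_equilibria_and_basins(
    norm: SocialNorm,
    params: GameParams,
    inst: Institution | None = None,
    *,
    mode: str = "institution",
    resolution: int = 50,
    t_max: float = 20_000.0,
    cluster_radius: float = 1e-3,
    **integrate_kwargs,
) -> EquilibriumReport:
    """Classify replicator trajectories from a barycentric grid of starts.

    Trajectory endpoints are clustered with radius ``cluster_radius``;
    clusters whose trajectories converged are labelled as equilibria with a
    finite-difference stability check, and the basin fraction of each
    equilibrium is the share of grid starts ending there.  Trajectories
    still moving at ``t_max`` count toward the unclassified fraction.
    """
    if resolution < 10:
        raise ValueError("grid resolution must be >= 10 per simplex edge")
    starts = simplex_grid(resolution)
    endpoints = []
    converged_flags = []
    for f0 in starts:
        traj = integrate_trajectory(
            f0, norm, params, inst, mode=mode, t_max=t_max, **integrate_kwargs
        )
        endpoints.append(traj.terminal)
        converged_flags.append(traj.converged)
    endpoints = np.asarray(endpoints)

    centers: list[np.ndarray] = []
    counts: list[int] = []
    unclassified = 0
    assignments = []
    for pt, ok in zip(endpoints, converged_flags):
        if not ok:
            unclassified += 1
            assignments.append(-1)
            continue
        for idx, ctr in enumerate(centers):
            if np.linalg.norm(pt - ctr) < cluster_radius:
                # running mean keeps the center representative
                centers[idx] = (ctr * counts[idx] + pt) / (counts[idx] + 1)
                counts[idx] += 1
                assignments.append(idx)
                break
        else:
            centers.append(pt.copy())
            counts.append(1)
            assignments.append(len(centers) - 1)

    n = len(starts)
    cache = _RepCache(norm, params, inst, mode)
    eqs = []
    for ctr, cnt in zip(centers, counts):
        f_eq = _project(ctr)
        stable = _stability(f_eq, cache)
        reps = cache.solve(f_eq)
        eqs.append(
            Equilibrium(
                freqs=tuple(float(x) for x in f_eq),
                stable=stable,
                cooperation=cache.coop(f_eq, reps),
                basin_fraction=cnt / n,
            )
        )
    return EquilibriumReport(
        equilibria=tuple(eqs), unclassified_fraction=unclassified / n, n_starts=n
    )


@dataclass(frozen=True)
class EquilibriumClassification:
    is_equilibrium: bool
    stable: bool
    rhs_norm: float


def classify_equilibrium(
    freqs,
    norm: SocialNorm,
    params: GameParams,
    inst: Institution | None = None,
    *,
    mode: str = "institution",
    eq_tol: float = 1e-6,
) -> EquilibriumClassification:
    """Check whether a point is a replicator equilibrium and whether it is
    locally stable (eigenvalues of the reduced finite-difference Jacobian)."""
    cache = _RepCache(norm, params, inst, mode)
    f = _project(freqs)
    reps = cache.solve(f)
    rhs_norm = float(np.linalg.norm(replicator_rhs(f, cache.payoffs(f, reps))))
    return EquilibriumClassification(
        is_equilibrium=rhs_norm < eq_tol,
        stable=_stability(f, cache),
        rhs_norm=rhs_norm,
    )


@dataclass(frozen=True)
class GrowthRate:
    """Instantaneous replicator growth of the adherent type."""

    rate: float  # f_Za' per unit time
    payoff_difference: float  # Pi_Za - Pi_Zn
    reps: MixedReputations


def adherent_growth_rate(
    f_Za: float, norm: SocialNorm, params: GameParams, inst: Institution
) -> GrowthRate:
    """Replicator growth rate of DISC-ADHERE at frequency ``f_Za`` in a
    population otherwise composed of DISC-PRIVATE, at reputation
    equilibrium."""
    if not (0.0 < f_Za < 1.0):
        raise ValueError(f"f_Za must lie in (0, 1), got {f_Za}")
    freqs = (0.0, 0.0, f_Za, 1.0 - f_Za)
    reps = solve_mixed_equilibrium(norm, params, inst, freqs)
    pv = payoffs_mixed(freqs, reps, params)
    diff = pv["Za"] - pv["Zn"]
    # f'(Za) = f_Za (Pi_Za - mean) = f_Za f_Zn (Pi_Za - Pi_Zn)
    return GrowthRate(rate=f_Za * (1.0 - f_Za) * diff, payoff_difference=diff, reps=reps)


@dataclass(frozen=True)
class CriticalRatio:
    """Critical benefit-to-cost ratio for selection on adherence.

    ``orientation`` records on which side of rho adherence is favored:
    'favored_above' when the payoff-difference denominator is positive
    (b/c > rho favors adherents), 'favored_below' when negative, and
    'neutral' when the denominator vanishes (rho = +inf).
    """

    rho: float
    orientation: str
    numerator: float
    denominator: float


def critical_ratio(
    norm: SocialNorm, params: GameParams, inst: Institution, freqs
) -> CriticalRatio:
    """rho = (G - g_dot) / (f_Zn [g_{Za,Zn} - g_{Zn,Zn}] + f_Za [G_Za - G_Zn])
    at the mixed reputation equilibrium for ``freqs`` = (f_X, f_Y, f_Za,
    f_Zn).  Reputations do not depend on b or c, so rho is a single number
    at fixed frequencies; adherent_growth_rate changes sign exactly at
    b/c = rho."""
    reps = solve_mixed_equilibrium(norm, params, inst, freqs)
    f = np.asarray(freqs, dtype=float)
    num = reps.G - reps.g_dot
    den = f[3] * (reps.g("Za", "Zn") - reps.g("Zn", "Zn")) + f[2] * (
        reps.G_of("Za") - reps.G_of("Zn")
    )
    if den == 0.0:
        return CriticalRatio(rho=math.inf, orientation="neutral", numerator=num, denominator=den)
    orientation = "favored_above" if den > 0 else "favored_below"
    return CriticalRatio(rho=num / den, orientation=orientation, numerator=num, denominator=den)


@dataclass(frozen=True)
class InstitutionEconomics:
    """Sustainable per-round tax and bribe-robustness bound."""

    tax: float  # T = b - c*rho
    bribe_bound: float  # B_max = N*T / (Q*(1-p))
    self_sustaining: bool  # T >= 0


def institution_economics(
    b: float, c: float, rho: float, N: int, Q: int, p: float = 0.0
) -> InstitutionEconomics:
    """Back-of-envelope economics of a tax-funded institution.

    Individuals gaining b - c per round from institutionalized cooperation
    (vs. zero under all-defect private assessment) will pay a tax up to
    T = b - c*rho; each of the Q members collects N*T/Q per round, and with
    discovery probability p of corruption the member resists any bribe B
    with (1-p)B < N*T/Q.
    """
    if not math.isfinite(rho):
        raise ValueError("rho must be finite")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"discovery probability p must lie in [0, 1], got {p}")
    T = b - c * rho
    if p == 1.0:
        bound = math.inf
    else:
        bound = N * T / (Q * (1.0 - p))
    return InstitutionEconomics(tax=T, bribe_bound=bound, self_sustaining=T >= 0.0)
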