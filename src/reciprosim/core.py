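"""Parameter objects, social norms, and elementary assessment probabilities.

The model is the donation game with reputations: a donor may pay a cost ``c``
to confer a benefit ``b`` on a recipient, and third-party observers assign
the donor a good or bad reputation according to a second-order social norm --
a 2x2 table indexed by (donor action, recipient reputation).  Two error
processes perturb this: a cooperative intent is executed as defection with
probability ``e1``, and any single reputation assignment is flipped with
probability ``e2``.

Reputations may be private (each observer keeps her own image of everyone)
or provided by a public institution: ``Q`` designated observers whose
thresholded consensus (strictness ``q``) is broadcast to the population.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = [
    "Action",
    "Rep",
    "Strategy",
    "GameParams",
    "SocialNorm",
    "Institution",
    "SimulationParams",
    "NORMS",
    "NORM_NAMES",
    "get_norm",
    "assessment_probability",
    "intended_action",
]


class Action(IntEnum):
    """A donor's action in one donation game."""

    DEFECT = 0
    COOPERATE = 1


class Rep(IntEnum):
    """A binary moral reputation."""

    BAD = 0
    GOOD = 1


class Strategy(IntEnum):
    """Behavioral strategies: unconditional cooperation/defection, or
    discrimination on the recipient's (perceived) reputation."""

    ALLC = 0
    ALLD = 1
    DISC = 2


@dataclass(frozen=True)
class GameParams:
    """Donation-game payoffs and error rates.

    Parameters
    ----------
    b, c
        Benefit received by the recipient and cost paid by the donor per
        cooperative act, in payoff units; requires ``b > c > 0``.
    e1
        Execution error: probability that an intended cooperation is
        realized as defection.
    e2
        Assessment error: probability that an observer assigns the opposite
        of the norm-prescribed reputation.

    The derived quantity ``epsilon = (1-e2)(1-e1) + e2*e1`` is the
    probability that a donor who intends to cooperate with a good-view
    recipient ends up assessed as good (either she cooperates and is judged
    correctly, or she slips and is misjudged in her favor).
    """

    b: float = 5.0
    c: float = 1.0
    e1: float = 0.02
    e2: float = 0.02

    def __post_init__(self) -> None:
        if not (self.b > self.c > 0):
            raise ValueError(f"require b > c > 0, got b={self.b}, c={self.c}")
        if not (0.0 <= self.e1 < 1.0):
            raise ValueError(f"require 0 <= e1 < 1, got {self.e1}")
        if not (0.0 <= self.e2 < 1.0):
            raise ValueError(f"require 0 <= e2 < 1, got {self.e2}")

    @property
    def epsilon(self) -> float:
        """(1-e2)(1-e1) + e2*e1, recomputed on access."""
        return (1.0 - self.e2) * (1.0 - self.e1) + self.e2 * self.e1


# Norm tables: table[action, recipient_reputation] with rows indexed by
# Action (0=defect, 1=cooperate) and columns by Rep (0=bad, 1=good);
# entry 1 means the donor is assigned a good reputation.
_NORM_TABLES = {
    # endorse cooperation with good, defection with bad
    "stern_judging": ((1, 0), (0, 1)),
    # any treatment of a bad recipient is fine
    "simple_standing": ((1, 0), (1, 1)),
    # only the action matters: cooperation good, defection bad
    "scoring": ((0, 0), (1, 1)),
    # any interaction with a bad recipient is condemned
    "shunning": ((0, 0), (0, 1)),
}

NORM_NAMES = tuple(_NORM_TABLES)


@dataclass(frozen=True)
class SocialNorm:
    """A second-order assessment rule.

    ``table[action, recipient_rep]`` is 1 if the norm assigns the donor a
    good reputation, 0 otherwise; rows are (defect, cooperate), columns are
    (bad, good).  All canonical norms endorse cooperation with a good
    recipient and condemn defection against one; they differ in how they
    judge interactions with bad recipients.

    User-defined tables are accepted (experimental) as long as they are 2x2
    binary.
    """

    name: str
    table: tuple[tuple[int, int], tuple[int, int]]
    experimental: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        t = tuple(tuple(int(v) for v in row) for row in self.table)
        if len(t) != 2 or any(len(row) != 2 for row in t):
            raise ValueError("norm table must be 2x2")
        if any(v not in (0, 1) for row in t for v in row):
            raise ValueError("norm table entries must be 0 (Bad) or 1 (Good)")
        object.__setattr__(self, "table", t)
        if self.name in _NORM_TABLES and t != _NORM_TABLES[self.name]:
            raise ValueError(f"table does not match the canonical norm {self.name!r}")

    def assigns_good(self, action: int, recipient_rep: int) -> bool:
        return bool(self.table[int(action)][int(recipient_rep)])

    def as_array(self) -> np.ndarray:
        return np.array(self.table, dtype=np.uint8)


NORMS: dict[str, SocialNorm] = {
    name: SocialNorm(name, table) for name, table in _NORM_TABLES.items()
}

STERN_JUDGING = NORMS["stern_judging"]
SIMPLE_STANDING = NORMS["simple_standing"]
SCORING = NORMS["scoring"]
SHUNNING = NORMS["shunning"]


def get_norm(name: str) -> SocialNorm:
    """Look up a canonical norm by name (case-insensitive, '-' tolerated)."""
    key = name.strip().lower().replace("-", "_").replace(" ", "_")
    try:
        return NORMS[key]
    except KeyError:
        raise ValueError(
            f"unknown social norm {name!r}; choose from {', '.join(NORM_NAMES)}"
        ) from None


@dataclass(frozen=True)
class Institution:
    """A public monitoring institution.

    ``Q`` observers each independently assess every population member once
    per round; the member is broadcast as good iff at least ``k_min =
    ceil(q*Q)`` of the votes are good.  ``q`` is the strictness threshold:
    an institution is *tolerant* when a single good vote suffices
    (``q < 1/Q``) and *strict* when unanimity is required
    (``q > (Q-1)/Q``).

    ``board`` selects who staffs the institution in mixed
    adherent/non-adherent populations: an ``external`` board of dedicated
    broadcast-following observers outside the strategic population, or an
    ``internal`` board of population members who assess using their own
    mode (broadcast if adherent, private image otherwise).
    """

    Q: int = 2
    q: float = 0.5
    board: str = "external"

    def __post_init__(self) -> None:
        if int(self.Q) != self.Q or self.Q < 1:
            raise ValueError(f"Q must be an integer >= 1, got {self.Q}")
        object.__setattr__(self, "Q", int(self.Q))
        if not (0.0 <= self.q <= 1.0):
            raise ValueError(f"q must lie in [0, 1], got {self.q}")
        if self.board not in ("external", "internal"):
            raise ValueError(f"board must be 'external' or 'internal', got {self.board!r}")
        if self.k_min == 0:
            warnings.warn(
                "q = 0 gives k_min = 0: the institution broadcasts everyone as good",
                stacklevel=2,
            )

    @property
    def k_min(self) -> int:
        """Minimum number of good votes for a good broadcast, ceil(q*Q).

        q*Q is rounded to 12 decimals before the ceiling so that thresholds
        that are exactly integer in intent (e.g. q=0.5, Q=2) are not pushed
        up by binary-float noise.
        """
        return int(math.ceil(round(self.q * self.Q, 12)))

    @property
    def is_tolerant(self) -> bool:
        """One good vote suffices (q < 1/Q, i.e. k_min <= 1)."""
        return self.k_min <= 1

    @property
    def is_strict(self) -> bool:
        """Unanimity required (q > (Q-1)/Q, i.e. k_min == Q)."""
        return self.k_min == self.Q

    @classmethod
    def tolerant(cls, Q: int, board: str = "external") -> "Institution":
        """A maximally tolerant institution of size Q (q just below 1/Q)."""
        return cls(Q=Q, q=0.5 / Q, board=board)

    @classmethod
    def strict(cls, Q: int, board: str = "external") -> "Institution":
        """A maximally strict institution of size Q (q just above (Q-1)/Q)."""
        return cls(Q=Q, q=1.0 - 0.5 / Q, board=board)


@dataclass(frozen=True)
class SimulationParams:
    """Monte Carlo simulation settings.

    Defaults follow the finite-population protocol: N=50 individuals,
    selection strength w=1 in the pairwise-comparison (Fermi) imitation
    rule, strategy-exploration rate mu=0.025, empathy E=0.
    """

    N: int = 50
    w: float = 1.0
    mu: float = 0.025
    E: float = 0.0
    generations: int = 10_000
    burn_in: int = 5_000
    replicates: int = 2_500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError(f"N must be >= 2, got {self.N}")
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError(f"mu must lie in [0, 1], got {self.mu}")
        if not (0.0 <= self.E <= 1.0):
            raise ValueError(f"E must lie in [0, 1], got {self.E}")
        if not (0 <= self.burn_in < self.generations):
            raise ValueError(
                f"burn_in must satisfy 0 <= burn_in < generations, got "
                f"burn_in={self.burn_in}, generations={self.generations}"
            )
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def assessment_probability(
    norm: SocialNorm,
    observer_view_of_recipient: int,
    donor_intent: int,
    params: GameParams,
) -> float:
    """Probability that one observation leaves the donor with a good image.

    The donor *intends* ``donor_intent``; an intended cooperation is
    realized as defection with probability ``e1``, and the observer then
    applies the norm to the realized action and her view of the recipient,
    flipping the verdict with probability ``e2``.  For the canonical norms
    this reproduces the standard four-entry probability table with entries
    drawn from {epsilon, 1-epsilon, e2, 1-e2}.
    """
    view = int(observer_view_of_recipient)
    intent = int(donor_intent)
    e2 = params.e2

    def p_good(action: int) -> float:
        return 1.0 - e2 if norm.assigns_good(action, view) else e2

    if intent == Action.COOPERATE:
        e1 = params.e1
        return (1.0 - e1) * p_good(Action.COOPERATE) + e1 * p_good(Action.DEFECT)
    return p_good(Action.DEFECT)


def intended_action(strategy: int, view_of_recipient: int) -> Action:
    """The action a strategy intends toward a recipient it views as given."""
    s = Strategy(strategy)
    if s is Strategy.ALLC:
        return Action.COOPERATE
    if s is Strategy.ALLD:
        return Action.DEFECT
    return Action.COOPERATE if int(view_of_recipient) == Rep.GOOD else Action.DEFECT
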