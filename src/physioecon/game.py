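"""Bribery-auction game: payoffs, the official's choice rule, and equilibria.

The economy is a procurement auction between two firms and one official.
Each firm splits a fixed budget ``A`` between a quality bid ``Q`` (which
benefits every player through the social return ``a``) and a bribe ``B``
(which benefits only the official and costs the winning firm ``c`` per
monetary unit).  The official selects one of the two bids; the winner
additionally earns a reward ``R`` and every player receives a fixed
per-period endowment ``F``.

Monetary payoffs
----------------
.. math::

    \\pi_{official} &= F + a Q_w + B_w \\\\
    \\pi_{winner}   &= F + a Q_w - c B_w + R \\\\
    \\pi_{loser}    &= F + a Q_w

Psychological payoffs generalise these with a per-agent bribery-aversion
cost :math:`\\gamma` per monetary unit of bribe:

.. math::

    \\pi_{official} &= F + a Q_w + (1-\\gamma_{official}) B_w \\\\
    \\pi_{winner}   &= F + a Q_w - (c+\\gamma_{winner}) B_w + R \\\\
    \\pi_{loser}    &= F + a Q_w

Setting every :math:`\\gamma = 0` recovers the monetary payoffs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GameParams",
    "Bid",
    "AgentPreferences",
    "PayoffVector",
    "EquilibriumProfile",
    "PsychEquilibriumPrediction",
    "BudgetViolationError",
    "UndefinedBidError",
    "DEFAULT_PARAMS",
    "monetary_payoffs",
    "psychological_payoffs",
    "official_choice",
    "enumerate_equilibria",
    "psych_equilibrium_bids",
    "continuous_equilibrium_bribe",
    "apply_inspection",
    "equilibria_to_frame",
]


class BudgetViolationError(ValueError):
    """A bid does not satisfy the budget constraint Q + B = A."""


class UndefinedBidError(ValueError):
    """The closed-form equilibrium bid is undefined (c + gamma = 0)."""


@dataclass(frozen=True)
class GameParams:
    """Constants of the auction economy.

    Parameters
    ----------
    F : fixed per-period endowment earned by every subject (monetary units).
    a : social return per unit of winning quality (dimensionless).
    c : cost per monetary unit of bribe paid by the winner.
    A : total bid budget; every bid satisfies Q + B = A.
    R : extra reward earned by the auction winner (monetary units).
    """

    F: float = 10.0
    a: float = 0.5
    c: float = 2.0
    A: int = 10
    R: float = 10.0

    def __post_init__(self) -> None:
        for name in ("F", "a", "c", "A", "R"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not float(self.A).is_integer() or self.A <= 0:
            raise ValueError("A must be a positive integer")


DEFAULT_PARAMS = GameParams()


@dataclass(frozen=True)
class Bid:
    """A (quality, bribe) bid.  Validity against a budget is checked by
    :meth:`validate`; grid-refined analyses may use non-integer values."""

    Q: float
    B: float

    def validate(self, params: GameParams, *, tol: float = 1e-9) -> "Bid":
        if self.Q < -tol or self.B < -tol:
            raise BudgetViolationError(f"negative bid component: {self}")
        if abs(self.Q + self.B - params.A) > tol:
            raise BudgetViolationError(
                f"bid {self} violates Q + B = {params.A}"
            )
        return self

    @classmethod
    def from_bribe(cls, B: float, params: GameParams) -> "Bid":
        return cls(Q=params.A - B, B=B).validate(params)


@dataclass(frozen=True)
class AgentPreferences:
    """Bribery-aversion costs per monetary unit of bribe, one per agent.

    ``gamma = 0`` for every agent recovers the pure monetary payoffs.
    """

    gamma_official: float = 0.0
    gamma_firm1: float = 0.0
    gamma_firm2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("gamma_official", "gamma_firm1", "gamma_firm2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def gamma_firm(self, role: int) -> float:
        if role == 1:
            return self.gamma_firm1
        if role == 2:
            return self.gamma_firm2
        raise ValueError("firm role must be 1 or 2")


@dataclass(frozen=True)
class PayoffVector:
    """Payoffs of the three players for one resolved auction."""

    official: float
    winner: float
    loser: float

    def by_firm(self, winner_role: int) -> tuple[float, float]:
        """Map (winner, loser) payoffs back to (firm1, firm2) order."""
        if winner_role == 1:
            return (self.winner, self.loser)
        if winner_role == 2:
            return (self.loser, self.winner)
        raise ValueError("winner_role must be 1 or 2")


def monetary_payoffs(
    bid_winner: Bid,
    params: GameParams = DEFAULT_PARAMS,
    winner_role: int = 1,
) -> PayoffVector:
    """Monetary payoffs of official, winner and loser given the winning bid.

    ``winner_role`` is bookkeeping only (used by :meth:`PayoffVector.by_firm`
    callers); the payoff levels depend solely on the winning bid.
    """
    if winner_role not in (1, 2):
        raise ValueError("winner_role must be 1 or 2")
    bid_winner.validate(params)
    base = params.F + params.a * bid_winner.Q
    return PayoffVector(
        official=base + bid_winner.B,
        winner=base - params.c * bid_winner.B + params.R,
        loser=base,
    )


def psychological_payoffs(
    bid_winner: Bid,
    params: GameParams = DEFAULT_PARAMS,
    prefs: AgentPreferences = AgentPreferences(),
    winner_role: int = 1,
) -> PayoffVector:
    """Utilities under bribery aversion.  Reduces to :func:`monetary_payoffs`
    when every gamma is zero."""
    if winner_role not in (1, 2):
        raise ValueError("winner_role must be 1 or 2")
    bid_winner.validate(params)
    gamma_w = prefs.gamma_firm(winner_role)
    base = params.F + params.a * bid_winner.Q
    return PayoffVector(
        official=base + (1.0 - prefs.gamma_official) * bid_winner.B,
        winner=base - (params.c + gamma_w) * bid_winner.B + params.R,
        loser=base,
    )


def official_choice(
    bid1: Bid,
    bid2: Bid,
    params: GameParams = DEFAULT_PARAMS,
    gamma_official: float = 0.0,
    tie_rule: str = "uniform",
) -> tuple[float, float]:
    """Probability that the official selects firm 1 resp. firm 2.

    If ``a >= 1 - gamma_official`` the official prefers quality and picks
    the highest-quality bid; otherwise the official maximises
    ``a*Q + (1-gamma)*B``.  Indifference is resolved by ``tie_rule``:
    ``"uniform"`` (default 50/50), ``"firm1"`` or ``"firm2"``.
    """
    if gamma_official < 0:
        raise ValueError("gamma_official must be nonnegative")
    bid1.validate(params)
    bid2.validate(params)
    if params.a >= 1.0 - gamma_official:
        s1, s2 = bid1.Q, bid2.Q
    else:
        s1 = params.a * bid1.Q + (1.0 - gamma_official) * bid1.B
        s2 = params.a * bid2.Q + (1.0 - gamma_official) * bid2.B
    if s1 > s2:
        return (1.0, 0.0)
    if s2 > s1:
        return (0.0, 1.0)
    if tie_rule == "uniform":
        return (0.5, 0.5)
    if tie_rule == "firm1":
        return (1.0, 0.0)
    if tie_rule == "firm2":
        return (0.0, 1.0)
    raise ValueError(f"unknown tie_rule {tie_rule!r}")


@dataclass(frozen=True)
class EquilibriumProfile:
    """A pure-strategy profile surviving the exhaustive deviation check.

    ``strict`` is True iff every unilateral deviation strictly lowers the
    deviating firm's expected payoff (expectation over the tie rule).
    """

    bid_firm1: Bid
    bid_firm2: Bid
    strict: bool


def _expected_payoff_matrices(
    bribes: np.ndarray,
    params: GameParams,
    gamma_official: float,
    firm_gammas: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """E1[i, j], E2[i, j]: expected firm payoffs when firm1 bids bribe i
    and firm2 bids bribe j, under uniform tie-breaking."""
    A, a, c, F, R = params.A, params.a, params.c, params.F, params.R
    Q = A - bribes
    if a >= 1.0 - gamma_official:
        score = Q
    else:
        score = a * Q + (1.0 - gamma_official) * bribes
    s1 = score[:, None]
    s2 = score[None, :]
    p1win = np.where(s1 > s2, 1.0, np.where(s1 < s2, 0.0, 0.5))

    win1 = F + a * Q + R - (c + firm_gammas[0]) * bribes  # firm1 wins with bribe b1
    win2 = F + a * Q + R - (c + firm_gammas[1]) * bribes
    lose = F + a * Q  # loser payoff depends on the *winner's* quality

    E1 = p1win * win1[:, None] + (1.0 - p1win) * lose[None, :]
    E2 = (1.0 - p1win) * win2[None, :] + p1win * lose[:, None]
    return E1, E2


def enumerate_equilibria(
    params: GameParams = DEFAULT_PARAMS,
    gamma_official: float = 0.0,
    firm_gammas: tuple[float, float] = (0.0, 0.0),
    grid_step: float = 1.0,
    tol: float = 1e-9,
) -> list[EquilibriumProfile]:
    """Exhaustive pure-strategy Nash enumeration on the bid grid.

    Bribes range over ``{0, grid_step, 2*grid_step, ..., A}`` (the default
    unit step reproduces the experiment's integer bids).  A profile is an
    equilibrium iff no unilateral deviation strictly raises the deviating
    firm's expected payoff; it is strict iff every deviation strictly
    lowers it.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    n = int(round(params.A / grid_step))
    if abs(n * grid_step - params.A) > tol:
        raise ValueError("grid_step must divide A")
    bribes = np.linspace(0.0, float(params.A), n + 1)
    E1, E2 = _expected_payoff_matrices(
        bribes, params, gamma_official, firm_gammas
    )
    best1 = E1.max(axis=0, keepdims=True)
    best2 = E2.max(axis=1, keepdims=True)
    is_eq = (E1 >= best1 - tol) & (E2 >= best2 - tol)
    # strict: the best response is attained uniquely
    n_best1 = (E1 >= best1 - tol).sum(axis=0, keepdims=True)
    n_best2 = (E2 >= best2 - tol).sum(axis=1, keepdims=True)
    strict = is_eq & (n_best1 == 1) & (n_best2 == 1)

    out: list[EquilibriumProfile] = []
    for i, j in np.argwhere(is_eq):
        out.append(
            EquilibriumProfile(
                bid_firm1=Bid(params.A - bribes[i], bribes[i]),
                bid_firm2=Bid(params.A - bribes[j], bribes[j]),
                strict=bool(strict[i, j]),
            )
        )
    return out


def equilibria_to_frame(profiles: list[EquilibriumProfile]) -> pd.DataFrame:
    """Tabulate an equilibrium set (columns: firm1_Q, firm1_B, firm2_Q,
    firm2_B, strict); write with ``DataFrame.to_csv(..., sep="\\t")``."""
    return pd.DataFrame(
        [
            {
                "firm1_Q": p.bid_firm1.Q,
                "firm1_B": p.bid_firm1.B,
                "firm2_Q": p.bid_firm2.Q,
                "firm2_B": p.bid_firm2.B,
                "strict": p.strict,
            }
            for p in profiles
        ]
    )


@dataclass(frozen=True)
class PsychEquilibriumPrediction:
    """Closed-form equilibrium bids under bribery aversion.

    ``branch`` is ``"quality"`` when ``a >= 1 - gamma_official`` (the
    official picks the highest quality, so firms bid (A, 0)) and
    ``"bribe"`` otherwise (firm i bids bribe R/(c + gamma_i), capped at A).
    ``bids`` holds the continuous prediction; ``bids_integer`` the nearest
    feasible integer bid (halves rounded up in the bribe component).
    """

    branch: str
    bids: tuple[Bid, Bid]
    bids_integer: tuple[Bid, Bid]


def psych_equilibrium_bids(
    params: GameParams = DEFAULT_PARAMS,
    prefs: AgentPreferences = AgentPreferences(),
) -> PsychEquilibriumPrediction:
    """Symmetric-information equilibrium bids of the psychological game."""
    if params.a >= 1.0 - prefs.gamma_official:
        bid = Bid(float(params.A), 0.0)
        return PsychEquilibriumPrediction("quality", (bid, bid), (bid, bid))
    bids: list[Bid] = []
    ints: list[Bid] = []
    for g in (prefs.gamma_firm1, prefs.gamma_firm2):
        denom = params.c + g
        if denom <= 0:
            raise UndefinedBidError(
                "equilibrium bribe R/(c+gamma) undefined for c + gamma = 0"
            )
        b = min(params.R / denom, float(params.A))
        bids.append(Bid(params.A - b, b))
        bi = min(math.floor(b + 0.5), params.A)
        ints.append(Bid(float(params.A - bi), float(bi)))
    return PsychEquilibriumPrediction("bribe", tuple(bids), tuple(ints))


def continuous_equilibrium_bribe(params: GameParams = DEFAULT_PARAMS) -> float:
    """Bribe component of the unique continuous-strategy Nash equilibrium
    under pure monetary payoffs (Bertrand-style: B = R / c)."""
    pred = psych_equilibrium_bids(params, AgentPreferences())
    return pred.bids[0].B


def apply_inspection(
    payoffs: PayoffVector,
    winner_bribed: bool,
    inspected: bool,
) -> PayoffVector:
    """Inspection/punishment transformation of realized payoffs.

    A revealed bribe zeroes the official's and winner's period earnings;
    an inspection that reveals no bribe zeroes the denouncing loser's
    earnings instead.  No inspection leaves payoffs unchanged.
    """
    if not inspected:
        return payoffs
    if winner_bribed:
        return PayoffVector(official=0.0, winner=0.0, loser=payoffs.loser)
    return PayoffVector(
        official=payoffs.official, winner=payoffs.winner, loser=0.0
    )
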