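"""Agent-based simulator for the bribery-auction sessions.

Fixed triplets (one official, two firms) play 15 Baseline (T0) periods
followed by 15 Inspection (T1) periods.  Firms pick integer bids by a
softmax (noisy best response) over expected utility, given (i) a
history-based belief about the probability that the official maximises
monetary reward, (ii) the empirical distribution of the opponent's past
bids, and (iii) in T1 the inspection hazard.  Officials choose
deterministically according to their drawn bribery aversion; losers in T1
inspect with a geometrically decaying probability.  Response times are
lognormal with an additive location shift whenever a decision goes
against the agent's myopic monetary optimum.

The behavioral rules are stylized (the study reports no behavioral
model); defaults are chosen to emulate the qualitative patterns of the
human sessions, not fitted to them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .game import (
    AgentPreferences,
    Bid,
    DEFAULT_PARAMS,
    GameParams,
    apply_inspection,
    monetary_payoffs,
    official_choice,
)

__all__ = [
    "SessionConfig",
    "PeriodRecord",
    "EventMarker",
    "simulate_session",
    "summarize_behavior",
]

_GAMMA_FAMILIES = ("exponential", "lognormal", "constant")


@dataclass(frozen=True)
class SessionConfig:
    """Knobs of the synthetic session.

    ``gamma_family``/``gamma_params`` specify the bribery-aversion
    distribution shared by all roles: ``("exponential", (scale,))``,
    ``("lognormal", (mu, sigma))`` or ``("constant", (value,))``.
    ``inspection_propensity_0`` is the losers' inspection probability in
    the first Inspection period and decays multiplicatively by
    ``inspection_decay`` each later period.  ``belief_prior`` are Beta
    pseudo-counts (monetary, pro-social) for the firms' belief that the
    official maximises monetary reward; the default (9, 1) encodes a
    strong initial expectation of a self-interested official, updated by
    every observed non-tie decision.  ``belief_recency`` discounts the
    opponent-bid belief geometrically with age (1.0 = plain empirical
    distribution), so firms track their rival's recent play.
    """

    n_triplets: int = 31
    n_periods_t0: int = 15
    n_periods_t1: int = 15
    gamma_family: str = "exponential"
    gamma_params: tuple[float, ...] = (0.35,)
    choice_temperature: float = 0.6
    belief_prior: tuple[float, float] = (9.0, 1.0)
    belief_recency: float = 0.7
    inspection_propensity_0: float = 0.42
    inspection_decay: float = 0.875
    rt_median_s: float = 2.0
    rt_sigma: float = 0.4
    rt_conflict_shift_s: float = 1.0
    screen_gap_s: tuple[float, float] = (0.5, 1.5)
    period_gap_s: tuple[float, float] = (4.0, 8.0)
    seed: int = 0
    params: GameParams = DEFAULT_PARAMS

    def __post_init__(self) -> None:
        if self.n_triplets < 0:
            raise ValueError("n_triplets must be >= 0")
        if not 0.0 <= self.inspection_propensity_0 <= 1.0:
            raise ValueError("inspection_propensity_0 must be in [0, 1]")
        if not 0.0 < self.inspection_decay <= 1.0:
            raise ValueError("inspection_decay must be in (0, 1]")
        if self.choice_temperature < 0:
            raise ValueError("choice_temperature must be >= 0")
        if self.gamma_family not in _GAMMA_FAMILIES:
            raise ValueError(
                f"gamma_family must be one of {_GAMMA_FAMILIES}"
            )

    @property
    def n_periods(self) -> int:
        return self.n_periods_t0 + self.n_periods_t1


@dataclass
class PeriodRecord:
    """One triplet-period of behavioral outcomes."""

    triplet: int
    period: int
    treatment: str  # "T0" | "T1"
    q1: int
    b1: int
    q2: int
    b2: int
    winner: int  # 1 | 2
    decision_class: str  # "bribe_max" | "quality_max" | "tie"
    inspected: bool
    bribe_revealed: bool
    payoff_official: float
    payoff_firm1: float
    payoff_firm2: float
    rt_firm1: float
    rt_firm2: float
    rt_official: float
    rt_inspection: float  # NaN when no inspection stage (T0)
    t_start: float


@dataclass
class EventMarker:
    """One on-screen event for one subject (times in s from session start)."""

    subject: str
    event_type: str  # decision_screen_on | decision_made | feedback_on | inspection_wait_on
    time_s: float
    condition: str
    period: int
    triplet: int
    event_id: str = ""


def _draw_gamma(cfg: SessionConfig, rng: np.random.Generator) -> float:
    if cfg.gamma_family == "exponential":
        return float(rng.exponential(cfg.gamma_params[0]))
    if cfg.gamma_family == "lognormal":
        mu, sigma = cfg.gamma_params
        return float(rng.lognormal(mu, sigma))
    return float(cfg.gamma_params[0])


def _firm_expected_utilities(
    bribes: np.ndarray,
    gamma_firm: float,
    p_money: float,
    opp_weights: np.ndarray,
    hazard: float,
    params: GameParams,
) -> np.ndarray:
    """Expected utility of each own bribe level, under the firm's beliefs.

    Win probability against an opponent bribe b_o: the monetary official
    (prob ``p_money``) picks the higher bribe, the pro-social official the
    higher quality (= lower bribe); ties split 50/50.  In T1 a winning
    bribe is confiscated with probability ``hazard``.
    """
    F, a, c, A, R = params.F, params.a, params.c, params.A, params.R
    b = bribes[:, None]
    bo = bribes[None, :]
    p_win = np.where(
        b > bo, p_money, np.where(b < bo, 1.0 - p_money, 0.5)
    )
    u_win = F + a * (A - bribes) - (c + gamma_firm) * bribes + R
    if hazard > 0:
        u_win = np.where(bribes > 0, (1.0 - hazard) * u_win, u_win)
    u_lose = F + a * (A - bribes)  # indexed by the opponent's bribe
    eu = p_win * u_win[:, None] + (1.0 - p_win) * u_lose[None, :]
    return eu @ opp_weights


def _softmax_choice(
    eu: np.ndarray, temperature: float, rng: np.random.Generator
) -> int:
    if temperature == 0.0:
        best = np.flatnonzero(eu >= eu.max() - 1e-12)
        return int(rng.choice(best))
    z = (eu - eu.max()) / temperature
    p = np.exp(z)
    p /= p.sum()
    return int(rng.choice(len(eu), p=p))


def _response_time(cfg: SessionConfig, conflict: bool, rng: np.random.Generator) -> float:
    rt = float(rng.lognormal(math.log(cfg.rt_median_s), cfg.rt_sigma))
    if conflict:
        rt += cfg.rt_conflict_shift_s
    return rt


def _uniform(rng: np.random.Generator, bounds: tuple[float, float]) -> float:
    return float(rng.uniform(*bounds))


def simulate_session(
    config: SessionConfig,
) -> tuple[list[PeriodRecord], list[EventMarker]]:
    """Simulate one session; reproducible bit-for-bit given ``config.seed``.

    Returns the per-triplet-period behavioral records and the per-subject
    event markers (strictly increasing timestamps per subject).  Agents
    are re-drawn at the treatment switch, mirroring the re-matching and
    new role assignment between Baseline and Inspection.
    """
    rng = np.random.default_rng(config.seed)
    params = config.params
    A = params.A
    bribe_grid = np.arange(A + 1, dtype=float)

    records: list[PeriodRecord] = []
    markers: list[EventMarker] = []
    event_counters: dict[str, int] = {}

    def emit(subject, etype, t, condition, period, triplet):
        k = event_counters.get(subject, 0)
        event_counters[subject] = k + 1
        markers.append(
            EventMarker(
                subject=subject,
                event_type=etype,
                time_s=t,
                condition=condition,
                period=period,
                triplet=triplet,
                event_id=f"{subject}-{k:05d}",
            )
        )

    for k in range(config.n_triplets):
        subj_official = f"official_{k:03d}"
        subj_firms = (f"firm_{k:03d}_1", f"firm_{k:03d}_2")
        t = _uniform(rng, config.period_gap_s)

        gammas = None
        history = None
        for period in range(1, config.n_periods + 1):
            in_t1 = period > config.n_periods_t0
            treatment = "T1" if in_t1 else "T0"
            if period == 1 or period == config.n_periods_t0 + 1:
                # fresh matching: new draws, beliefs reset
                gammas = AgentPreferences(
                    gamma_official=_draw_gamma(config, rng),
                    gamma_firm1=_draw_gamma(config, rng),
                    gamma_firm2=_draw_gamma(config, rng),
                )
                history = {
                    "bribe_max": 0,
                    "quality_max": 0,
                    "opp_bids": ([], []),  # bids observed *by* firm 1, 2
                }

            hazard = 0.0
            if in_t1:
                hazard = config.inspection_propensity_0 * (
                    config.inspection_decay
                    ** (period - config.n_periods_t0 - 1)
                )

            a0, b0 = config.belief_prior
            p_money = (history["bribe_max"] + a0) / (
                history["bribe_max"] + history["quality_max"] + a0 + b0
            )

            # --- bid stage -------------------------------------------------
            t_bid = t
            bids: list[int] = []
            rts: list[float] = []
            conflicts: list[bool] = []
            for i, firm in enumerate(subj_firms):
                seen = history["opp_bids"][i]
                if seen:
                    w = np.zeros(A + 1)
                    for age, b_seen in enumerate(reversed(seen)):
                        w[b_seen] += config.belief_recency**age
                else:
                    w = np.ones(A + 1)
                w /= w.sum()
                g_i = gammas.gamma_firm(i + 1)
                eu = _firm_expected_utilities(
                    bribe_grid, g_i, p_money, w, hazard, params
                )
                b = _softmax_choice(eu, config.choice_temperature, rng)
                # myopic monetary optimum: same beliefs, gamma = 0
                eu0 = _firm_expected_utilities(
                    bribe_grid, 0.0, p_money, w, hazard, params
                )
                b_star = int(np.argmax(eu0))
                conflict = (b > 0) != (b_star > 0)
                rt = _response_time(config, conflict, rng)
                bids.append(b)
                rts.append(rt)
                conflicts.append(conflict)
                emit(
                    firm,
                    "decision_screen_on",
                    t_bid,
                    f"{treatment}:bid_{'bribe' if b > 0 else 'no_bribe'}",
                    period,
                    k,
                )
                emit(
                    firm,
                    "decision_made",
                    t_bid + rt,
                    f"{treatment}:bid_{'bribe' if b > 0 else 'no_bribe'}",
                    period,
                    k,
                )

            bid1 = Bid.from_bribe(bids[0], params)
            bid2 = Bid.from_bribe(bids[1], params)

            # --- allocation stage ------------------------------------------
            t_alloc = t_bid + max(rts) + _uniform(rng, config.screen_gap_s)
            p1, p2 = official_choice(
                bid1, bid2, params, gammas.gamma_official
            )
            winner = 1 if rng.random() < p1 else 2
            if bids[0] == bids[1]:
                decision_class = "tie"
            else:
                chosen_b = bids[winner - 1]
                other_b = bids[2 - winner]
                decision_class = (
                    "bribe_max" if chosen_b > other_b else "quality_max"
                )
            # official's myopic monetary optimum (hazard-discounted in T1)
            v = [
                (1.0 - (hazard if b > 0 else 0.0))
                * (params.F + params.a * (A - b) + b)
                for b in bids
            ]
            if abs(v[0] - v[1]) < 1e-12:
                official_conflict = False
            else:
                official_conflict = (winner != (1 if v[0] > v[1] else 2))
            rt_off = _response_time(config, official_conflict, rng)
            cond_off = f"{treatment}:choice_{decision_class}"
            emit(subj_official, "decision_screen_on", t_alloc, cond_off, period, k)
            emit(subj_official, "decision_made", t_alloc + rt_off, cond_off, period, k)

            if decision_class != "tie":
                history[decision_class] += 1

            winner_bid = bid1 if winner == 1 else bid2
            winner_bribed = winner_bid.B > 0
            loser = 2 if winner == 1 else 1

            # --- inspection stage (T1 only) --------------------------------
            inspected = False
            rt_insp = float("nan")
            t_after = t_alloc + rt_off
            if in_t1:
                t_insp = t_after + _uniform(rng, config.screen_gap_s)
                inspected = bool(rng.random() < hazard)
                rt_insp = _response_time(config, inspected, rng)
                wait_cond = (
                    f"T1:wait_{'bribed' if winner_bribed else 'honest'}"
                )
                emit(
                    subj_firms[winner - 1],
                    "inspection_wait_on",
                    t_insp,
                    wait_cond,
                    period,
                    k,
                )
                insp_cond = f"T1:{'inspect' if inspected else 'no_inspect'}"
                emit(
                    subj_firms[loser - 1],
                    "decision_screen_on",
                    t_insp,
                    insp_cond,
                    period,
                    k,
                )
                emit(
                    subj_firms[loser - 1],
                    "decision_made",
                    t_insp + rt_insp,
                    insp_cond,
                    period,
                    k,
                )
                t_after = t_insp + rt_insp

            bribe_revealed = inspected and winner_bribed
            payoffs = monetary_payoffs(winner_bid, params, winner_role=winner)
            payoffs = apply_inspection(payoffs, winner_bribed, inspected)
            pf1, pf2 = payoffs.by_firm(winner)

            # --- feedback --------------------------------------------------
            t_fb = t_after + _uniform(rng, config.screen_gap_s)
            if bribe_revealed:
                fb_cond = f"{treatment}:fb_revealed"
            elif inspected:
                fb_cond = f"{treatment}:fb_accused"
            else:
                fb_cond = (
                    f"{treatment}:fb_{'bribe' if winner_bribed else 'no_bribe'}"
                )
            for subj in (subj_official, *subj_firms):
                emit(subj, "feedback_on", t_fb, fb_cond, period, k)

            records.append(
                PeriodRecord(
                    triplet=k,
                    period=period,
                    treatment=treatment,
                    q1=int(bid1.Q),
                    b1=int(bid1.B),
                    q2=int(bid2.Q),
                    b2=int(bid2.B),
                    winner=winner,
                    decision_class=decision_class,
                    inspected=inspected,
                    bribe_revealed=bribe_revealed,
                    payoff_official=payoffs.official,
                    payoff_firm1=pf1,
                    payoff_firm2=pf2,
                    rt_firm1=rts[0],
                    rt_firm2=rts[1],
                    rt_official=rt_off,
                    rt_inspection=rt_insp,
                    t_start=t,
                )
            )

            # firms observe each other's bids from the feedback screen
            history["opp_bids"][0].append(bids[1])
            history["opp_bids"][1].append(bids[0])

            t = t_fb + _uniform(rng, config.period_gap_s)

    return records, markers


def records_to_frame(records: list[PeriodRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def markers_to_frame(markers: list[EventMarker]) -> pd.DataFrame:
    return pd.DataFrame([vars(m) for m in markers])


def summarize_behavior(records: list[PeriodRecord]) -> dict:
    """Per-treatment behavioral summary.

    Returns a dict with:

    - ``mean_bribe``: mean over both firms' bribe bids, per treatment;
    - ``bribe_histogram``: counts of bribe levels per treatment;
    - ``official_decisions``: per treatment, shares of non-tie decisions
      classed monetary-maximizing vs pro-social, plus the tie count;
    - ``inspection_by_period``: per T1 period, share of loser-periods
      with an inspection;
    - ``inspection_share``: overall share of possible instances inspected;
    - ``inspecting_losers_bribed_share``: among inspections, the share in
      which the inspecting loser had itself offered a bribe.
    """
    if not records:
        raise ValueError("empty record list")
    df = records_to_frame(records)
    bribes = pd.concat(
        [
            df[["treatment", "b1"]].rename(columns={"b1": "bribe"}),
            df[["treatment", "b2"]].rename(columns={"b2": "bribe"}),
        ]
    )
    mean_bribe = bribes.groupby("treatment")["bribe"].mean().to_dict()
    hist = (
        bribes.groupby(["treatment", "bribe"]).size().unstack(fill_value=0)
    )

    decisions = {}
    for trt, sub in df.groupby("treatment"):
        nontie = sub[sub["decision_class"] != "tie"]
        n = len(nontie)
        decisions[trt] = {
            "n_non_tie": n,
            "n_tie": int((sub["decision_class"] == "tie").sum()),
            "share_bribe_max": (
                float((nontie["decision_class"] == "bribe_max").mean())
                if n
                else float("nan")
            ),
            "share_quality_max": (
                float((nontie["decision_class"] == "quality_max").mean())
                if n
                else float("nan")
            ),
        }

    t1 = df[df["treatment"] == "T1"]
    if len(t1):
        insp_by_period = t1.groupby("period")["inspected"].mean()
        inspection_share = float(t1["inspected"].mean())
        insp = t1[t1["inspected"]]
        if len(insp):
            loser_bribed = np.where(
                insp["winner"] == 1, insp["b2"] > 0, insp["b1"] > 0
            )
            bribed_share = float(np.mean(loser_bribed))
        else:
            bribed_share = float("nan")
    else:
        insp_by_period = pd.Series(dtype=float)
        inspection_share = float("nan")
        bribed_share = float("nan")

    return {
        "mean_bribe": mean_bribe,
        "bribe_histogram": hist,
        "official_decisions": decisions,
        "inspection_by_period": insp_by_period,
        "inspection_share": inspection_share,
        "inspecting_losers_bribed_share": bribed_share,
    }
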