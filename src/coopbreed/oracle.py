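"""Stochastic individual-lifetime simulator — the brute-force fitness oracle.

Simulates the exact event structure the closed forms integrate: every
reproductive cycle a mother credits one offspring (which survives to
breeding adulthood with the branch's survival probability), then survives
the cycle — length ``T`` years for independent caregiving, ``T - delta``
when the lactational load is shared — or dies.  Cooperative Mothers run
the Search/Paired state machine (partner found among encountered CMs, pair
dissolved on partner death); encounters are drawn from the like-with-like
meeting distribution; Cooperative-vs-Opportunistic encounters resolve by a
fair coin into the sucker's payoff or a mutual independent cycle.

Paternal care follows the model's expected-care convention: by default a
lifetime is simulated at the deterministic expected paternal-care level of
the strategy (the same single care value the closed forms use), so the
Monte Carlo mean estimates exactly the quantity the closed forms compute.
``care="draw"`` instead draws a mate (Coalition/Non-coalition, partnered
or not) once per lifetime for sensitivity analyses.

Two entry points: :func:`simulate_lifetime` produces one event-level
:class:`LifetimeRecord` with per-year survival draws (useful for replay
checks); :func:`estimate_fitness` runs a vectorized population of
lifetimes with one compound survival draw ``Bernoulli(sf**L)`` per cycle —
distributionally identical under the constant annual hazard — and returns
the Monte Carlo mean and standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .female import (coalition_partner_prob, expected_paternal_care,
                     meeting_distribution, offspring_survival,
                     pair_coalition_prob)
from .params import (CM, IM, OM, ModelParams, ParamError, PopulationState,
                     as_generator, validate_params)

__all__ = [
    "LifetimeRecord",
    "FitnessEstimate",
    "simulate_lifetime",
    "estimate_fitness",
    "replay_total",
]

EVENT_TYPES = ("search_met_CM", "search_met_OM", "search_met_IM",
               "sucker_period", "im_cycle", "coop_cycle", "pair_dissolved",
               "death")
#: events at which an offspring is produced
REPRODUCTIVE_EVENTS = ("im_cycle", "coop_cycle")


@dataclass(frozen=True)
class LifetimeRecord:
    """One simulated female reproductive history.

    ``events`` is a time-ordered list of ``(type, year)`` pairs;
    ``offspring_outcomes`` holds one survived-to-breeding indicator per
    birth, aligned with the reproductive events (``im_cycle`` and
    ``coop_cycle``) in order.
    """

    strategy: str
    events: tuple
    offspring_outcomes: tuple
    total: int
    care: float


@dataclass(frozen=True)
class FitnessEstimate:
    mean: float
    se: float
    n: int


def replay_total(record: LifetimeRecord) -> int:
    """Recompute the surviving-offspring count by replaying the event log.

    Also validates the record against the rule table: events time-ordered,
    nothing after death, one birth per reproductive event.
    """
    last_year = -np.inf
    births = 0
    for idx, (etype, year) in enumerate(record.events):
        if etype not in EVENT_TYPES:
            raise ValueError(f"unknown event type {etype!r}")
        if year < last_year:
            raise ValueError("events out of time order")
        last_year = year
        if etype == "death" and idx != len(record.events) - 1:
            raise ValueError("events recorded after death")
        if etype in REPRODUCTIVE_EVENTS:
            births += 1
    if births != len(record.offspring_outcomes):
        raise ValueError("birth count does not match offspring outcomes")
    return int(sum(record.offspring_outcomes))


def _resolve_care(p: ModelParams, state: PopulationState, strategy: str,
                  care, rng: np.random.Generator) -> float:
    if care is None:
        return expected_paternal_care(p, state, strategy)
    if care == "draw":
        # one pair-bond per lifetime: mate type, then his coalition status
        if rng.random() < pair_coalition_prob(p, state, strategy):
            if rng.random() < coalition_partner_prob(p, state.q_coal):
                return p.b_coal
            return p.b_noncoal
        return p.b_noncoal
    return float(care)


def _survive_years(rng: np.random.Generator, sf: float, length: float) -> bool:
    """Year-by-year Bernoulli survival over a possibly fractional cycle."""
    whole = int(length)
    for _ in range(whole):
        if rng.random() >= sf:
            return False
    frac = length - whole
    if frac > 0.0 and rng.random() >= sf ** frac:
        return False
    return True


def simulate_lifetime(p: ModelParams, state: PopulationState, strategy: str,
                      rng, care=None) -> LifetimeRecord:
    """Simulate one reproductive lifetime at the event level."""
    validate_params(p)
    rng = as_generator(rng)
    care_val = _resolve_care(p, state, strategy, care, rng)
    md = meeting_distribution(p, state, strategy)
    s_im = offspring_survival(p, 0, care_val)
    s_allo = offspring_survival(p, 1, care_val)
    t_full = p.T_ibi
    t_short = p.T_ibi - p.delta_ibi

    events: list = []
    outcomes: list = []
    year = 0.0
    paired = False

    def do_cycle(etype: str, surv: float | None, length: float) -> bool:
        """Record a cycle; credit an offspring unless ``surv`` is None."""
        nonlocal year
        events.append((etype, year))
        if surv is not None:
            outcomes.append(1 if rng.random() < surv else 0)
        alive = _survive_years(rng, p.sf, length)
        year += length
        if not alive:
            events.append(("death", year))
        return alive

    alive = True
    while alive:
        if strategy == IM:
            alive = do_cycle("im_cycle", s_im, t_full)
        elif strategy == OM:
            u = rng.random()
            if u < md.p_meet_cm:
                events.append(("search_met_CM", year))
                if rng.random() < 0.5:  # OM reproduces first, pockets the help
                    alive = do_cycle("coop_cycle", s_allo, t_short)
                else:  # CM reproduces first, OM refuses; both act as IMs
                    alive = do_cycle("im_cycle", s_im, t_full)
            else:
                alive = do_cycle("im_cycle", s_im, t_full)
        elif strategy == CM:
            if not paired:
                u = rng.random()
                if u < md.p_meet_cm:
                    events.append(("search_met_CM", year))
                    paired = True
                elif u < md.p_meet_cm + md.p_meet_om:
                    events.append(("search_met_OM", year))
                    if rng.random() < 0.5:  # sucker: allomother, no own birth
                        alive = do_cycle("sucker_period", None, t_short)
                    else:
                        alive = do_cycle("im_cycle", s_im, t_full)
                    continue
                else:
                    events.append(("search_met_IM", year))
                    alive = do_cycle("im_cycle", s_im, t_full)
                    continue
            # paired cooperative cycle; partner survives independently
            alive = do_cycle("coop_cycle", s_allo, t_short)
            if alive and not _survive_years(rng, p.sf, t_short):
                paired = False
                events.append(("pair_dissolved", year))
        else:
            raise ParamError(f"unknown female strategy {strategy!r}")

    return LifetimeRecord(strategy=strategy, events=tuple(events),
                          offspring_outcomes=tuple(outcomes),
                          total=int(sum(outcomes)), care=care_val)


_MAX_CYCLES = 200_000


def _simulate_counts(p: ModelParams, state: PopulationState, strategy: str,
                     n: int, rng: np.random.Generator, care) -> np.ndarray:
    """Vectorized lifetimes -> surviving-offspring counts (length ``n``)."""
    if care == "draw":
        u_mate = rng.random(n)
        u_part = rng.random(n)
        coal = u_mate < pair_coalition_prob(p, state, strategy)
        partnered = u_part < coalition_partner_prob(p, state.q_coal)
        care_vec = np.where(coal & partnered, p.b_coal, p.b_noncoal)
    else:
        care_scalar = (expected_paternal_care(p, state, strategy)
                       if care is None else float(care))
        care_vec = np.full(n, care_scalar)

    s_im = np.clip(p.s0 + care_vec, 0.0, 1.0)
    s_allo = np.clip(p.s0 + p.b_allo + care_vec, 0.0, 1.0)
    d1 = p.sf ** p.T_ibi
    d2 = p.sf ** (p.T_ibi - p.delta_ibi)
    md = meeting_distribution(p, state, strategy)

    alive = np.ones(n, dtype=bool)
    offspring = np.zeros(n, dtype=np.int64)

    if strategy == IM:
        for _ in range(_MAX_CYCLES):
            if not alive.any():
                return offspring
            offspring += alive & (rng.random(n) < s_im)
            alive &= rng.random(n) < d1
    elif strategy == OM:
        for _ in range(_MAX_CYCLES):
            if not alive.any():
                return offspring
            exploit = (rng.random(n) < md.p_meet_cm) & (rng.random(n) < 0.5)
            s_b = np.where(exploit, s_allo, s_im)
            d_b = np.where(exploit, d2, d1)
            offspring += alive & (rng.random(n) < s_b)
            alive &= rng.random(n) < d_b
    elif strategy == CM:
        paired = np.zeros(n, dtype=bool)
        p_cc, p_co = md.p_meet_cm, md.p_meet_om
        for _ in range(_MAX_CYCLES):
            if not alive.any():
                return offspring
            u = rng.random(n)
            searching = alive & ~paired
            met_cm = searching & (u < p_cc)
            met_om = searching & (u >= p_cc) & (u < p_cc + p_co)
            met_im = searching & (u >= p_cc + p_co)
            sucker = met_om & (rng.random(n) < 0.5)
            im_cycle = (met_om & ~sucker) | met_im
            paired |= met_cm
            in_coop = alive & paired  # includes the cycle the pair forms
            births = (in_coop & (rng.random(n) < s_allo)) | \
                     (im_cycle & (rng.random(n) < s_im))
            offspring += births
            short = in_coop | sucker
            d_b = np.where(short, d2, d1)
            alive &= rng.random(n) < d_b
            partner_died = in_coop & (rng.random(n) >= d2)
            paired &= ~partner_died
    else:
        raise ParamError(f"unknown female strategy {strategy!r}")
    raise RuntimeError("lifetime simulation exceeded the cycle cap")


def estimate_fitness(p: ModelParams, state: PopulationState, strategy: str,
                     n_lifetimes: int, seed, care=None) -> FitnessEstimate:
    """Monte Carlo mean ± SE of lifetime surviving offspring.

    ``care=None`` uses the strategy's expected paternal care (the closed
    forms' convention); ``care="draw"`` draws a mate per lifetime; a float
    fixes the care level directly.
    """
    if n_lifetimes < 2:
        raise ParamError("n_lifetimes must be >= 2")
    validate_params(p)
    rng = as_generator(seed)
    counts = _simulate_counts(p, state, strategy, n_lifetimes, rng, care)
    mean = float(counts.mean())
    se = float(counts.std(ddof=1) / np.sqrt(n_lifetimes))
    return FitnessEstimate(mean=mean, se=se, n=n_lifetimes)
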