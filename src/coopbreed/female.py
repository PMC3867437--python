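"""Closed-form expected lifetime fitness of the three female strategies.

Fitness is the expected number of offspring surviving to breeding adulthood
over a mother's lifetime.  Time is discounted geometrically by survival: a
mother credits one offspring at the start of each reproductive cycle and
reaches the next cycle only by surviving its length, so a cycle of length
``L`` years carries a continuation factor ``sf**L``.  Two cycle lengths
occur: the full interbirth interval ``T`` (independent caregiving,
continuation ``d1 = sf**T``) and the shortened interval ``T - delta``
enjoyed by mothers who share the lactational load (continuation
``d2 = sf**(T - delta)``).

* An Independent Mother (IM) repeats the plain cycle forever:
  ``w_im = S / (1 - d1)``.
* An Opportunistic Mother (OM) accepts alloparental care when she meets a
  Cooperative Mother (half of such encounters) but never reciprocates; her
  fitness solves a one-state renewal equation over encounter outcomes.
* A Cooperative Mother (CM) searches for a reciprocating partner, paying a
  sucker's cost (an unreciprocated allomothering period) on half of her
  encounters with OMs, and once paired cooperates for as long as both
  partners survive; her fitness solves a two-state (Search/Paired) linear
  system.

Encounter probabilities mix like-with-like kin assortment with population
frequencies: a focal female meets her own strategy with probability
``r + (1 - r) * own_freq`` and a different strategy ``sigma`` with
probability ``(1 - r) * freq(sigma)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .params import (CM, IM, OM, FEMALE_STRATEGIES, ClampWarning, ModelParams,
                     ParamError, PopulationState)

__all__ = [
    "FemaleMeetingDistribution",
    "FemaleFitnessProfile",
    "meeting_distribution",
    "offspring_survival",
    "coalition_partner_prob",
    "pair_coalition_prob",
    "expected_paternal_care",
    "fitness_im",
    "fitness_om",
    "fitness_cm",
    "female_profile",
]


@dataclass(frozen=True)
class FemaleMeetingDistribution:
    """Probabilities that a focal female's next female interactant plays CM/OM/IM."""

    p_meet_cm: float
    p_meet_om: float
    p_meet_im: float

    def as_dict(self) -> dict:
        return {CM: self.p_meet_cm, OM: self.p_meet_om, IM: self.p_meet_im}


@dataclass(frozen=True)
class FemaleFitnessProfile:
    """Expected lifetime surviving-offspring counts per female strategy.

    ``w_mean`` is the frequency-weighted population mean female fitness,
    the quantity entering the male extra-pair-mating payoff.
    """

    w_im: float
    w_om: float
    w_cm: float
    w_mean: float

    def as_dict(self) -> dict:
        return {"w_im": self.w_im, "w_om": self.w_om,
                "w_cm": self.w_cm, "w_mean": self.w_mean}


def meeting_distribution(p: ModelParams, state: PopulationState,
                         self_strategy: str) -> FemaleMeetingDistribution:
    """Like-with-like encounter distribution for a focal female.

    Own strategy is met with probability ``r + (1 - r) * own_freq``; any
    other strategy with ``(1 - r) * freq``.  ``r = 0`` reduces to random
    mixing, ``r = 1`` to full segregation.
    """
    if self_strategy not in FEMALE_STRATEGIES:
        raise ParamError(f"unknown female strategy {self_strategy!r}")
    r = p.r_kin
    freqs = state.female_frequencies()
    probs = {s: (1.0 - r) * freqs[s] for s in FEMALE_STRATEGIES}
    probs[self_strategy] += r
    return FemaleMeetingDistribution(p_meet_cm=probs[CM], p_meet_om=probs[OM],
                                     p_meet_im=probs[IM])


def offspring_survival(p: ModelParams, allo: int, care: float) -> float:
    """Offspring survival to breeding adulthood, clamped to [0, 1].

    ``s0`` plus the alloparental effect (if the offspring receives
    alloparental care) plus the paternal-care increment.
    """
    if care < 0:
        raise ParamError(f"care must be >= 0, got {care!r}")
    s = p.s0 + p.b_allo * (1 if allo else 0) + care
    return min(1.0, max(0.0, s))


def coalition_partner_prob(p: ModelParams, q_coal: float) -> float:
    """Probability a Coalition Male has found a coalition partner.

    Like-with-like male assortment: ``r + (1 - r) * q``.
    """
    return p.r_kin + (1.0 - p.r_kin) * q_coal


def pair_coalition_prob(p: ModelParams, state: PopulationState,
                        female_strategy: str) -> float:
    """Probability that a female of the given strategy pairs with a Coalition Male.

    Cooperative Mothers pair with Coalition Males with probability
    ``a + (1 - a) * q``; OM and IM females share the residual Coalition-Male
    mass, ``(q - x * P_cm) / (1 - x)``, clamped to [0, 1] so the pairing
    table remains a proper distribution in extreme (x, a) corners.
    """
    q = state.q_coal
    p_cm = p.a_assort + (1.0 - p.a_assort) * q
    if female_strategy == CM:
        return p_cm
    x = state.x_cm
    if x >= 1.0:
        return q  # degenerate: no OM/IM females exist
    resid = (q - x * p_cm) / (1.0 - x)
    if resid < -1e-12 or resid > 1.0 + 1e-12:
        warnings.warn(
            f"residual Coalition-Male pairing probability {resid:.6g} clamped "
            f"to [0, 1] (x_cm={x:.3g}, q_coal={q:.3g}, a_assort={p.a_assort:.3g})",
            ClampWarning, stacklevel=2)
    return min(1.0, max(0.0, resid))


def expected_paternal_care(p: ModelParams, state: PopulationState,
                           female_strategy: str) -> float:
    """Expected paternal-care survival increment for a female of a strategy.

    A Coalition-Male mate delivers the coalition care level ``b_coal`` only
    when he actually has a coalition partner (probability
    ``r + (1 - r) * q``); otherwise he cares like a Non-coalition Male.
    """
    pc = pair_coalition_prob(p, state, female_strategy)
    pi_m = coalition_partner_prob(p, state.q_coal)
    care_coal_mate = pi_m * p.b_coal + (1.0 - pi_m) * p.b_noncoal
    return pc * care_coal_mate + (1.0 - pc) * p.b_noncoal


def _discounts(p: ModelParams) -> tuple[float, float]:
    if p.sf >= 1.0:
        raise ParamError("sf = 1 gives a non-finite reproductive horizon")
    d1 = p.sf ** p.T_ibi
    d2 = p.sf ** (p.T_ibi - p.delta_ibi)
    return d1, d2


def fitness_im(p: ModelParams, care: float) -> float:
    """Independent Mother: geometric series of plain cycles, ``S / (1 - d1)``."""
    d1, _ = _discounts(p)
    return offspring_survival(p, 0, care) / (1.0 - d1)


def fitness_om(p: ModelParams, state: PopulationState, care: float) -> float:
    """Opportunistic Mother: renewal over encounter outcomes.

    Meeting a CM (probability ``(1 - r) x``): half the time the OM
    reproduces first and pockets the alloparental benefit (shortened cycle,
    allo survival bonus); the other half the CM opts to reproduce first,
    the OM refuses to allomother and both revert to independent cycles.
    Meeting an OM or IM: a plain independent cycle.
    """
    d1, d2 = _discounts(p)
    md = meeting_distribution(p, state, OM)
    s_allo = offspring_survival(p, 1, care)
    s_im = offspring_survival(p, 0, care)
    p_other = md.p_meet_om + md.p_meet_im
    num = md.p_meet_cm * 0.5 * (s_allo + s_im) + p_other * s_im
    den = 1.0 - (md.p_meet_cm * 0.5 * (d1 + d2) + p_other * d1)
    if den <= 0.0:
        raise ParamError("renewal denominator <= 0 (requires sf < 1)")
    return num / den


def fitness_cm(p: ModelParams, state: PopulationState, care: float) -> float:
    """Cooperative Mother: two-state (Search, Paired) linear system.

    Searching, she meets a CM (enter the cooperative pair, which pays off
    immediately), an OM (fair coin between the sucker's payoff — an
    unreciprocated allomothering period with no own offspring — and a
    plain independent cycle), or an IM (plain cycle).  Paired, each
    cooperative cycle pays the allo-boosted offspring and continues while
    both partners survive the shortened cycle (independently, ``d2`` each);
    if her partner dies and she survives, she returns to searching.
    Returns the value of the Search state.
    """
    d1, d2 = _discounts(p)
    md = meeting_distribution(p, state, CM)
    p_cc, p_co, p_ci = md.p_meet_cm, md.p_meet_om, md.p_meet_im
    s_coop = offspring_survival(p, 1, care)
    s_im = offspring_survival(p, 0, care)
    # V_P = s_coop + d2^2 V_P + d2 (1 - d2) V_S  =>  eliminate V_P
    pair_denom = 1.0 - d2 * d2
    a = (p_cc * d2 * (1.0 - d2) / pair_denom
         + p_co * 0.5 * (d1 + d2)
         + p_ci * d1)
    b = p_cc * s_coop / pair_denom + (0.5 * p_co + p_ci) * s_im
    if a >= 1.0:
        raise ParamError("singular Search/Paired system (requires sf < 1)")
    return b / (1.0 - a)


def female_profile(p: ModelParams, state: PopulationState) -> FemaleFitnessProfile:
    """All three female fitnesses, each at its strategy's expected paternal care,
    plus the frequency-weighted population mean."""
    w_im = fitness_im(p, expected_paternal_care(p, state, IM))
    w_om = fitness_om(p, state, expected_paternal_care(p, state, OM))
    w_cm = fitness_cm(p, state, expected_paternal_care(p, state, CM))
    w_mean = state.x_cm * w_cm + state.y_om * w_om + state.z_im * w_im
    return FemaleFitnessProfile(w_im=w_im, w_om=w_om, w_cm=w_cm, w_mean=w_mean)
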