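"""Fitness of Coalition and Non-coalition Males.

A male's expected lifetime sired surviving offspring has two parts:

* within-pair siring — the fitness of his paired female (evaluated at the
  care level he actually provides) weighted by population paternity
  certainty ``Pi``, the probability that provisioning reaches his own
  biological offspring;
* an extra-pair gain ``e * w_mean`` — extra-pair maters have equal access
  to all females, so the lifetime extra-pair extent multiplies the mean
  female fitness.

Paternity certainty is population-level, eroded by whatever extra-pair
activity the male population sustains:
``Pi = 1 - (q * e_coal + (1 - q) * e_noncoal)``, monotone increasing in the
Coalition-Male frequency ``q`` because coalition partners monitor each
other (``e_coal <= e_noncoal``).

Coalition Males find a coalition partner with probability
``r + (1 - r) * q``; without a partner there is no economy of scale and no
mutual monitoring, so an unpartnered Coalition Male provides Non-coalition
care and engages in Non-coalition extra-pair mating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .female import (coalition_partner_prob, female_profile, fitness_cm,
                     fitness_im, fitness_om)
from .params import (FEMALE_STRATEGIES, ClampWarning, ModelParams,
                     PopulationState)

__all__ = [
    "PairingTable",
    "MaleFitnessProfile",
    "paternity_certainty",
    "pairing_table",
    "fitness_coalition_male",
    "fitness_noncoalition_male",
    "male_advantage",
    "male_profile",
]

COAL, NONCOAL = "Coal", "Non"


@dataclass(frozen=True)
class PairingTable:
    """Joint distribution of (female strategy, male type) pairs.

    ``joint`` is a 3x2 array, rows ordered (CM, OM, IM), columns
    (Coalition, Non-coalition).  Row sums equal the female strategy
    frequencies and column sums equal ``(q, 1 - q)``; in extreme
    (x_cm, a_assort) corners the Coalition demand from Cooperative Mothers
    can exceed the Coalition supply, in which case the CM entry is clamped
    (with a warning) and the residual redistributed, keeping marginals
    exact.
    """

    joint: np.ndarray
    clamped: bool = False

    def row(self, strategy: str) -> np.ndarray:
        return self.joint[FEMALE_STRATEGIES.index(strategy)]

    def column(self, male_type: str) -> np.ndarray:
        return self.joint[:, 0 if male_type == COAL else 1]

    def conditional_female(self, male_type: str,
                           fallback: np.ndarray | None = None) -> np.ndarray:
        """P(female strategy | male type); ``fallback`` when the column has
        no mass (that male type is absent from the population)."""
        col = self.column(male_type)
        mass = col.sum()
        if mass <= 1e-15:
            if fallback is None:
                raise ZeroDivisionError(
                    f"no population mass on male type {male_type!r}")
            return fallback
        return col / mass


@dataclass(frozen=True)
class MaleFitnessProfile:
    """Expected lifetime sired surviving offspring for both male types."""

    w_coal: float
    w_noncoal: float
    advantage: float
    pi_paternity: float

    def as_dict(self) -> dict:
        return {"w_coal": self.w_coal, "w_noncoal": self.w_noncoal,
                "advantage": self.advantage, "pi_paternity": self.pi_paternity}


def paternity_certainty(p: ModelParams, q_coal: float) -> float:
    """``Pi = 1 - (q e_coal + (1 - q) e_noncoal)``; increasing in ``q``."""
    return 1.0 - (q_coal * p.e_coal + (1.0 - q_coal) * p.e_noncoal)


def pairing_table(p: ModelParams, state: PopulationState) -> PairingTable:
    """Joint (female strategy, male type) pairing distribution.

    Cooperative Mothers claim Coalition Males with probability
    ``a + (1 - a) q``; OM and IM females split the residual Coalition-Male
    mass in proportion to their frequencies.
    """
    x, y, z, q = state.x_cm, state.y_om, state.z_im, state.q_coal
    demand_cm = x * (p.a_assort + (1.0 - p.a_assort) * q)
    clamped = False
    if demand_cm > q:
        warnings.warn(
            f"Cooperative-Mother demand for Coalition Males ({demand_cm:.6g}) "
            f"exceeds supply q={q:.6g}; clamped", ClampWarning, stacklevel=2)
        demand_cm = q
        clamped = True
    resid = q - demand_cm
    rest = y + z
    coal = np.array([
        demand_cm,
        y / rest * resid if rest > 0 else 0.0,
        z / rest * resid if rest > 0 else 0.0,
    ])
    freqs = np.array([x, y, z])
    non = freqs - coal
    # guard tiny negative round-off
    non = np.clip(non, 0.0, None)
    return PairingTable(joint=np.column_stack([coal, non]), clamped=clamped)


def _female_fitness_by_strategy(p: ModelParams, state: PopulationState,
                                care: float) -> np.ndarray:
    """(w_cm, w_om, w_im) with every strategy evaluated at one care level."""
    return np.array([
        fitness_cm(p, state, care),
        fitness_om(p, state, care),
        fitness_im(p, care),
    ])


def male_profile(p: ModelParams, state: PopulationState) -> MaleFitnessProfile:
    """Fitness of both male types, their difference, and paternity certainty.

    The expectation over the paired female's strategy uses the pairing
    table's conditional columns; her fitness is re-evaluated at the care
    level this male actually provides.  For an absent male type (q = 0 or
    q = 1) the conditional falls back to the population female frequencies,
    the natural rare-mutant limit under random pairing.
    """
    q = state.q_coal
    tbl = pairing_table(p, state)
    freqs = np.array([state.x_cm, state.y_om, state.z_im])
    cond_coal = tbl.conditional_female(COAL, fallback=freqs)
    cond_non = tbl.conditional_female(NONCOAL, fallback=freqs)

    pi = paternity_certainty(p, q)
    w_mean = female_profile(p, state).w_mean
    w_at_bcoal = _female_fitness_by_strategy(p, state, p.b_coal)
    w_at_bnon = _female_fitness_by_strategy(p, state, p.b_noncoal)

    pi_m = coalition_partner_prob(p, q)
    partnered = pi * float(cond_coal @ w_at_bcoal) + p.e_coal * w_mean
    unpartnered = pi * float(cond_coal @ w_at_bnon) + p.e_noncoal * w_mean
    w_coal = pi_m * partnered + (1.0 - pi_m) * unpartnered
    w_noncoal = pi * float(cond_non @ w_at_bnon) + p.e_noncoal * w_mean
    return MaleFitnessProfile(w_coal=w_coal, w_noncoal=w_noncoal,
                              advantage=w_coal - w_noncoal, pi_paternity=pi)


def fitness_coalition_male(p: ModelParams, state: PopulationState) -> float:
    """Expected lifetime sired surviving offspring of a Coalition Male."""
    return male_profile(p, state).w_coal


def fitness_noncoalition_male(p: ModelParams, state: PopulationState) -> float:
    """Expected lifetime sired surviving offspring of a Non-coalition Male."""
    return male_profile(p, state).w_noncoal


def male_advantage(p: ModelParams, state: PopulationState) -> float:
    """Signed Coalition-minus-Non-coalition fitness difference."""
    return male_profile(p, state).advantage
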