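"""Parameter space, constraints, and uniform Monte Carlo sampling.

The model lives in an 11-dimensional parameter space: two survival
probabilities (offspring-to-adulthood baseline ``s0`` and annual maternal
survival ``sf``), the life-history pair (interbirth interval ``T_ibi`` and
its allomothering-induced shortening ``delta_ibi``), the alloparental
survival effect ``b_allo``, the male side (extra-pair mating extents
``e_noncoal`` >= ``e_coal`` and paternal-care increments
``b_noncoal`` <= ``b_coal``), and the two assortment strengths
(within-sex kin-selection parameter ``r_kin`` and the between-sex
cooperative assortment ``a_assort``).

Parameter-uncertainty analyses draw each field independently and uniformly
from a hypothesized range; the two ordering constraints are enforced by
rejection (the whole vector is redrawn), which keeps marginals uniform on
the accepted region.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CM",
    "OM",
    "IM",
    "FEMALE_STRATEGIES",
    "ParamError",
    "ClampWarning",
    "ModelParams",
    "ParamRanges",
    "PopulationState",
    "validate_params",
    "sample_params",
    "uniform_simplex_state",
    "edge_state",
    "params_to_dataframe",
    "params_from_dataframe",
    "as_generator",
]

#: Female strategy labels: Cooperative, Opportunistic and Independent Mothers.
CM, OM, IM = "CM", "OM", "IM"
FEMALE_STRATEGIES = (CM, OM, IM)


class ParamError(ValueError):
    """A model-parameter invariant was violated."""


class ClampWarning(UserWarning):
    """A pairing probability was clamped to keep a proper distribution."""


@dataclass(frozen=True)
class ModelParams:
    """One point of the model's parameter space.

    Defaults are the midpoints of the hypothesized ranges (assortment off).

    Attributes
    ----------
    s0 : float
        Baseline probability that an offspring survives to breeding
        adulthood, absent alloparental and paternal care.
    sf : float
        Annual survival probability of a mother (must be < 1 so lifetime
        fitness is finite).
    b_allo : float
        Marginal change in offspring survival-to-adulthood caused by
        alloparental care; may be negative (net cost).
    T_ibi : float
        Interbirth interval, in years, of an independently caring mother.
    delta_ibi : float
        Decrease of the interbirth interval (years) for mothers who share
        the lactational load; 0 <= delta_ibi < T_ibi.
    e_noncoal, e_coal : float
        Extent of lifetime extra-pair matings for Non-coalition and
        Coalition Males; coalition partners monitor one another, hence
        e_coal <= e_noncoal.
    b_noncoal, b_coal : float
        Paternal-care increment to offspring survival for Non-coalition and
        (partnered) Coalition Males; coalition foraging has an economy of
        scale, hence b_noncoal <= b_coal.
    r_kin : float
        Kin-selection (like-with-like) assortment strength within each sex.
    a_assort : float
        Positive-assortment strength between Cooperative Mothers and
        Coalition Males.
    """

    s0: float = 0.625
    sf: float = 0.945
    b_allo: float = 0.0
    T_ibi: float = 5.0
    delta_ibi: float = 1.25
    e_noncoal: float = 0.10
    e_coal: float = 0.025
    b_noncoal: float = 0.025
    b_coal: float = 0.05
    r_kin: float = 0.0
    a_assort: float = 0.0

    def validate(self) -> "ModelParams":
        return validate_params(self)

    def replace(self, **kw) -> "ModelParams":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


PARAM_FIELDS = tuple(f.name for f in dataclasses.fields(ModelParams))


def validate_params(p: ModelParams) -> ModelParams:
    """Check every invariant of the parameter space.

    Returns ``p`` unchanged if valid, otherwise raises :class:`ParamError`
    naming the offending field and constraint.
    """
    for name in PARAM_FIELDS:
        v = getattr(p, name)
        if not math.isfinite(v):
            raise ParamError(f"{name}: non-finite value {v!r}")
    checks = (
        ("s0", 0.0 <= p.s0 <= 1.0, "0 <= s0 <= 1"),
        ("sf", 0.0 <= p.sf < 1.0, "0 <= sf < 1"),
        ("b_allo", -1.0 <= p.b_allo <= 1.0, "-1 <= b_allo <= 1"),
        ("T_ibi", p.T_ibi > 0.0, "T_ibi > 0"),
        ("delta_ibi", 0.0 <= p.delta_ibi < p.T_ibi, "0 <= delta_ibi < T_ibi"),
        ("e_noncoal", 0.0 <= p.e_noncoal <= 1.0, "0 <= e_noncoal <= 1"),
        ("e_coal", 0.0 <= p.e_coal <= 1.0, "0 <= e_coal <= 1"),
        ("e_coal", p.e_coal <= p.e_noncoal, "ordering e_coal <= e_noncoal"),
        ("b_noncoal", 0.0 <= p.b_noncoal <= 1.0, "0 <= b_noncoal <= 1"),
        ("b_coal", 0.0 <= p.b_coal <= 1.0, "0 <= b_coal <= 1"),
        ("b_noncoal", p.b_noncoal <= p.b_coal, "ordering b_noncoal <= b_coal"),
        ("r_kin", 0.0 <= p.r_kin <= 1.0, "0 <= r_kin <= 1"),
        ("a_assort", 0.0 <= p.a_assort <= 1.0, "0 <= a_assort <= 1"),
    )
    for name, ok, constraint in checks:
        if not ok:
            raise ParamError(f"{name}: constraint '{constraint}' violated "
                             f"(value {getattr(p, name)!r})")
    return p


Bound = tuple  # (lo, hi)


@dataclass(frozen=True)
class ParamRanges:
    """Lo/hi bounds per parameter; defaults are the hypothesized ranges.

    ``r_kin`` and ``a_assort`` default to the full [0, 1] interval; the
    experiment drivers fix them (to 0, or to swept values) as each design
    requires.
    """

    s0: Bound = (0.5, 0.75)
    sf: Bound = (0.90, 0.99)
    b_allo: Bound = (-0.5, 0.5)
    T_ibi: Bound = (5.0, 5.0)
    delta_ibi: Bound = (0.5, 2.0)
    e_noncoal: Bound = (0.0, 0.2)
    e_coal: Bound = (0.0, 0.05)
    b_noncoal: Bound = (0.0, 0.05)
    b_coal: Bound = (0.0, 0.1)
    r_kin: Bound = (0.0, 1.0)
    a_assort: Bound = (0.0, 1.0)

    @classmethod
    def table_defaults(cls) -> "ParamRanges":
        """The default hypothesized ranges."""
        return cls()

    def validate(self) -> "ParamRanges":
        for name in PARAM_FIELDS:
            lo, hi = getattr(self, name)
            if not (math.isfinite(lo) and math.isfinite(hi)):
                raise ParamError(f"{name}: non-finite bounds ({lo!r}, {hi!r})")
            if lo > hi:
                raise ParamError(f"{name}: lo {lo!r} > hi {hi!r}")
        # bounds must lie inside each field's invariant domain; cross-field
        # orderings are enforced at sample time by rejection
        _domain = {
            "s0": (0.0, 1.0), "sf": (0.0, 1.0 - 1e-15), "b_allo": (-1.0, 1.0),
            "T_ibi": (1e-12, math.inf), "delta_ibi": (0.0, math.inf),
            "e_noncoal": (0.0, 1.0), "e_coal": (0.0, 1.0),
            "b_noncoal": (0.0, 1.0), "b_coal": (0.0, 1.0),
            "r_kin": (0.0, 1.0), "a_assort": (0.0, 1.0),
        }
        for name, (dlo, dhi) in _domain.items():
            lo, hi = getattr(self, name)
            if lo < dlo or hi > dhi:
                raise ParamError(
                    f"{name}: bounds ({lo!r}, {hi!r}) outside domain [{dlo}, {dhi}]")
        return self

    def fix(self, **kw: float) -> "ParamRanges":
        """Return a copy with the given fields fixed to degenerate ranges."""
        return dataclasses.replace(self, **{k: (float(v), float(v)) for k, v in kw.items()})

    def replace(self, **kw) -> "ParamRanges":
        return dataclasses.replace(self, **kw)

    def midpoint(self) -> ModelParams:
        """The centre of every range (a convenient representative point)."""
        vals = {n: 0.5 * (getattr(self, n)[0] + getattr(self, n)[1]) for n in PARAM_FIELDS}
        return validate_params(ModelParams(**vals))


@dataclass(frozen=True)
class PopulationState:
    """Female strategy frequencies on the 2-simplex plus Coalition-Male frequency."""

    x_cm: float
    y_om: float
    z_im: float
    q_coal: float

    def __post_init__(self):
        for name in ("x_cm", "y_om", "z_im", "q_coal"):
            v = getattr(self, name)
            if not (-1e-12 <= v <= 1.0 + 1e-12):
                raise ParamError(f"{name}: frequency {v!r} outside [0, 1]")
        s = self.x_cm + self.y_om + self.z_im
        if abs(s - 1.0) > 1e-9:
            raise ParamError(f"female frequencies sum to {s!r}, not 1")

    def female_frequencies(self) -> dict:
        return {CM: self.x_cm, OM: self.y_om, IM: self.z_im}

    def replace(self, **kw) -> "PopulationState":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def edge_state(x_cm: float, q_coal: float) -> PopulationState:
    """State on the CM–OM edge of the simplex (no Independent Mothers)."""
    return PopulationState(x_cm=x_cm, y_om=1.0 - x_cm, z_im=0.0, q_coal=q_coal)


def as_generator(seed) -> np.random.Generator:
    """Coerce an int seed / SeedSequence / Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    if isinstance(seed, np.random.SeedSequence):
        return np.random.Generator(np.random.PCG64(seed))
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(int(seed))))


_MAX_REJECTION_ROUNDS = 10_000


def sample_params(ranges: ParamRanges, n: int, seed) -> list[ModelParams]:
    """Draw ``n`` parameter vectors, each field independent uniform on [lo, hi].

    Vectors violating the ordering constraints (``e_coal <= e_noncoal``,
    ``b_noncoal <= b_coal``) are rejected and redrawn in full, so marginals
    stay uniform on the accepted region.  Reproducible given ``seed``.
    """
    if n < 1:
        raise ParamError(f"n must be >= 1, got {n}")
    ranges.validate()
    rng = as_generator(seed)
    lo = np.array([getattr(ranges, f)[0] for f in PARAM_FIELDS])
    hi = np.array([getattr(ranges, f)[1] for f in PARAM_FIELDS])
    idx = {f: i for i, f in enumerate(PARAM_FIELDS)}

    draws = np.empty((n, len(PARAM_FIELDS)))
    pending = np.arange(n)
    for _ in range(_MAX_REJECTION_ROUNDS):
        u = rng.random((pending.size, len(PARAM_FIELDS)))
        cand = lo + u * (hi - lo)
        ok = (cand[:, idx["e_coal"]] <= cand[:, idx["e_noncoal"]]) & \
             (cand[:, idx["b_noncoal"]] <= cand[:, idx["b_coal"]])
        draws[pending[ok]] = cand[ok]
        pending = pending[~ok]
        if pending.size == 0:
            break
    else:
        raise ParamError(
            "rejection sampling did not terminate: ordering constraints are "
            "unsatisfiable under the given ranges")
    out = [ModelParams(**dict(zip(PARAM_FIELDS, row))) for row in draws]
    for p in out:
        validate_params(p)
    return out


def uniform_simplex_state(rng) -> PopulationState:
    """Female frequencies uniform on the 2-simplex; q_coal uniform on [0, 1]."""
    rng = as_generator(rng)
    x, y, z = rng.dirichlet((1.0, 1.0, 1.0))
    return PopulationState(x_cm=float(x), y_om=float(y), z_im=float(z),
                           q_coal=float(rng.random()))


def params_to_dataframe(params: Sequence[ModelParams]) -> pd.DataFrame:
    """One row per draw, columns named exactly as the ModelParams fields."""
    return pd.DataFrame([p.to_dict() for p in params], columns=list(PARAM_FIELDS))


def params_from_dataframe(df: pd.DataFrame) -> list[ModelParams]:
    out = []
    for _, row in df.iterrows():
        out.append(validate_params(ModelParams(**{f: float(row[f]) for f in PARAM_FIELDS})))
    return out
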