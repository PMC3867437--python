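"""Deterministic evolutionary dynamics of the female strategies.

Frequencies evolve by discrete-time replicator (proportional-fitness)
dynamics: ``x' = x * w / w_mean``.  The Coalition-Male frequency is held
fixed — the female analysis conditions on the male composition.

The basin of attraction for Cooperative Mothers is measured on the CM–OM
edge of the simplex (Independent-Mother frequency zero, the conservative
setting): the unstable equilibrium ``x*`` where ``w_cm = w_om`` separates
initial conditions flowing toward the OM vertex (below) from those flowing
toward Cooperative Mothers (above), so ``basin_cm = 1 - x*``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .female import female_profile
from .params import (CM, IM, OM, ModelParams, ParamError, PopulationState,
                     edge_state)

__all__ = [
    "SimplexClassification",
    "BasinResult",
    "TrajectoryResult",
    "replicator_step",
    "trajectory",
    "classify_simplex",
    "cm_om_edge_equilibrium",
]

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class SimplexClassification:
    """Fitness comparison on a triangular lattice over the female simplex.

    ``labels[i]`` is the strictly highest-fitness strategy at lattice point
    ``i`` (or ``"tie"``).  Pairwise differences are stored so the
    ``w_om = w_im`` contour ("thick dark line" of the ternary analysis) can
    be traced from the sign field ``d_om_im``.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    labels: np.ndarray
    d_cm_om: np.ndarray
    d_om_im: np.ndarray
    d_cm_im: np.ndarray
    q_coal: float
    resolution: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x_cm": self.x, "y_om": self.y, "z_im": self.z,
            "label": self.labels,
            "w_cm_minus_w_om": self.d_cm_om,
            "w_om_minus_w_im": self.d_om_im,
            "w_cm_minus_w_im": self.d_cm_im,
        })


@dataclass(frozen=True)
class BasinResult:
    """Unstable CM–OM edge equilibrium and the implied CM basin of attraction.

    ``boundary_case`` is ``"interior"`` for a genuine interior crossing,
    ``"cm_always"`` (``x* = 0``) when Cooperative Mothers are favored along
    the whole edge, and ``"om_always"`` (``x* = 1``) when they never are.
    ``multiple`` flags more than one sign change along the edge; the
    largest unstable (− to +) crossing is reported.
    """

    x_star: float
    basin_cm: float
    boundary_case: str
    multiple: bool = False
    q_coal: float = 0.0
    tol: float = 1e-6

    def as_dict(self) -> dict:
        return {"x_star": self.x_star, "basin_cm": self.basin_cm,
                "boundary_case": self.boundary_case, "multiple": self.multiple,
                "q_coal": self.q_coal, "tol": self.tol}


@dataclass(frozen=True)
class TrajectoryResult:
    states: tuple
    converged: bool

    def __iter__(self):
        return iter(self.states)

    @property
    def final(self) -> PopulationState:
        return self.states[-1]


def replicator_step(p: ModelParams, state: PopulationState) -> PopulationState:
    """One discrete replicator update of the female frequencies."""
    prof = female_profile(p, state)
    if prof.w_mean <= 0.0:
        raise ParamError("population fitness collapse: mean female fitness <= 0")
    new = np.array([state.x_cm * prof.w_cm,
                    state.y_om * prof.w_om,
                    state.z_im * prof.w_im]) / prof.w_mean
    new = new / new.sum()  # keep the simplex exactly
    return PopulationState(x_cm=float(new[0]), y_om=float(new[1]),
                           z_im=float(new[2]), q_coal=state.q_coal)


def trajectory(p: ModelParams, state0: PopulationState, max_steps: int = 1000,
               tol: float = 1e-10) -> TrajectoryResult:
    """Iterate the replicator map until the L1 change drops below ``tol``.

    Non-convergence within ``max_steps`` returns the truncated trajectory
    flagged ``converged=False``.
    """
    if max_steps < 1:
        raise ParamError("max_steps must be >= 1")
    if tol <= 0:
        raise ParamError("tol must be > 0")
    states = [state0]
    cur = state0
    converged = False
    for _ in range(max_steps):
        nxt = replicator_step(p, cur)
        states.append(nxt)
        l1 = (abs(nxt.x_cm - cur.x_cm) + abs(nxt.y_om - cur.y_om)
              + abs(nxt.z_im - cur.z_im))
        cur = nxt
        if l1 < tol:
            converged = True
            break
    return TrajectoryResult(states=tuple(states), converged=converged)


def classify_simplex(p: ModelParams, q_coal: float,
                     grid_resolution: int = 30) -> SimplexClassification:
    """Label the favored strategy on a triangular lattice over the simplex."""
    if grid_resolution < 2:
        raise ParamError("grid_resolution must be >= 2")
    n = grid_resolution
    xs, ys, zs, labels = [], [], [], []
    d_cm_om, d_om_im, d_cm_im = [], [], []
    for i in range(n + 1):
        for j in range(n + 1 - i):
            k = n - i - j
            x, y, z = i / n, j / n, k / n
            prof = female_profile(p, PopulationState(x, y, z, q_coal))
            w = {CM: prof.w_cm, OM: prof.w_om, IM: prof.w_im}
            best = max(w, key=w.get)
            second = max((v for s, v in w.items() if s != best), default=-np.inf)
            labels.append("tie" if w[best] - second <= _TIE_TOL else best)
            xs.append(x); ys.append(y); zs.append(z)
            d_cm_om.append(prof.w_cm - prof.w_om)
            d_om_im.append(prof.w_om - prof.w_im)
            d_cm_im.append(prof.w_cm - prof.w_im)
    return SimplexClassification(
        x=np.array(xs), y=np.array(ys), z=np.array(zs),
        labels=np.array(labels, dtype=object),
        d_cm_om=np.array(d_cm_om), d_om_im=np.array(d_om_im),
        d_cm_im=np.array(d_cm_im), q_coal=q_coal, resolution=n)


def _edge_gap(p: ModelParams, q_coal: float, x: float) -> float:
    prof = female_profile(p, edge_state(x, q_coal))
    return prof.w_cm - prof.w_om


def cm_om_edge_equilibrium(p: ModelParams, q_coal: float, tol: float = 1e-6,
                           prescan: int = 200) -> BasinResult:
    """Locate the unstable CM–OM edge equilibrium by pre-scan plus bisection.

    Scans ``w_cm - w_om`` at ``prescan`` points on the edge; brackets where
    the sign goes − to + with increasing CM frequency (the unstable
    crossing) are refined by bisection to ``tol`` in frequency.  If the gap
    keeps one sign along the whole edge the result is a boundary case with
    the basin equal to 1 (CM always favored) or 0 (never).
    """
    if tol <= 0:
        raise ParamError("tol must be > 0")
    xs = np.linspace(0.0, 1.0, prescan)
    gaps = np.array([_edge_gap(p, q_coal, x) for x in xs])
    if np.all(gaps > 0.0):
        return BasinResult(0.0, 1.0, "cm_always", False, q_coal, tol)
    if np.all(gaps <= 0.0):
        return BasinResult(1.0, 0.0, "om_always", False, q_coal, tol)

    sign_change = np.nonzero(np.diff(np.signbit(-gaps)))[0]  # any flip of (gap > 0)
    unstable = [i for i in sign_change if gaps[i] <= 0.0 < gaps[i + 1]]
    multiple = len(sign_change) > 1
    if not unstable:
        # only stable (+ to −) crossings: CM favored near the OM vertex but
        # not near its own — report the last crossing, flagged
        i = sign_change[-1]
        lo, hi = xs[i], xs[i + 1]
        rising = False
    else:
        i = unstable[-1]  # largest unstable crossing (conservative basin)
        lo, hi = xs[i], xs[i + 1]
        rising = True
    g_lo = gaps[i]
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        g_mid = _edge_gap(p, q_coal, mid)
        same_side = (g_mid <= 0.0) if (g_lo <= 0.0) else (g_mid > 0.0)
        if same_side:
            lo = mid
        else:
            hi = mid
    x_star = 0.5 * (lo + hi)
    if not rising:
        return BasinResult(x_star, 1.0 - x_star, "interior", True, q_coal, tol)
    return BasinResult(x_star, 1.0 - x_star, "interior", multiple, q_coal, tol)
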