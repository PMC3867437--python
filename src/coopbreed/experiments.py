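"""Monte Carlo experiment drivers: basin sweeps, male-advantage surfaces,
and (x, q) region grids.

Each driver is a pure composition of the sampling, fitness and dynamics
modules: it fixes a design variable on a grid, draws the remaining
parameters uniformly from their hypothesized ranges, evaluates the model,
and reports per-grid-value means with 95% uncertainty bands (empirical
2.5/97.5 percentiles by default; standard-error bands by flag).

Variance-reduction design: parameter draws are derived from the root seed
and the grid-cell index only, so the same draws are reused across grid
values and across (r, a) panel combinations (common random numbers).
Orderings across a sweep therefore reflect the model, not draw noise, and
every result is bit-reproducible from (config, seed).

Unless a sweep targets them, the assortment parameters default to zero
(the conservative, no-assortment baseline) and the Coalition-Male
frequency is drawn uniformly per draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import cm_om_edge_equilibrium
from .male import male_advantage
from .params import (ModelParams, ParamError, ParamRanges, edge_state,
                     sample_params, uniform_simplex_state, validate_params)

__all__ = [
    "SweepResult",
    "RegionGrid",
    "basin_sweep",
    "male_advantage_surface",
    "male_region_grid",
    "SWEEP_VARIABLES",
    "SURFACE_AXES",
]

#: sweep-variable aliases -> ModelParams field
SWEEP_VARIABLES = {
    "maternal_survival": "sf",
    "kin_selection": "r_kin",
    "alloparental_effect": "b_allo",
}

SURFACE_AXES = ("epm_difference", "care_difference")

DEFAULT_SWEEP_GRIDS = {
    "maternal_survival": tuple(np.linspace(0.90, 0.99, 7).round(6)),
    "kin_selection": tuple(np.linspace(0.0, 0.5, 6).round(6)),
    "alloparental_effect": tuple(np.linspace(-0.5, 0.5, 6).round(6)),
}


@dataclass(frozen=True)
class SweepResult:
    """Per-grid-value mean and 95% band of a Monte Carlo sweep."""

    sweep_var: str
    grid: tuple
    mean: tuple
    lower: tuple
    upper: tuple
    n_draws: int
    seed: int
    band: str = "percentile"
    outcome: str = "basin_cm"

    def to_frame(self) -> pd.DataFrame:
        """Long format: one (grid value, statistic) per row."""
        rows = []
        for g, m, lo, hi in zip(self.grid, self.mean, self.lower, self.upper):
            rows += [
                {"sweep_var": self.sweep_var, "grid_value": g,
                 "statistic": "mean", "value": m},
                {"sweep_var": self.sweep_var, "grid_value": g,
                 "statistic": "lower95", "value": lo},
                {"sweep_var": self.sweep_var, "grid_value": g,
                 "statistic": "upper95", "value": hi},
            ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class RegionGrid:
    """Mean male advantage over an (x_cm, q_coal) grid at one (r, a) setting."""

    r_kin: float
    a_assort: float
    x_values: tuple
    q_values: tuple
    mean_advantage: np.ndarray  # shape (len(x_values), len(q_values))
    n_draws: int
    seed: int

    @property
    def favored(self) -> np.ndarray:
        return self.mean_advantage > 0.0

    def favored_area(self) -> float:
        """Fraction of grid cells whose mean advantage favors Coalition Males."""
        return float(self.favored.mean())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, x in enumerate(self.x_values):
            for j, q in enumerate(self.q_values):
                rows.append({
                    "r_kin": self.r_kin, "a_assort": self.a_assort,
                    "x_cm": x, "q_coal": q,
                    "mean_advantage": self.mean_advantage[i, j],
                    "favored": bool(self.favored[i, j]),
                })
        return pd.DataFrame(rows)


def _child_rng(seed: int, *index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=[int(seed), *map(int, index)])
    return np.random.Generator(np.random.PCG64(ss))


def _band(values: np.ndarray, band: str) -> tuple[float, float, float]:
    mean = float(values.mean())
    if band == "percentile":
        lo, hi = np.percentile(values, [2.5, 97.5])
    elif band == "sem":
        half = 1.96 * values.std(ddof=1) / np.sqrt(values.size)
        lo, hi = mean - half, mean + half
    else:
        raise ParamError(f"unknown band type {band!r}")
    return mean, float(lo), float(hi)


def _baseline_ranges(ranges: ParamRanges | None) -> ParamRanges:
    if ranges is None:
        ranges = ParamRanges.table_defaults().fix(r_kin=0.0, a_assort=0.0)
    return ranges.validate()


def basin_sweep(sweep_var: str, grid=None, ranges: ParamRanges | None = None,
                n_draws: int = 1000, seed: int = 0,
                band: str = "percentile") -> SweepResult:
    """CM basin of attraction vs one swept parameter, Monte Carlo over the rest.

    For each grid value the swept parameter is fixed, ``n_draws`` parameter
    sets are drawn from the remaining ranges (Coalition-Male frequency
    uniform per draw), and the basin is computed from the unstable CM–OM
    edge equilibrium.
    """
    if sweep_var not in SWEEP_VARIABLES:
        raise ParamError(
            f"unknown sweep variable {sweep_var!r}; one of {sorted(SWEEP_VARIABLES)}")
    if n_draws < 2:
        raise ParamError("n_draws must be >= 2")
    field = SWEEP_VARIABLES[sweep_var]
    if grid is None:
        grid = DEFAULT_SWEEP_GRIDS[sweep_var]
    grid = tuple(float(g) for g in grid)
    ranges = _baseline_ranges(ranges)

    means, los, his = [], [], []
    for gi, gval in enumerate(grid):
        rng = _child_rng(seed, gi)
        fixed = ranges.fix(**{field: gval})
        draws = sample_params(fixed, n_draws, rng)
        qs = rng.random(n_draws)
        vals = np.array([
            cm_om_edge_equilibrium(p, float(q)).basin_cm
            for p, q in zip(draws, qs)
        ])
        m, lo, hi = _band(vals, band)
        means.append(m); los.append(lo); his.append(hi)
    return SweepResult(sweep_var=sweep_var, grid=grid, mean=tuple(means),
                       lower=tuple(los), upper=tuple(his), n_draws=n_draws,
                       seed=seed, band=band, outcome="basin_cm")


def _surface_grid(axis: str, fixed_other: float, n_points: int) -> tuple:
    """Equal-count grid spanning the axis's feasible span under the default
    ranges, given the fixed offset of the other member of the pair."""
    if axis == "epm_difference":
        hi = ParamRanges().e_noncoal[1] - fixed_other
    else:
        hi = ParamRanges().b_coal[1] - fixed_other
    return tuple(np.linspace(0.0, hi, n_points).round(9))


def male_advantage_surface(axis: str, grid=None, fixed_other: float = 0.025,
                           ranges: ParamRanges | None = None,
                           n_draws: int = 10_000, seed: int = 0,
                           band: str = "percentile",
                           n_grid_points: int = 8) -> SweepResult:
    """Mean Coalition-vs-Non-coalition advantage vs a strategy difference.

    ``axis="epm_difference"`` varies ``e_noncoal - e_coal`` with ``e_coal``
    fixed at ``fixed_other``; ``axis="care_difference"`` varies
    ``b_coal - b_noncoal`` with ``b_noncoal`` fixed.  Remaining parameters
    are drawn from their ranges with assortment off (r = a = 0); each draw
    gets a female state uniform on the simplex and a uniform Coalition-Male
    frequency.  The same draws are reused across grid values.
    """
    if axis not in SURFACE_AXES:
        raise ParamError(f"unknown surface axis {axis!r}; one of {SURFACE_AXES}")
    if n_draws < 2:
        raise ParamError("n_draws must be >= 2")
    if grid is None:
        grid = _surface_grid(axis, fixed_other, n_grid_points)
    grid = tuple(float(g) for g in grid)
    if any(g < 0 for g in grid):
        raise ParamError("difference grid must be non-negative")
    ranges = _baseline_ranges(ranges)

    rng = _child_rng(seed, 0)
    base_draws = sample_params(ranges, n_draws, rng)
    states = [uniform_simplex_state(rng) for _ in range(n_draws)]

    means, los, his = [], [], []
    for diff in grid:
        vals = np.empty(n_draws)
        for k, (bp, st) in enumerate(zip(base_draws, states)):
            if axis == "epm_difference":
                pk = bp.replace(e_coal=fixed_other, e_noncoal=fixed_other + diff)
            else:
                pk = bp.replace(b_noncoal=fixed_other, b_coal=fixed_other + diff)
            vals[k] = male_advantage(validate_params(pk), st)
        m, lo, hi = _band(vals, band)
        means.append(m); los.append(lo); his.append(hi)
    return SweepResult(sweep_var=axis, grid=grid, mean=tuple(means),
                       lower=tuple(los), upper=tuple(his), n_draws=n_draws,
                       seed=seed, band=band, outcome="male_advantage")


def sign_change_location(result: SweepResult) -> float | None:
    """Linear-interpolated grid location where the mean outcome crosses zero."""
    g, m = np.asarray(result.grid), np.asarray(result.mean)
    for i in range(len(g) - 1):
        if m[i] >= 0.0 > m[i + 1]:
            frac = m[i] / (m[i] - m[i + 1])
            return float(g[i] + frac * (g[i + 1] - g[i]))
    return None


def male_region_grid(r_values=(0.0, 0.6), a_values=(0.0, 0.75),
                     grid_resolution: int = 10,
                     ranges: ParamRanges | None = None, n_draws: int = 100,
                     seed: int = 0) -> list[RegionGrid]:
    """Mean male advantage over an (x_cm, q_coal) grid for each (r, a) panel.

    The female state is the conservative zero-IM split
    ``(x, 1 - x, 0, q)``.  Cell draws are shared across panels (common
    random numbers), so panel contrasts are paired comparisons.
    """
    if n_draws < 1:
        raise ParamError("n_draws must be >= 1")
    ranges = _baseline_ranges(ranges)
    xs = tuple(((np.arange(grid_resolution) + 0.5) / grid_resolution).round(9))
    qs = xs
    combos = [(float(r), float(a)) for r in r_values for a in a_values]

    # draw once per cell, reuse across panels
    cell_draws: dict[tuple[int, int], list[ModelParams]] = {}
    for i in range(grid_resolution):
        for j in range(grid_resolution):
            rng = _child_rng(seed, i, j)
            cell_draws[i, j] = sample_params(ranges, n_draws, rng)

    out = []
    for r, a in combos:
        mean_adv = np.empty((grid_resolution, grid_resolution))
        for i, x in enumerate(xs):
            for j, q in enumerate(qs):
                st = edge_state(x, q)
                vals = [
                    male_advantage(validate_params(p.replace(r_kin=r, a_assort=a)), st)
                    for p in cell_draws[i, j]
                ]
                mean_adv[i, j] = float(np.mean(vals))
        out.append(RegionGrid(r_kin=r, a_assort=a, x_values=xs, q_values=qs,
                              mean_advantage=mean_adv, n_draws=n_draws,
                              seed=seed))
    return out
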