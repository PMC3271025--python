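"""Toy bistable network of Rhodopsin production.

A minimal rate-balance model of the proposed positive-feedback loop: Rhodopsin
protein up-regulates its own production machinery, giving a sigmoidal (Hill)
production term scaled by the Rhodopsin mRNA level m (the control parameter a
repressor like Dve lowers), balanced against first-order degradation:

    dP/dt = m * (basal + v_max * P^h / (P*^h + P^h)) - delta * P

Depending on m the system is monostable at low production, bistable, or
monostable at high production; in the bistable window a cell in the basal
state stays there until a rare fluctuation carries it over the unstable
threshold.  The buffering interpretation: keeping m low keeps the system in
the monostable-low regime — the repressor controls the *stability* of the
network, not its state.

The functional form and defaults (h = 4, basal = 0.05 v_max) are modeling
choices by analogy with classic bistable circuits such as the lac operon; the
rate balance is written in the protein coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

REGIMES = ("monostable_low", "bistable", "monostable_high")


@dataclass(frozen=True)
class ToyNetworkParams:
    """Rate-balance parameters; all positive, h >= 1."""

    m: float = 1.0  # Rhodopsin mRNA level (dimensionless control parameter)
    v_max: float = 1.0  # maximal production rate
    p_star: float = 1.0  # production threshold P* (half-activation protein level)
    h: float = 4.0  # activation steepness (Hill coefficient)
    basal: float = 0.05  # basal production rate (fraction of v_max by default)
    delta: float = 0.6  # degradation rate constant

    def __post_init__(self) -> None:
        for name in ("m", "v_max", "p_star", "basal", "delta"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.h < 1:
            raise ValueError("h must be >= 1")


def production_rate(P, params: ToyNetworkParams) -> np.ndarray:
    """m * (basal + v_max * P^h / (P*^h + P^h)); sigmoidal positive feedback."""
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise ValueError("protein level must be >= 0")
    hill = P**params.h / (params.p_star**params.h + P**params.h)
    return params.m * (params.basal + params.v_max * hill)


def degradation_rate(P, params: ToyNetworkParams) -> np.ndarray:
    return params.delta * np.asarray(P, dtype=float)


def net_rate(P, params: ToyNetworkParams) -> np.ndarray:
    return production_rate(P, params) - degradation_rate(P, params)


@dataclass(frozen=True)
class FixedPoint:
    level: float
    stable: bool


@dataclass(frozen=True)
class FixedPointSet:
    points: tuple[FixedPoint, ...]

    @property
    def n_stable(self) -> int:
        return sum(p.stable for p in self.points)

    @property
    def levels(self) -> list[float]:
        return [p.level for p in self.points]

    def __len__(self) -> int:
        return len(self.points)


def _p_max(params: ToyNetworkParams) -> float:
    """Upper bracket: the high steady state cannot exceed m(basal+v_max)/delta."""
    return 1.5 * params.m * (params.basal + params.v_max) / params.delta + params.p_star


def find_fixed_points(
    params: ToyNetworkParams, n_grid: int = 4000, tol: float = 1e-10
) -> FixedPointSet:
    """All steady states of dP/dt on [0, P_max] by sign-change bracketing.

    Roots are refined by bisection (brentq); stability follows from the sign
    of the net rate's slope (negative slope = stable).  Off the bifurcation
    set the number of fixed points is odd and stability alternates.
    """
    pmax = _p_max(params)
    grid = np.linspace(0.0, pmax, n_grid)
    f = net_rate(grid, params)
    roots: list[float] = []
    for i in range(len(grid) - 1):
        if f[i] == 0.0 and (not roots or abs(grid[i] - roots[-1]) > 1e-8 * pmax):
            roots.append(float(grid[i]))
        elif f[i] * f[i + 1] < 0:
            r = brentq(lambda p: float(net_rate(p, params)), grid[i], grid[i + 1], xtol=tol)
            if not roots or abs(r - roots[-1]) > 1e-8 * pmax:
                roots.append(float(r))
    if f[-1] == 0.0:
        roots.append(float(grid[-1]))
    eps = 1e-6 * pmax
    pts = []
    for r in sorted(roots):
        slope = (net_rate(min(r + eps, pmax), params) - net_rate(max(r - eps, 0.0), params))
        pts.append(FixedPoint(level=r, stable=bool(slope < 0)))
    return FixedPointSet(points=tuple(pts))


def classify_regime(params: ToyNetworkParams) -> str:
    """Classify as monostable_low / bistable / monostable_high.

    Bistable = two stable fixed points.  A single stable point is 'low' when
    it sits below the production threshold P*, else 'high'.
    """
    fps = find_fixed_points(params)
    if fps.n_stable >= 2:
        return "bistable"
    stable_levels = [p.level for p in fps.points if p.stable]
    if not stable_levels:  # numerically degenerate; treat as low
        return "monostable_low"
    return "monostable_low" if stable_levels[0] < params.p_star else "monostable_high"


def regime_diagram(
    m_values, base: ToyNetworkParams | None = None
) -> list[dict]:
    """Sweep the mRNA level and tabulate regimes and fixed points."""
    from dataclasses import replace

    base = base or ToyNetworkParams()
    rows = []
    for m in np.asarray(m_values, dtype=float):
        p = replace(base, m=float(m))
        fps = find_fixed_points(p)
        rows.append(
            {
                "m": float(m),
                "regime": classify_regime(p),
                "n_fixed_points": len(fps),
                "fixed_points": fps.levels,
                "stable": [fp.stable for fp in fps.points],
            }
        )
    return rows


def bistable_m_interval(
    base: ToyNetworkParams | None = None, m_lo: float = 1e-3, m_hi: float = 20.0,
    n: int = 400,
) -> tuple[float, float] | None:
    """Approximate bistable window of the mRNA control parameter, if any."""
    from dataclasses import replace

    base = base or ToyNetworkParams()
    ms = np.geomspace(m_lo, m_hi, n)
    flags = [classify_regime(replace(base, m=float(m))) == "bistable" for m in ms]
    if not any(flags):
        return None
    idx = np.flatnonzero(flags)
    return float(ms[idx[0]]), float(ms[idx[-1]])
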