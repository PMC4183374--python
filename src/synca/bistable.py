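"""Effective potential, saddle-node bifurcation and Kramers escape time for
the bistable (double-well) synapse under background activity.

Averaging the calcium-gated terms over the stationary calcium law adds two
quadratic wells to the bare quartic potential:

    U_eff(rho; nu) = 1/4 rho^2 (1-rho)^2 + Gamma_d rho^2 / 2
                     + Gamma_p (1-rho)^2 / 2,

with Gamma_d = gamma_d * alpha_d(nu) and Gamma_p = gamma_p * alpha_p(nu).  The
depression term deepens the DOWN well at the expense of the UP well; the
potentiation term pulls the remaining minimum towards
Gamma_p / (Gamma_p + Gamma_d).  As the rate grows the UP minimum disappears
through a saddle-node bifurcation; above that rate the synapse is monostable
and the flat-potential decay theory applies.

Below the bifurcation, memory is lost by noise-driven escape over the barrier.
The averaged dynamics are tau_rho * drho = -U_eff'(rho) dt
+ sigma_eff sqrt(tau_rho) dW with effective noise
sigma_eff = sigma * sqrt(alpha_d + alpha_p), and the mean escape time from the
UP well is the standard Kramers result

    T = 2 pi tau_rho / sqrt(U_eff''(rho_min) |U_eff''(rho_saddle)|)
        * exp( 2 dU / sigma_eff^2 ),

with dU the barrier height from the UP minimum to the saddle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import optimize

from . import calcium as _calcium
from .params import PlasticityParams, Potential

__all__ = [
    "EffectiveLandscape",
    "bare_potential",
    "effective_potential",
    "bifurcation_rate",
    "kramers_escape_time",
]

_SCAN_LO, _SCAN_HI, _SCAN_N = -0.2, 1.2, 2000


def bare_potential(rho, rho_star: float = 0.5):
    """Quartic double well with minima at 0 and 1 and barrier at ``rho_star``;
    its downhill drift is -U'(rho) = -rho (1-rho) (rho_star - rho)."""
    rho = np.asarray(rho, dtype=float)
    return (rho_star * rho ** 2 / 2.0 - (1.0 + rho_star) * rho ** 3 / 3.0
            + rho ** 4 / 4.0)


@dataclass
class EffectiveLandscape:
    """Effective efficacy landscape at one background rate (pre = post = nu)."""

    nu: float
    Gamma_p: float
    Gamma_d: float
    sigma_eff: float
    rho_star: float
    tau_rho: float
    fixed_points: np.ndarray        # sorted roots of dU_eff/drho in [-0.2, 1.2]
    U_eff: Callable = field(repr=False, default=None)
    dU_eff: Callable = field(repr=False, default=None)
    d2U_eff: Callable = field(repr=False, default=None)

    @property
    def bistable(self) -> bool:
        return len(self.fixed_points) == 3

    @property
    def barrier_dU(self) -> float:
        """U_eff(saddle) - U_eff(UP minimum); 0 when monostable."""
        if not self.bistable:
            return 0.0
        down, saddle, up = self.fixed_points
        return float(self.U_eff(saddle) - self.U_eff(up))

    @property
    def T_escape(self) -> float:
        """Kramers mean escape time (s) from the UP well; inf if sigma_eff = 0."""
        if not self.bistable:
            raise ValueError(
                "monostable landscape: use the flat-potential decay time")
        if self.sigma_eff == 0.0:
            return math.inf
        _, saddle, up = self.fixed_points
        curv = math.sqrt(self.d2U_eff(up) * abs(self.d2U_eff(saddle)))
        return (2.0 * math.pi * self.tau_rho / curv
                * math.exp(2.0 * self.barrier_dU / self.sigma_eff ** 2))


def _build(nu: float, p: PlasticityParams, alpha_d: float, alpha_p: float
           ) -> EffectiveLandscape:
    Gp = p.gamma_p * alpha_p
    Gd = p.gamma_d * alpha_d
    rs = p.rho_star

    def U(rho):
        rho = np.asarray(rho, dtype=float)
        return (bare_potential(rho, rs) + Gd * rho ** 2 / 2.0
                + Gp * (1.0 - rho) ** 2 / 2.0)

    def dU(rho):
        rho = np.asarray(rho, dtype=float)
        return rho * (1.0 - rho) * (rs - rho) + Gd * rho - Gp * (1.0 - rho)

    def d2U(rho):
        rho = np.asarray(rho, dtype=float)
        return (rs - 2.0 * (1.0 + rs) * rho + 3.0 * rho ** 2) + Gd + Gp

    grid = np.linspace(_SCAN_LO, _SCAN_HI, _SCAN_N)
    vals = dU(grid)
    roots = []
    for i in np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0):
        roots.append(optimize.brentq(dU, grid[i], grid[i + 1], xtol=1e-12))
    for i in np.flatnonzero(vals == 0.0):
        roots.append(grid[i])
    roots = np.array(sorted(roots))
    sigma_eff = p.sigma * math.sqrt(alpha_d + alpha_p)
    return EffectiveLandscape(nu=nu, Gamma_p=Gp, Gamma_d=Gd,
                              sigma_eff=sigma_eff, rho_star=rs,
                              tau_rho=p.tau_rho, fixed_points=roots,
                              U_eff=U, dU_eff=dU, d2U_eff=d2U)


def effective_potential(nu: float, p: PlasticityParams,
                        alphas: tuple[float, float] | None = None
                        ) -> EffectiveLandscape:
    """Effective landscape at pre = post = ``nu`` spikes/s (double-well mode)."""
    if p.potential is not Potential.DOUBLE_WELL:
        raise ValueError("effective potential is defined for the double well")
    if nu < 0:
        raise ValueError("nu must be >= 0")
    if alphas is None:
        if nu == 0:
            alphas = (0.0, 0.0)
        else:
            pdf = _calcium.stationary_pdf_numeric(nu, nu, p)
            alphas = (pdf.alpha_d, pdf.alpha_p)
    return _build(nu, p, *alphas)


def bifurcation_rate(p: PlasticityParams, nu_lo: float = 1e-3,
                     nu_hi: float = 20.0, xtol: float = 1e-3) -> float:
    """Rate at which the UP minimum disappears (fixed-point count 3 -> 1),
    located by bisection with root-counting of dU_eff/drho."""
    if p.potential is not Potential.DOUBLE_WELL:
        raise ValueError("bifurcation is defined for the double-well potential")

    def n_fixed(nu):
        return len(effective_potential(nu, p).fixed_points)

    if n_fixed(nu_lo) != 3:
        raise ValueError(f"not bistable even at {nu_lo}/s")
    if n_fixed(nu_hi) != 1:
        raise ValueError(f"still bistable at {nu_hi}/s; raise nu_hi")
    lo, hi = nu_lo, nu_hi
    while hi - lo > xtol:
        mid = 0.5 * (lo + hi)
        if n_fixed(mid) == 3:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def kramers_escape_time(nu: float, p: PlasticityParams) -> float:
    """Mean escape time (s) from the UP state at pre = post = ``nu``."""
    land = effective_potential(nu, p)
    if not land.bistable:
        raise ValueError(
            "monostable at this rate: use ou_theory.decay_time_constant")
    return land.T_escape
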