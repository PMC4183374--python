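"""Memory-decay theory for the flat-potential synapse.

Averaging the gated plasticity dynamics over the stationary calcium law turns
the efficacy into a (truncated) Ornstein-Uhlenbeck process: with
``Gamma_p = gamma_p * alpha_p`` and ``Gamma_d = gamma_d * alpha_d`` the mean
efficacy obeys

    tau_rho * d<rho>/dt = Gamma_p (1 - <rho>) - Gamma_d <rho>,

so an initially potentiated synapse decays exponentially with

    tau_eff = tau_rho / (Gamma_p + Gamma_d)

towards the unbounded mean ``Gamma_p / (Gamma_p + Gamma_d)``.  The reflecting
bounds at 0 and 1 truncate the stationary Gaussian, and the observable
asymptote is the truncated-Gaussian mean on [0, 1] built from that mean and the
stationary standard deviation

    sd = sigma * sqrt(alpha_d + alpha_p) / sqrt(2 (Gamma_p + Gamma_d))

(the gated noise has variance sigma^2 between the thresholds and 2 sigma^2
above the upper one, hence the ``alpha_d + alpha_p`` weight).

At low rates ``alpha_d ~ nu**k`` where k is the number of near-simultaneous
spikes needed to clear the depression threshold, giving the power law
``tau_eff ~ nu**-k``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import calcium as _calcium
from .params import PlasticityParams

__all__ = [
    "OUSummary",
    "summarize",
    "decay_time_constant",
    "asymptotic_mean",
    "mean_trajectory",
    "low_rate_power_law",
]


@dataclass(frozen=True)
class OUSummary:
    """Net plasticity rates and the derived decay/asymptote quantities."""

    Gamma_p: float            # net potentiation rate gamma_p * alpha_p
    Gamma_d: float            # net depression rate gamma_d * alpha_d
    tau_eff: float            # decay time constant (s)
    rho_bar: float            # truncated-Gaussian asymptotic mean on [0, 1]
    rho_bar_unbounded: float  # Gamma_p / (Gamma_p + Gamma_d)
    sd_stationary: float      # stationary OU standard deviation (pre-truncation)
    alpha_d: float
    alpha_p: float


def _alphas(nu_pre: float, nu_post: float, p: PlasticityParams):
    pdf = _calcium.stationary_pdf_numeric(nu_pre, nu_post, p)
    return pdf.alpha_d, pdf.alpha_p


def summarize(nu_pre: float, nu_post: float, p: PlasticityParams,
              alphas: tuple[float, float] | None = None) -> OUSummary:
    """Full OU summary at the given independent Poisson rates.

    ``alphas`` may be supplied to reuse a previously computed calcium PDF.
    """
    alpha_d, alpha_p = alphas if alphas is not None else _alphas(nu_pre, nu_post, p)
    Gp = p.gamma_p * alpha_p
    Gd = p.gamma_d * alpha_d
    G = Gp + Gd
    if G == 0.0:
        return OUSummary(Gamma_p=0.0, Gamma_d=0.0, tau_eff=math.inf,
                         rho_bar=math.nan, rho_bar_unbounded=math.nan,
                         sd_stationary=0.0, alpha_d=alpha_d, alpha_p=alpha_p)
    mu = Gp / G
    sd = p.sigma * math.sqrt((alpha_d + alpha_p) / (2.0 * G))
    if sd == 0.0:
        rho_bar = min(max(mu, 0.0), 1.0)
    else:
        a, b = (0.0 - mu) / sd, (1.0 - mu) / sd
        rho_bar = float(stats.truncnorm.mean(a, b, loc=mu, scale=sd))
    return OUSummary(Gamma_p=Gp, Gamma_d=Gd, tau_eff=p.tau_rho / G,
                     rho_bar=rho_bar, rho_bar_unbounded=mu, sd_stationary=sd,
                     alpha_d=alpha_d, alpha_p=alpha_p)


def decay_time_constant(nu_pre: float, nu_post: float, p: PlasticityParams) -> float:
    """Exponential decay time constant of the mean efficacy (s); +inf when the
    calcium trace never reaches the depression threshold."""
    return summarize(nu_pre, nu_post, p).tau_eff


def asymptotic_mean(nu_pre: float, nu_post: float, p: PlasticityParams) -> float:
    """Asymptotic mean efficacy (truncated-Gaussian mean on [0, 1])."""
    s = summarize(nu_pre, nu_post, p)
    if not math.isfinite(s.tau_eff):
        raise ValueError("zero net plasticity rate: asymptote undefined")
    return s.rho_bar


def mean_trajectory(rho0: float, t, summary: OUSummary):
    """Mean efficacy at time(s) ``t``: exponential relaxation from ``rho0`` to
    the truncated-Gaussian asymptote with time constant ``tau_eff``."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if not math.isfinite(summary.tau_eff):
        return np.broadcast_to(np.asarray(rho0, dtype=float), t.shape).copy()
    return summary.rho_bar + (rho0 - summary.rho_bar) * np.exp(-t / summary.tau_eff)


def low_rate_power_law(p: PlasticityParams, nu_grid) -> tuple[int, float]:
    """Number of spikes k needed to cross theta_d and the fitted log-log slope
    of ``tau_eff(nu)`` over ``nu_grid`` (pre = post = nu).

    At low rates the slope approaches ``-k``.
    """
    nu_grid = np.sort(np.asarray(nu_grid, dtype=float))
    if nu_grid.size < 3 or nu_grid[0] <= 0 or nu_grid[-1] / nu_grid[0] < 10.0 - 1e-9:
        raise ValueError("nu_grid must hold >= 3 positive rates spanning a decade")
    k = _calcium.min_spikes_to_cross(p, p.theta_d)
    taus = np.array([decay_time_constant(nu, nu, p) for nu in nu_grid])
    slope = np.polyfit(np.log(nu_grid), np.log(taus), 1)[0]
    return k, float(slope)
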