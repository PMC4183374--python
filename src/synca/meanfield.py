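"""Self-consistent mean-field theory for the plastic E/I network.

At the fixed point, three quantities determine each other: the excitatory and
inhibitory population rates (through the standard leaky integrate-and-fire
transfer function driven by the mean and variance of the summed synaptic
input) and the mean E-to-E efficacy (through the Poisson-input asymptote of
the plasticity model evaluated at the excitatory rate).  The solver iterates
the three maps with damping until the residual is below tolerance.

The transfer function (inverse mean first-passage time, zero refractory
period)

    nu = [ tau_m sqrt(pi) \\int_{y_r}^{y_th} erfcx(-u) du ]^{-1},
    y_x = (V_x - mu) / sigma,

is evaluated with the scaled complementary error function so the integrand
never overflows in the fluctuation-driven regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, special

from . import ou_theory
from .params import PlasticityParams

__all__ = ["MeanFieldSolution", "siegert_rate", "solve_self_consistent"]


def siegert_rate(mu: float, sigma: float, tau_m_s: float, V_th: float,
                 V_r: float) -> float:
    """Stationary firing rate (spikes/s) of an LIF neuron with white-noise
    input of mean ``mu`` and fluctuation amplitude ``sigma`` (both mV)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0 (white-noise-driven LIF only)")
    y_r = (V_r - mu) / sigma
    y_th = (V_th - mu) / sigma
    if y_th > 26.0:  # rate numerically zero; erfcx(-u) ~ 2 e^{u^2} overflows
        return 0.0
    val, _ = integrate.quad(lambda u: special.erfcx(-u), y_r, y_th,
                            epsrel=1e-10, limit=200)
    return 1.0 / (tau_m_s * math.sqrt(math.pi) * val)


@dataclass
class MeanFieldSolution:
    nu_E: float
    nu_I: float
    rho_bar: float
    mu_E: float
    mu_I: float
    sigma_E: float
    sigma_I: float
    residual: float
    iterations: int


def _moments(np_, nu_E, nu_I, rho_bar):
    """Mean and fluctuation amplitude of the input to each population.

    ``np_`` is a NetworkParams-like object; expected in-degrees are
    p_conn * N_E and p_conn * N_I; inhibitory weights carry their sign.
    """
    C_E = np_.p_conn * np_.N_E
    C_I = np_.p_conn * np_.N_I
    tau = np_.tau_m * 1e-3
    w_EE = np_.J_EE_max * rho_bar
    mu_rec_E = tau * (C_E * w_EE * nu_E + C_I * np_.J_EI * nu_I)
    mu_rec_I = tau * (C_E * np_.J_IE * nu_E + C_I * np_.J_II * nu_I)
    var_E = tau * (C_E * w_EE ** 2 * nu_E + C_I * np_.J_EI ** 2 * nu_I)
    var_I = tau * (C_E * np_.J_IE ** 2 * nu_E + C_I * np_.J_II ** 2 * nu_I)
    mu_E = np_.V_L + np_.mu_ext + mu_rec_E
    mu_I = np_.V_L + np_.mu_ext + mu_rec_I
    sigma_E = math.sqrt(np_.sigma_ext ** 2 + var_E)
    sigma_I = math.sqrt(np_.sigma_ext ** 2 + var_I)
    return mu_E, mu_I, sigma_E, sigma_I


def solve_self_consistent(net, p: PlasticityParams,
                          init: tuple[float, float] = (2.0, 2.0),
                          damping: float = 0.5, tol: float = 1e-8,
                          max_iter: int = 400) -> MeanFieldSolution:
    """Damped fixed-point iteration on (nu_E, nu_I, rho_bar).

    ``net`` holds the network constants (a ``NetworkParams``).  The mean E-to-E
    efficacy is the Poisson-input truncated-OU asymptote at the excitatory
    rate (pre = post = nu_E).
    """
    nu_E, nu_I = init
    if nu_E <= 0 or nu_I <= 0:
        raise ValueError("initial rates must be > 0")
    tau = net.tau_m * 1e-3
    rho_bar = 0.5
    alpha_cache: dict[float, float] = {}

    def rho_of(nu):
        key = round(nu, 4)
        if key not in alpha_cache:
            if key <= 0:
                alpha_cache[key] = float("nan")
            else:
                alpha_cache[key] = ou_theory.asymptotic_mean(key, key, p)
        return alpha_cache[key]

    residual = math.inf
    for it in range(1, max_iter + 1):
        mu_E, mu_I, sigma_E, sigma_I = _moments(net, nu_E, nu_I, rho_bar)
        nu_E_new = siegert_rate(mu_E, sigma_E, tau, net.V_th, net.V_r)
        nu_I_new = siegert_rate(mu_I, sigma_I, tau, net.V_th, net.V_r)
        rho_new = rho_of(max(nu_E_new, 1e-4))
        residual = max(abs(nu_E_new - nu_E), abs(nu_I_new - nu_I),
                       abs(rho_new - rho_bar))
        nu_E += damping * (nu_E_new - nu_E)
        nu_I += damping * (nu_I_new - nu_I)
        rho_bar += damping * (rho_new - rho_bar)
        if residual < tol:
            break
    else:
        raise RuntimeError(
            f"mean-field iteration did not converge (residual {residual:.3g})")
    mu_E, mu_I, sigma_E, sigma_I = _moments(net, nu_E, nu_I, rho_bar)
    return MeanFieldSolution(nu_E=nu_E, nu_I=nu_I, rho_bar=rho_bar,
                             mu_E=mu_E, mu_I=mu_I, sigma_E=sigma_E,
                             sigma_I=sigma_I, residual=residual, iterations=it)
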