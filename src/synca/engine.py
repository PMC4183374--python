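"""Exact event-based propagation of the synaptic efficacy.

Between calcium events the efficacy evolves under the gated dynamics

    tau_rho * drho = [ -U'(rho) + gamma_p (1-rho) H(c-theta_p)
                       - gamma_d rho H(c-theta_d) ] dt
                     + sigma sqrt(tau_rho) sqrt(H(c-theta_d) + H(c-theta_p)) dW,

with the calcium trace a decaying exponential, so each inter-event interval
splits into at most three epochs (above theta_p, between the thresholds, below
theta_d) whose durations are closed-form crossing times.  Because
gamma_p, gamma_d >> 1 the quartic potential is negligible during the short
suprathreshold epochs and the efficacy there is an Ornstein-Uhlenbeck process
whose transition mean and standard deviation are exact; the subthreshold epoch
is deterministic and integrates in closed form for both potentials.  The
update is therefore exact event to event — no time-stepping error.

A pure-Python reference path (:func:`advance`, :func:`run_synapse`) exposes
each step; a numba kernel (:func:`run_events_fast`) runs the identical update
rule over a pre-merged event array for ensemble and network work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .calcium import CalciumState, threshold_crossing_partition
from .params import PlasticityParams, Potential

__all__ = [
    "SynapseState",
    "deterministic_update_flat",
    "deterministic_update_double_well",
    "stochastic_epoch_update",
    "advance",
    "run_synapse",
    "merge_event_queue",
    "run_events_fast",
]


# ---------------------------------------------------------------------------
# epoch updates
# ---------------------------------------------------------------------------

def deterministic_update_flat(rho: float, t: float) -> float:
    """Below theta_d the flat potential exerts no drift: identity."""
    if t < 0:
        raise ValueError("epoch length must be >= 0")
    return rho


def deterministic_update_double_well(rho: float, t: float, tau_rho: float,
                                     rho_star: float = 0.5) -> float:
    """Closed-form relaxation in the quartic double well over duration ``t``.

    For the symmetric well (rho_star = 1/2) the substitution u = (rho - 1/2)^2
    turns tau * drho/dt = -rho (1-rho) (1/2-rho) into the logistic equation
    tau * du/dt = u/2 - 2 u^2, so

        u(t) = u* u0 / ( u* e^{-s} + u0 (1 - e^{-s}) ),   u* = 1/4, s = t/(2 tau),

    and rho(t) = 1/2 + sign(rho0 - 1/2) sqrt(u(t)).  Fixed points 0, 1/2, 1 are
    exact; values outside [0, 1] relax back towards the nearest well.
    """
    if t < 0:
        raise ValueError("epoch length must be >= 0")
    if not math.isclose(rho_star, 0.5):
        raise NotImplementedError("closed form implemented for rho_star = 1/2")
    x = rho - 0.5
    u0 = x * x
    if u0 == 0.0 or t == 0.0:
        return rho
    e = math.exp(-t / (2.0 * tau_rho))
    u = 0.25 * u0 / (0.25 * e + u0 * (1.0 - e))
    return 0.5 + math.copysign(math.sqrt(u), x)


def stochastic_epoch_update(rho: float, t: float, drift_target: float,
                            drift_rate: float, noise_amp: float,
                            tau_rho: float, rng: np.random.Generator) -> float:
    """Exact OU transition over a suprathreshold epoch of length ``t``.

    ``drift_rate`` is the dimensionless relaxation rate g (gamma_d between the
    thresholds, gamma_p + gamma_d above both); the process is
    tau * drho = -g (rho - target) dt + noise_amp sqrt(tau) dW, whose
    transition law is Gaussian with mean target + (rho - target) e^{-g t / tau}
    and variance noise_amp^2 (1 - e^{-2 g t / tau}) / (2 g).
    """
    if t < 0:
        raise ValueError("epoch length must be >= 0")
    if t == 0.0:
        return rho
    decay = math.exp(-drift_rate * t / tau_rho)
    mean = drift_target + (rho - drift_target) * decay
    if noise_amp == 0.0:
        return mean
    sd = noise_amp * math.sqrt((1.0 - decay * decay) / (2.0 * drift_rate))
    return mean + sd * rng.standard_normal()


# ---------------------------------------------------------------------------
# full event-to-event state advance
# ---------------------------------------------------------------------------

@dataclass
class SynapseState:
    calcium: CalciumState = field(default_factory=CalciumState)
    rho: float = 1.0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)


def advance(state: SynapseState, dt: float, p: PlasticityParams) -> SynapseState:
    """Advance a synapse by ``dt`` with no event at the end.

    Applies, in temporal order: the above-theta_p OU epoch (drift towards
    gamma_p/(gamma_p+gamma_d) at rate gamma_p+gamma_d, noise sigma*sqrt(2)),
    the between-thresholds OU epoch (drift towards 0 at rate gamma_d, noise
    sigma), then the deterministic subthreshold update; finally decays calcium.
    In flat-potential mode rho is clipped to [0, 1] after each stochastic
    epoch, realising the truncation of the OU process at the bounds.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    c0 = state.calcium.c
    t_p, t_b, t_lo = threshold_crossing_partition(
        c0, dt, p.theta_d, p.theta_p, p.tau_ca_s)
    flat = p.potential is Potential.FLAT
    rho = state.rho
    if t_p > 0.0:
        rho = stochastic_epoch_update(
            rho, t_p, p.gamma_p / (p.gamma_p + p.gamma_d),
            p.gamma_p + p.gamma_d, p.sigma * math.sqrt(2.0), p.tau_rho,
            state.rng)
        if flat:
            rho = min(max(rho, 0.0), 1.0)
    if t_b > 0.0:
        rho = stochastic_epoch_update(rho, t_b, 0.0, p.gamma_d, p.sigma,
                                      p.tau_rho, state.rng)
        if flat:
            rho = min(max(rho, 0.0), 1.0)
    if t_lo > 0.0:
        if flat:
            rho = deterministic_update_flat(rho, t_lo)
        else:
            rho = deterministic_update_double_well(rho, t_lo, p.tau_rho,
                                                   p.rho_star)
    state.rho = rho
    state.calcium = CalciumState(
        c=c0 * math.exp(-dt / p.tau_ca_s),
        t_last=state.calcium.t_last + dt)
    return state


def merge_event_queue(pre_train, post_train, p: PlasticityParams):
    """Merge spike trains into a sorted calcium-event queue.

    Presynaptic transients arrive at spike time + D, postsynaptic at spike
    time.  Events closer than 1e-12 s are merged into a single jump of summed
    amplitude so that coincident arrivals neither depend on sort order nor
    consume extra noise draws.
    Returns (times, amplitudes).
    """
    pre = np.asarray(pre_train, dtype=float)
    post = np.asarray(post_train, dtype=float)
    if np.any(np.diff(pre) < 0) or np.any(np.diff(post) < 0):
        raise ValueError("spike trains must be sorted")
    times = np.concatenate([pre + p.delay_s, post])
    amps = np.concatenate([np.full(pre.size, p.C_pre),
                           np.full(post.size, p.C_post)])
    order = np.argsort(times, kind="stable")
    times, amps = times[order], amps[order]
    if times.size == 0:
        return times, amps
    keep = np.empty(times.size, dtype=bool)
    keep[0] = True
    keep[1:] = np.diff(times) > 1e-12
    groups = np.cumsum(keep) - 1
    out_t = times[keep]
    out_a = np.zeros(out_t.size)
    np.add.at(out_a, groups, amps)
    return out_t, out_a


def run_synapse(pre_train, post_train, p: PlasticityParams, rho0: float = 1.0,
                seed: int = 0, c0: float = 0.0):
    """Event-based trajectory for one synapse (reference implementation).

    Returns ``(event_times, rho_after_event)`` with the efficacy recorded just
    after each calcium event; reproducible given ``seed``.
    """
    times, amps = merge_event_queue(pre_train, post_train, p)
    state = SynapseState(calcium=CalciumState(c=c0, t_last=0.0), rho=rho0,
                         rng=np.random.default_rng(seed))
    rhos = np.empty(times.size)
    for i, (t, a) in enumerate(zip(times, amps)):
        advance(state, t - state.calcium.t_last, p)
        state.calcium = CalciumState(c=state.calcium.c + a, t_last=t)
        rhos[i] = state.rho
    return times, rhos


# ---------------------------------------------------------------------------
# numba fast path (identical update rule)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _dw_update(rho, t, tau_rho):
    x = rho - 0.5
    u0 = x * x
    if u0 == 0.0 or t == 0.0:
        return rho
    e = math.exp(-t / (2.0 * tau_rho))
    u = 0.25 * u0 / (0.25 * e + u0 * (1.0 - e))
    if x < 0.0:
        return 0.5 - math.sqrt(u)
    return 0.5 + math.sqrt(u)


@njit(cache=True)
def _advance_rho(rho, c0, dt, tau_ca, theta_d, theta_p, gamma_d, gamma_p,
                 sigma, tau_rho, double_well, z1, z2):
    """Same epoch sequence as :func:`advance`, scalar and jit-compiled.

    ``z1``/``z2`` are the pre-drawn unit normals for the above-theta_p and
    between-thresholds epochs; the function itself never touches the RNG (a
    scalar RNG call here would de-optimise callers that also draw noise in
    vector blocks).
    """
    t_p = 0.0
    t_d = 0.0
    if c0 > theta_p:
        t_p = min(dt, tau_ca * math.log(c0 / theta_p))
    if c0 > theta_d:
        t_d = min(dt, tau_ca * math.log(c0 / theta_d))
    t_b = t_d - t_p
    t_lo = dt - t_d
    if t_p > 0.0:
        g = gamma_p + gamma_d
        decay = math.exp(-g * t_p / tau_rho)
        rho = gamma_p / g + (rho - gamma_p / g) * decay
        # noise amplitude sigma * sqrt(2) above both thresholds
        rho += sigma * math.sqrt((1.0 - decay * decay) / g) * z1
        if not double_well:
            rho = min(max(rho, 0.0), 1.0)
    if t_b > 0.0:
        decay = math.exp(-gamma_d * t_b / tau_rho)
        rho = rho * decay
        rho += sigma * math.sqrt((1.0 - decay * decay) / (2.0 * gamma_d)) * z2
        if not double_well:
            rho = min(max(rho, 0.0), 1.0)
    if t_lo > 0.0 and double_well:
        rho = _dw_update(rho, t_lo, tau_rho)
    return rho


@njit(cache=True)
def _run_events(times, amps, is_sample, rho0, tau_ca, theta_d, theta_p,
                gamma_d, gamma_p, sigma, tau_rho, double_well, seed):
    np.random.seed(seed)
    c = 0.0
    rho = rho0
    t_last = 0.0
    n_out = 0
    for i in range(is_sample.size):
        if is_sample[i]:
            n_out += 1
    out = np.empty(n_out)
    k = 0
    for i in range(times.size):
        dt = times[i] - t_last
        z1 = np.random.standard_normal()
        z2 = np.random.standard_normal()
        rho = _advance_rho(rho, c, dt, tau_ca, theta_d, theta_p, gamma_d,
                           gamma_p, sigma, tau_rho, double_well, z1, z2)
        c = c * math.exp(-dt / tau_ca) + amps[i]
        t_last = times[i]
        if is_sample[i]:
            out[k] = rho
            k += 1
    return out


def run_events_fast(times, amps, is_sample, p: PlasticityParams,
                    rho0: float, seed: int) -> np.ndarray:
    """Jit-compiled event loop; returns rho at the events flagged as samples.

    ``times`` must be sorted and already include the presynaptic delay; sample
    points are zero-amplitude events.
    """
    return _run_events(np.ascontiguousarray(times, dtype=np.float64),
                       np.ascontiguousarray(amps, dtype=np.float64),
                       np.ascontiguousarray(is_sample, dtype=np.bool_),
                       float(rho0), p.tau_ca_s, p.theta_d, p.theta_p,
                       p.gamma_d, p.gamma_p, p.sigma, p.tau_rho,
                       p.potential is Potential.DOUBLE_WELL,
                       int(seed) % (2 ** 31 - 1))


@njit(cache=True)
def _first_passage(max_events, rate_total, p_pre, delay, rho0, rho_cross,
                   C_pre, C_post, tau_ca, theta_d, theta_p, gamma_d, gamma_p,
                   sigma, tau_rho, double_well, seed):
    """Simulate a synapse under merged Poisson drive until rho first crosses
    ``rho_cross`` downward; returns crossing time or -1.0 (censored).

    The pre-spike delay only shifts one Poisson stream, so events are drawn
    directly from the merged process at rate ``rate_total``."""
    np.random.seed(seed)
    c = 0.0
    rho = rho0
    t = 0.0
    for _ in range(max_events):
        dt = -math.log(np.random.random()) / rate_total
        z1 = np.random.standard_normal()
        z2 = np.random.standard_normal()
        rho = _advance_rho(rho, c, dt, tau_ca, theta_d, theta_p, gamma_d,
                           gamma_p, sigma, tau_rho, double_well, z1, z2)
        t += dt
        if rho < rho_cross:
            return t
        c = c * math.exp(-dt / tau_ca)
        if np.random.random() < p_pre:
            c += C_pre
        else:
            c += C_post
    return -1.0
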