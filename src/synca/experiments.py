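"""Ensemble experiments on isolated synapses driven by independent Poisson
pre- and postsynaptic firing: memory-decay curves, exponential fits, and
UP-state dwell-time statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .engine import _first_passage, merge_event_queue, run_events_fast
from .params import ExperimentConfig, PlasticityParams, Potential

__all__ = [
    "DecayFit",
    "EnsembleResult",
    "generate_poisson_train",
    "run_ensemble",
    "fit_exponential",
    "DwellStats",
    "dwell_time_stats",
]


def generate_poisson_train(rate: float, duration: float,
                           rng: np.random.Generator | int) -> np.ndarray:
    """Sorted spike times of a homogeneous Poisson process on [0, duration)."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = rng.poisson(rate * duration)
    return np.sort(rng.random(n) * duration)


@dataclass
class EnsembleResult:
    times: np.ndarray        # sample grid (s)
    mean: np.ndarray         # ensemble-mean efficacy at the samples
    traces: np.ndarray | None  # (n_synapses, n_samples) if requested


def run_ensemble(config: ExperimentConfig, p: PlasticityParams,
                 sample_dt: float | None = None,
                 return_traces: bool = False) -> EnsembleResult:
    """Simulate ``n_synapses`` independent synapses and bin the mean efficacy.

    Every synapse gets its own pre/post Poisson pair and its own random
    stream, keyed by (config.seed, synapse index), so the result does not
    depend on execution order.  Sampling is exact: sample points are
    zero-amplitude events of the event queue.
    """
    if sample_dt is None:
        sample_dt = config.duration / 200.0
    samples = np.arange(sample_dt, config.duration + 1e-12, sample_dt)
    n_s = samples.size
    acc = np.zeros(n_s)
    traces = np.empty((config.n_synapses, n_s)) if return_traces else None
    root = np.random.SeedSequence([config.seed, 0x5CA])
    for i, child in enumerate(root.spawn(config.n_synapses)):
        rng = np.random.default_rng(child)
        pre = generate_poisson_train(config.nu_pre, config.duration, rng)
        post = generate_poisson_train(config.nu_post, config.duration, rng)
        times, amps = merge_event_queue(pre, post, p)
        ev_t = np.concatenate([times, samples])
        ev_a = np.concatenate([amps, np.zeros(n_s)])
        ev_s = np.concatenate([np.zeros(times.size, dtype=bool),
                               np.ones(n_s, dtype=bool)])
        order = np.argsort(ev_t, kind="stable")
        kernel_seed = int(child.generate_state(1, np.uint32)[0]) % (2 ** 31 - 1)
        out = run_events_fast(ev_t[order], ev_a[order], ev_s[order], p,
                              config.rho_init, kernel_seed)
        acc += out
        if return_traces:
            traces[i] = out
    return EnsembleResult(times=samples, mean=acc / config.n_synapses,
                          traces=traces)


@dataclass
class DecayFit:
    tau_fit: float        # fitted decay time constant (s)
    asymptote_fit: float  # fitted plateau a
    rho0_fit: float       # fitted value at t = 0 (a + b)
    residual_rms: float


def fit_exponential(times, values, tau0: float | None = None) -> DecayFit:
    """Least-squares fit of a + b * exp(-t / tau) to a mean efficacy trace."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 10:
        raise ValueError("need at least 10 points to fit a decay")
    if np.ptp(y) < 1e-12:
        raise ValueError("constant trace: no decay to fit")
    if tau0 is None:
        tau0 = (t[-1] - t[0]) / 3.0
    p0 = (y[-1], y[0] - y[-1], tau0)

    def model(t, a, b, tau):
        return a + b * np.exp(-t / tau)

    try:
        popt, _ = optimize.curve_fit(model, t, y, p0=p0, maxfev=20000,
                                     bounds=([-1.0, -2.0, 1e-6],
                                             [2.0, 2.0, np.inf]))
    except RuntimeError as exc:
        raise RuntimeError(
            f"exponential fit did not converge: {exc}; trace span "
            f"[{y.min():.4g}, {y.max():.4g}] over {t[-1] - t[0]:.4g} s"
        ) from exc
    a, b, tau = popt
    rms = float(np.sqrt(np.mean((model(t, *popt) - y) ** 2)))
    return DecayFit(tau_fit=float(tau), asymptote_fit=float(a),
                    rho0_fit=float(a + b), residual_rms=rms)


@dataclass
class DwellStats:
    mean_dwell: float     # exponential-MLE mean UP-state dwell time (s)
    n_crossed: int
    n_censored: int
    total_observed: float  # summed observation time (s)


def dwell_time_stats(nu: float, p: PlasticityParams, n_synapses: int,
                     t_max: float, seed: int = 0,
                     rho_cross: float | None = None) -> DwellStats:
    """Mean first-passage time from rho = 1 down across the barrier.

    Each synapse is driven by merged pre+post Poisson input at 2 * nu and
    simulated until its efficacy first falls below ``rho_cross`` (default:
    the barrier position rho_star) or until ``t_max`` (censored).  The mean is
    the exponential maximum-likelihood estimate with right-censoring:
    total observed time / number of observed crossings.
    """
    if p.potential is not Potential.DOUBLE_WELL:
        raise ValueError("dwell times are defined for the double-well synapse")
    if rho_cross is None:
        rho_cross = p.rho_star
    if p.sigma == 0.0:
        # no noise: below the bifurcation the UP state is never left
        return DwellStats(mean_dwell=math.inf, n_crossed=0,
                          n_censored=n_synapses, total_observed=0.0)
    rate_total = 2.0 * nu
    max_events = int(1.2 * rate_total * t_max) + 200
    total = 0.0
    n_cross = 0
    root = np.random.SeedSequence([seed, 0xD3E11])
    for child in root.spawn(n_synapses):
        s = int(child.generate_state(1, np.uint32)[0]) % (2 ** 31 - 1)
        t = _first_passage(max_events, rate_total, 0.5, p.delay_s, 1.0,
                           rho_cross, p.C_pre, p.C_post, p.tau_ca_s,
                           p.theta_d, p.theta_p, p.gamma_d, p.gamma_p,
                           p.sigma, p.tau_rho,
                           p.potential is Potential.DOUBLE_WELL, s)
        if 0.0 <= t <= t_max:
            total += t
            n_cross += 1
        else:
            total += t_max
    if n_cross == 0:
        if t_max <= 0:
            raise ValueError("no crossings and no censoring information")
        return DwellStats(mean_dwell=math.inf, n_crossed=0,
                          n_censored=n_synapses, total_observed=total)
    return DwellStats(mean_dwell=total / n_cross, n_crossed=n_cross,
                      n_censored=n_synapses - n_cross, total_observed=total)
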