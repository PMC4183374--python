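"""Recurrent E/I network of leaky integrate-and-fire neurons with plastic
excitatory-to-excitatory synapses.

Voltages follow tau_m dV = (V_L + mu_ext - V) dt + sigma_ext sqrt(tau_m) dW
plus delayed synaptic jumps; a spike resets V to V_r (zero refractory period).
Connectivity is Bernoulli(p_conn) without autapses.  Every E-to-E synapse
carries the calcium-based plasticity model and delivers a voltage jump of
J_EE_max * rho; synapses involving inhibition are fixed.  Synaptic efficacies
are updated event-wise with the exact scheme from :mod:`synca.engine` — at
each postsynaptic spike (calcium jump C_post) and, after the NMDA-rise delay
D, at each presynaptic spike (jump C_pre) — so the network time step only
limits the voltage integration, not the plasticity.

This is a scaled-down stand-in for the full-size network (8000 E + 2000 I at
p = 0.05): the default 800 E + 200 I at p = 0.2 keeps the expected in-degrees
at 160 E / 40 I, and the voltage jumps are sized so the input mean and
variance per neuron stay in the fluctuation-driven, inhibition-dominated
regime.  The transmission delay equals the integration step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import stats

from . import bistable, ou_theory
from .engine import _advance_rho
from .params import PlasticityParams, Potential

__all__ = [
    "NetworkParams",
    "NetworkState",
    "SimResult",
    "build_network",
    "simulate",
    "memory_implant_experiment",
    "stationary_efficacy_sampler",
    "simulate_independent_lif",
    "isi_statistics",
]


@dataclass(frozen=True)
class NetworkParams:
    N_E: int = 800
    N_I: int = 200
    p_conn: float = 0.2
    tau_m: float = 20.0        # ms
    V_L: float = -70.0         # mV
    V_th: float = -50.0        # mV
    V_r: float = -60.0         # mV
    refractory: float = 0.0    # ms; the model is defined with zero refractoriness
    mu_ext: float = 13.5       # mV, constant external drive above the leak
    sigma_ext: float = 4.0     # mV, external white-noise amplitude
    J_EE_max: float = 0.25     # mV, E->E jump at rho = 1
    J_EI: float = -1.0         # mV, I->E jump
    J_IE: float = 0.25         # mV, E->I jump
    J_II: float = -1.0         # mV, I->I jump
    dt: float = 0.1            # ms; transmission delay equals dt
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.V_r < self.V_th:
            raise ValueError("V_r must be below V_th")
        if not (0.0 < self.p_conn <= 1.0):
            raise ValueError("p_conn must be in (0, 1]")
        if self.N_E < 1 or self.N_I < 1:
            raise ValueError("population sizes must be >= 1")
        if self.refractory != 0.0:
            raise ValueError("the model is defined with zero refractory period")

    @property
    def N(self) -> int:
        return self.N_E + self.N_I


@dataclass
class NetworkState:
    net: NetworkParams
    plasticity: PlasticityParams
    out_ptr: np.ndarray      # CSR over presynaptic neurons
    out_idx: np.ndarray      # postsynaptic targets
    out_syn: np.ndarray      # E->E synapse id per edge, -1 for fixed edges
    out_w: np.ndarray        # fixed weight per edge (ignored for plastic edges)
    post_ptr: np.ndarray     # CSR over E neurons: incoming E->E synapses
    post_syn: np.ndarray
    syn_pre: np.ndarray      # presynaptic neuron per E->E synapse
    syn_post: np.ndarray
    rho: np.ndarray          # per-synapse efficacy
    c: np.ndarray            # per-synapse calcium
    t_last: np.ndarray       # per-synapse last-event time (s)
    V: np.ndarray            # membrane potentials (mV)

    @property
    def n_synapses(self) -> int:
        return self.rho.size


def stationary_efficacy_sampler(nu: float, p: PlasticityParams):
    """Inverse-CDF sampler for the stationary efficacy law at pre = post = nu.

    Flat potential: truncated Gaussian on [0, 1].  Double well: the stationary
    Fokker-Planck density exp(-2 U_eff / sigma_eff^2) of the effective
    landscape, normalised on a grid — bimodal below the bifurcation rate.
    Returns a callable (n, rng) -> samples.
    """
    if p.potential is Potential.FLAT:
        s = ou_theory.summarize(nu, nu, p)
        a = (0.0 - s.rho_bar_unbounded) / s.sd_stationary
        b = (1.0 - s.rho_bar_unbounded) / s.sd_stationary

        def sample(n, rng):
            return stats.truncnorm.rvs(a, b, loc=s.rho_bar_unbounded,
                                       scale=s.sd_stationary, size=n,
                                       random_state=rng)
        return sample

    land = bistable.effective_potential(nu, p)
    grid = np.linspace(-0.2, 1.2, 4001)
    logw = -2.0 * land.U_eff(grid) / land.sigma_eff ** 2
    w = np.exp(logw - logw.max())
    cdf = np.cumsum(w)
    cdf /= cdf[-1]

    def sample(n, rng):
        return np.interp(rng.random(n), cdf, grid)
    return sample


def build_network(net: NetworkParams, p: PlasticityParams,
                  rho_init_mode: str = "constant", rho_init: float = 0.5,
                  target_rate: float | None = None) -> NetworkState:
    """Draw the Bernoulli connectivity (no autapses) and initialise synapses.

    ``rho_init_mode``: "constant" sets every E->E efficacy to ``rho_init``;
    "stationary_cdf" samples them by reverse lookup of the stationary-efficacy
    CDF at ``target_rate`` (required).
    """
    rng = np.random.default_rng(net.seed)
    N, N_E = net.N, net.N_E
    conn = rng.random((N, N)) < net.p_conn
    np.fill_diagonal(conn, False)

    fixed_w = np.zeros((N, N))
    fixed_w[:N_E, N_E:] = net.J_IE   # E pre -> I post
    fixed_w[N_E:, :N_E] = net.J_EI   # I pre -> E post
    fixed_w[N_E:, N_E:] = net.J_II

    out_ptr = np.zeros(N + 1, dtype=np.int64)
    out_idx_l, out_syn_l, out_w_l = [], [], []
    syn_pre_l, syn_post_l = [], []
    n_syn = 0
    for j in range(N):
        targets = np.flatnonzero(conn[j])
        out_idx_l.append(targets)
        syn_ids = np.full(targets.size, -1, dtype=np.int64)
        if j < N_E:
            ee = targets < N_E
            n_ee = int(ee.sum())
            syn_ids[ee] = np.arange(n_syn, n_syn + n_ee)
            syn_pre_l.append(np.full(n_ee, j, dtype=np.int64))
            syn_post_l.append(targets[ee])
            n_syn += n_ee
        out_syn_l.append(syn_ids)
        out_w_l.append(fixed_w[j, targets])
        out_ptr[j + 1] = out_ptr[j] + targets.size
    out_idx = np.concatenate(out_idx_l)
    out_syn = np.concatenate(out_syn_l)
    out_w = np.concatenate(out_w_l)
    syn_pre = np.concatenate(syn_pre_l)
    syn_post = np.concatenate(syn_post_l)

    # incoming E->E synapses per E neuron (for postsynaptic calcium events)
    order = np.argsort(syn_post, kind="stable")
    post_syn = order.astype(np.int64)
    counts = np.bincount(syn_post, minlength=N_E)
    post_ptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)

    if rho_init_mode == "constant":
        rho = np.full(n_syn, float(rho_init))
    elif rho_init_mode == "stationary_cdf":
        if target_rate is None:
            raise ValueError("stationary_cdf mode needs target_rate")
        rho = stationary_efficacy_sampler(target_rate, p)(n_syn, rng)
    else:
        raise ValueError(f"unknown rho_init_mode {rho_init_mode!r}")

    V = net.V_r + (net.V_th - net.V_r) * rng.random(N)
    return NetworkState(net=net, plasticity=p, out_ptr=out_ptr,
                        out_idx=out_idx.astype(np.int64), out_syn=out_syn,
                        out_w=out_w, post_ptr=post_ptr, post_syn=post_syn,
                        syn_pre=syn_pre, syn_post=syn_post,
                        rho=np.asarray(rho, dtype=np.float64),
                        c=np.zeros(n_syn), t_last=np.zeros(n_syn), V=V)


@njit(cache=True)
def _process_events(step, t, nspk, spk, ring, ring_cnt, out_ptr, out_idx,
                    out_syn, out_w, post_ptr, post_syn, rho, c_syn, t_last,
                    inp, zbuf, zi, ever_below, ever_above, N_E, J_EE_max,
                    C_pre, C_post, tau_ca, theta_d, theta_p, gamma_d, gamma_p,
                    sigma, tau_rho, rho_star, double_well, plastic, D_steps):
    """Per-step synaptic work: presynaptic calcium transients that fell due
    (pre spike + D, via the ring buffer), spike delivery into the delayed
    input buffer, and immediate postsynaptic transients.

    Kept in its own jit function: the branchy event math de-optimises the
    voltage loop when compiled into the same function.
    """
    slot = step % (D_steps + 1)
    for k in range(ring_cnt[slot]):
        j = ring[slot, k]
        for e in range(out_ptr[j], out_ptr[j + 1]):
            s = out_syn[e]
            if s >= 0:
                dtv = t - t_last[s]
                rho[s] = _advance_rho(rho[s], c_syn[s], dtv, tau_ca, theta_d,
                                      theta_p, gamma_d, gamma_p, sigma,
                                      tau_rho, double_well, zbuf[zi],
                                      zbuf[zi + 1])
                zi += 2
                c_syn[s] = c_syn[s] * math.exp(-dtv / tau_ca) + C_pre
                t_last[s] = t
                if rho[s] < rho_star:
                    ever_below[s] = True
                elif rho[s] > rho_star:
                    ever_above[s] = True
    ring_cnt[slot] = 0
    for k in range(nspk):
        j = spk[k]
        # synaptic delivery, consumed by the voltage loop of the next step
        for e in range(out_ptr[j], out_ptr[j + 1]):
            s = out_syn[e]
            if s >= 0:
                inp[out_idx[e]] += J_EE_max * rho[s]
            else:
                inp[out_idx[e]] += out_w[e]
        if plastic and j < N_E:
            # schedule the delayed presynaptic transients ...
            slot2 = (step + D_steps) % (D_steps + 1)
            ring[slot2, ring_cnt[slot2]] = j
            ring_cnt[slot2] += 1
            # ... and apply the postsynaptic ones now
            for e in range(post_ptr[j], post_ptr[j + 1]):
                s = post_syn[e]
                dtv = t - t_last[s]
                rho[s] = _advance_rho(rho[s], c_syn[s], dtv, tau_ca, theta_d,
                                      theta_p, gamma_d, gamma_p, sigma,
                                      tau_rho, double_well, zbuf[zi],
                                      zbuf[zi + 1])
                zi += 2
                c_syn[s] = c_syn[s] * math.exp(-dtv / tau_ca) + C_post
                t_last[s] = t
                if rho[s] < rho_star:
                    ever_below[s] = True
                elif rho[s] > rho_star:
                    ever_above[s] = True
    return zi


@njit(cache=True)
def _record(r, t, win, cnt_E, cnt_I, N_E, N, rho, tags, rec_t, rec_rate_E,
            rec_rate_I, rec_rho_tag, rec_rho_untag):
    """Population rates over the closing window plus tagged/untagged mean
    efficacy.  A helper for the same reason as _process_events."""
    rec_t[r] = t
    rec_rate_E[r] = cnt_E / (N_E * win)
    rec_rate_I[r] = cnt_I / ((N - N_E) * win)
    s_tag = 0.0
    n_tag = 0
    s_un = 0.0
    n_un = 0
    for s in range(rho.size):
        if tags[s] == 1:
            s_tag += rho[s]
            n_tag += 1
        else:
            s_un += rho[s]
            n_un += 1
    rec_rho_tag[r] = s_tag / max(n_tag, 1)
    rec_rho_untag[r] = s_un / max(n_un, 1)


@njit(cache=True)
def _sim_kernel(n_steps, dt_s, N_E, N, V, out_ptr, out_idx, out_syn, out_w,
                post_ptr, post_syn, rho, c_syn, t_last, tags,
                tau_m_s, Vrest, sigma_ext, V_th, V_r, J_EE_max,
                C_pre, C_post, tau_ca, theta_d, theta_p, gamma_d, gamma_p,
                sigma, tau_rho, rho_star, double_well, plastic, D_steps,
                record_stride, t0, seed, max_spikes):
    np.random.seed(seed)
    leak = dt_s / tau_m_s
    noise = sigma_ext * math.sqrt(dt_s / tau_m_s)
    inp = np.zeros(N)
    spk = np.empty(N, dtype=np.int64)
    ring = np.empty((D_steps + 1, N_E), dtype=np.int64)
    ring_cnt = np.zeros(D_steps + 1, dtype=np.int64)
    # Pre-drawn unit normals for the synapse updates, refilled only at the
    # top of the step loop and sized so one step can never exhaust the
    # buffer (each synapse sees at most one pre and one post event per step,
    # two normals each).
    zneed = 4 * max(rho.size, 1)
    zcap = zneed + (1 << 20)
    zbuf = np.random.standard_normal(zcap)
    zi = 0
    n_rec = n_steps // record_stride
    rec_rate_E = np.zeros(n_rec)
    rec_rate_I = np.zeros(n_rec)
    rec_rho_tag = np.zeros(n_rec)
    rec_rho_untag = np.zeros(n_rec)
    rec_t = np.zeros(n_rec)
    ever_below = np.zeros(rho.size, dtype=np.bool_)
    ever_above = np.zeros(rho.size, dtype=np.bool_)
    raster_t = np.empty(max_spikes)
    raster_id = np.empty(max_spikes, dtype=np.int64)
    n_spk_total = 0
    cnt_E = 0
    cnt_I = 0
    for step in range(n_steps):
        t = t0 + step * dt_s
        if zi > zcap - zneed:
            zbuf = np.random.standard_normal(zcap)
            zi = 0
        # voltage update; noise drawn as one block per step
        xi = np.random.standard_normal(N)
        nspk = 0
        for i in range(N):
            V[i] += leak * (Vrest - V[i]) + inp[i] + noise * xi[i]
            inp[i] = 0.0
            if V[i] >= V_th:
                V[i] = V_r
                spk[nspk] = i
                nspk += 1
        for k in range(nspk):
            j = spk[k]
            if n_spk_total < max_spikes:
                raster_t[n_spk_total] = t
                raster_id[n_spk_total] = j
            n_spk_total += 1
            if j < N_E:
                cnt_E += 1
            else:
                cnt_I += 1
        zi = _process_events(step, t, nspk, spk, ring, ring_cnt, out_ptr,
                             out_idx, out_syn, out_w, post_ptr, post_syn,
                             rho, c_syn, t_last, inp, zbuf, zi, ever_below,
                             ever_above, N_E, J_EE_max, C_pre, C_post,
                             tau_ca, theta_d, theta_p, gamma_d, gamma_p,
                             sigma, tau_rho, rho_star, double_well, plastic,
                             D_steps)
        if (step + 1) % record_stride == 0:
            _record((step + 1) // record_stride - 1, t, record_stride * dt_s,
                    cnt_E, cnt_I, N_E, N, rho, tags, rec_t, rec_rate_E,
                    rec_rate_I, rec_rho_tag, rec_rho_untag)
            cnt_E = 0
            cnt_I = 0
    n_kept = min(n_spk_total, max_spikes)
    return (rec_t, rec_rate_E, rec_rate_I, rec_rho_tag, rec_rho_untag,
            raster_t[:n_kept], raster_id[:n_kept], n_spk_total,
            ever_below, ever_above)


@dataclass
class SimResult:
    times: np.ndarray            # record-window end times (s)
    rate_E: np.ndarray           # E-population rate per window (spikes/s)
    rate_I: np.ndarray
    mean_rho_tagged: np.ndarray
    mean_rho_untagged: np.ndarray
    raster_times: np.ndarray
    raster_ids: np.ndarray
    n_spikes_total: int
    tags: np.ndarray = field(repr=False, default=None)
    transitions_down: int = 0    # tagged synapses that ever fell below rho_star
    transitions_up: int = 0      # untagged synapses that ever rose above it

    def mean_rate_E(self, t_from: float = 0.0) -> float:
        m = self.times >= t_from
        return float(self.rate_E[m].mean())


def simulate(state: NetworkState, duration: float, plastic: bool = True,
             tags: np.ndarray | None = None, record_dt: float = 1.0,
             seed: int | None = None, max_spikes: int = 4_000_000,
             t0: float = 0.0) -> SimResult:
    """Run the network for ``duration`` seconds (state is advanced in place).

    ``tags`` marks a subset of E->E synapses (1 = tagged) whose mean efficacy
    is recorded separately; ``plastic=False`` freezes every efficacy at its
    current value (fixed-weight control).
    """
    net, p = state.net, state.plasticity
    dt_s = net.dt * 1e-3
    n_steps = int(round(duration / dt_s))
    record_stride = max(int(round(record_dt / dt_s)), 1)
    D_steps = max(int(round(p.delay_s / dt_s)), 1)
    if tags is None:
        tags = np.zeros(state.n_synapses, dtype=np.int8)
    if seed is None:
        seed = net.seed + 1
    out = _sim_kernel(
        n_steps, dt_s, net.N_E, net.N, state.V, state.out_ptr, state.out_idx,
        state.out_syn, state.out_w, state.post_ptr, state.post_syn, state.rho,
        state.c, state.t_last, np.asarray(tags, dtype=np.int8),
        net.tau_m * 1e-3, net.V_L + net.mu_ext, net.sigma_ext, net.V_th,
        net.V_r, net.J_EE_max, p.C_pre, p.C_post, p.tau_ca_s, p.theta_d,
        p.theta_p, p.gamma_d, p.gamma_p, p.sigma, p.tau_rho, p.rho_star,
        p.potential is Potential.DOUBLE_WELL, plastic, D_steps, record_stride,
        t0, int(seed) % (2 ** 31 - 1), max_spikes)
    (rec_t, rE, rI, rho_tag, rho_untag, rst_t, rst_id, n_total,
     ever_below, ever_above) = out
    tags = np.asarray(tags, dtype=bool)
    return SimResult(times=rec_t, rate_E=rE, rate_I=rI,
                     mean_rho_tagged=rho_tag, mean_rho_untagged=rho_untag,
                     raster_times=rst_t, raster_ids=rst_id,
                     n_spikes_total=int(n_total), tags=tags,
                     transitions_down=int(np.sum(ever_below & tags)),
                     transitions_up=int(np.sum(ever_above & ~tags)))


def memory_implant_experiment(state: NetworkState, duration: float,
                              fraction: float = 0.05,
                              baseline: float | None = None,
                              record_dt: float = 1.0,
                              seed: int | None = None) -> SimResult:
    """Implant a memory trace and watch it decay under the network's own
    background activity.

    A random ``fraction`` of the E->E synapses is set fully potentiated
    (rho = 1); the remainder starts at ``baseline`` — by default the
    flat-potential asymptote at the mean-field rate (flat mode) or the DOWN
    well (double-well mode).  Returns the traces of tagged and untagged mean
    efficacy together with the population rates.
    """
    net, p = state.net, state.plasticity
    rng = np.random.default_rng(net.seed + 7)
    n_tag = max(int(round(fraction * state.n_synapses)), 1)
    tags = np.zeros(state.n_synapses, dtype=np.int8)
    tags[rng.choice(state.n_synapses, size=n_tag, replace=False)] = 1
    if baseline is None:
        if p.potential is Potential.DOUBLE_WELL:
            baseline = 0.0
        else:
            from . import meanfield as _mf
            baseline = _mf.solve_self_consistent(net, p).rho_bar
    state.rho[:] = baseline
    state.rho[tags == 1] = 1.0
    state.c[:] = 0.0
    state.t_last[:] = 0.0
    return simulate(state, duration, plastic=True, tags=tags,
                    record_dt=record_dt, seed=seed)


# ---------------------------------------------------------------------------
# independent LIF neurons (transfer-function and ISI checks)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _lif_kernel(n_neurons, n_steps, dt_s, tau_m_s, mu, sigma, V_th, V_r, seed,
                max_spikes):
    np.random.seed(seed)
    leak = dt_s / tau_m_s
    noise = sigma * math.sqrt(dt_s / tau_m_s)
    V = np.full(n_neurons, V_r)
    t_sp = np.empty(max_spikes)
    id_sp = np.empty(max_spikes, dtype=np.int64)
    n = 0
    for step in range(n_steps):
        t = step * dt_s
        xi = np.random.standard_normal(n_neurons)
        for i in range(n_neurons):
            V[i] += leak * (mu - V[i]) + noise * xi[i]
            if V[i] >= V_th:
                V[i] = V_r
                if n < max_spikes:
                    t_sp[n] = t
                    id_sp[n] = i
                    n += 1
    return t_sp[:n], id_sp[:n]


def simulate_independent_lif(n_neurons: int, duration: float, mu: float,
                             sigma: float, net: NetworkParams,
                             seed: int = 0, burn_in: float = 1.0):
    """Disconnected LIF neurons under white-noise drive with total input mean
    ``mu`` (mV) and fluctuation ``sigma``; returns (times, ids) after a
    burn-in transient is discarded."""
    dt_s = net.dt * 1e-3
    n_steps = int(round((duration + burn_in) / dt_s))
    cap = int(n_neurons * (duration + burn_in) * 200) + 1000
    t, ids = _lif_kernel(n_neurons, n_steps, dt_s, net.tau_m * 1e-3, mu,
                         sigma, net.V_th, net.V_r,
                         int(seed) % (2 ** 31 - 1), cap)
    keep = t >= burn_in
    return t[keep] - burn_in, ids[keep]


@dataclass
class ISIStats:
    cv: float
    mean_isi: float
    n_isis: int
    short_mass: float          # fraction of ISIs below the short cutoff
    short_mass_poisson: float  # same fraction for an exponential at this rate
    hist_edges: np.ndarray = field(repr=False, default=None)
    hist_density: np.ndarray = field(repr=False, default=None)


def isi_statistics(times: np.ndarray, ids: np.ndarray, min_isis: int = 1000,
                   short_cutoff: float = 0.020, n_bins: int = 60) -> ISIStats:
    """Pooled interspike-interval statistics of a raster.

    ``short_mass`` measures the probability of ISIs below ``short_cutoff``
    seconds (default: one membrane time constant) and is compared with the
    exponential (Poisson) reference at the same mean rate: its excess or
    deficit controls how often calcium transients summate across the
    plasticity thresholds.
    """
    times = np.asarray(times, dtype=float)
    ids = np.asarray(ids)
    isis = []
    for i in np.unique(ids):
        ti = times[ids == i]
        if ti.size >= 2:
            isis.append(np.diff(np.sort(ti)))
    if not isis:
        raise ValueError("no interspike intervals in the raster")
    isis = np.concatenate(isis)
    if isis.size < min_isis:
        raise ValueError(f"too few ISIs ({isis.size} < {min_isis})")
    mean = float(isis.mean())
    cv = float(isis.std(ddof=1) / mean)
    short = float(np.mean(isis < short_cutoff))
    short_pois = 1.0 - math.exp(-short_cutoff / mean)
    dens, edges = np.histogram(isis, bins=n_bins,
                               range=(0.0, float(np.quantile(isis, 0.99))),
                               density=True)
    return ISIStats(cv=cv, mean_isi=mean, n_isis=int(isis.size),
                    short_mass=short, short_mass_poisson=short_pois,
                    hist_edges=edges, hist_density=dens)
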