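"""Desk-scale experiment protocols bundling simulation, theory overlay and
exponential fits, with a manifest per run.

Each protocol reproduces one of the canonical experiments at a size that runs
in minutes on one core: single-synapse memory decay (flat potential),
bistable-synapse analysis (effective potential, bifurcation, escape time),
and the scaled-network memory-implant experiments.  Scaled-down sizes are
recorded in the manifest's substitution log.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import __version__, bistable, io, meanfield, ou_theory
from .experiments import fit_exponential, run_ensemble
from .network import NetworkParams, build_network, memory_implant_experiment
from .params import ExperimentConfig, preset

__all__ = ["run_figure_protocol", "PROTOCOLS"]


def _decay_protocol(out: Path, manifest: io.RunManifest, *, preset_name,
                    rate, n_synapses, duration, seed):
    p = preset(preset_name)
    summary = ou_theory.summarize(rate, rate, p)
    cfg = ExperimentConfig(nu_pre=rate, nu_post=rate, duration=duration,
                           n_synapses=n_synapses, seed=seed, rho_init=1.0)
    res = run_ensemble(cfg, p)
    fit = fit_exponential(res.times, res.mean)
    theory = ou_theory.mean_trajectory(1.0, res.times, summary)
    io.write_trace(out / "mean_trace.csv", res.times, mean_rho=res.mean,
                   theory_rho=theory)
    result = {"tau_fit_s": fit.tau_fit, "asymptote_fit": fit.asymptote_fit,
              "tau_theory_s": summary.tau_eff, "rho_bar_theory": summary.rho_bar,
              "alpha_d": summary.alpha_d, "alpha_p": summary.alpha_p}
    with open(out / "fit.json", "w") as fh:
        json.dump(result, fh, indent=2)
    manifest.add_output(out / "mean_trace.csv")
    manifest.add_output(out / "fit.json")
    return result


def _bistable_protocol(out: Path, manifest: io.RunManifest, *, preset_name,
                       rate, seed):
    p = preset(preset_name, "double_well")
    nu_c = bistable.bifurcation_rate(p)
    land = bistable.effective_potential(rate, p)
    grid = np.linspace(-0.1, 1.1, 601)
    io.write_trace(out / "effective_potential.csv", grid, U_eff=land.U_eff(grid))
    result = {"nu_c": nu_c, "rate": rate,
              "fixed_points": land.fixed_points.tolist(),
              "sigma_eff": land.sigma_eff, "bistable": land.bistable}
    if land.bistable:
        result["barrier_dU"] = land.barrier_dU
        result["T_escape_s"] = land.T_escape
    with open(out / "bistable.json", "w") as fh:
        json.dump(result, fh, indent=2)
    manifest.add_output(out / "effective_potential.csv")
    manifest.add_output(out / "bistable.json")
    return result


def _implant_protocol(out: Path, manifest: io.RunManifest, *, preset_name,
                      potential, duration, seed, record_dt=2.0):
    p = preset(preset_name, potential)
    net = NetworkParams(seed=seed)
    manifest.note(
        "scaled network: 800E+200I at p_conn=0.2 stands in for 8000E+2000I "
        "at p_conn=0.05; run length %.0f s" % duration)
    sol = meanfield.solve_self_consistent(net, p)
    baseline = 0.0 if potential == "double_well" else sol.rho_bar
    state = build_network(net, p, rho_init_mode="constant", rho_init=baseline)
    res = memory_implant_experiment(state, duration, baseline=baseline,
                                    record_dt=record_dt, seed=seed + 1)
    io.write_trace(out / "traces.csv", res.times, rate_E=res.rate_E,
                   rate_I=res.rate_I, rho_tagged=res.mean_rho_tagged,
                   rho_untagged=res.mean_rho_untagged)
    io.write_spike_train(out / "raster.txt", res.raster_times, res.raster_ids)
    result = {"nu_E_meanfield": sol.nu_E, "nu_I_meanfield": sol.nu_I,
              "nu_E_simulated": res.mean_rate_E(duration / 2),
              "transitions_down": res.transitions_down,
              "transitions_up": res.transitions_up}
    obs_rate = max(result["nu_E_simulated"], 1e-3)
    summary = ou_theory.summarize(obs_rate, obs_rate, p)
    result["tau_theory_at_observed_rate_s"] = summary.tau_eff
    if potential == "flat":
        fit = fit_exponential(res.times, res.mean_rho_tagged,
                              tau0=summary.tau_eff)
        result["tau_fit_s"] = fit.tau_fit
    with open(out / "implant.json", "w") as fh:
        json.dump(result, fh, indent=2)
    for f in ("traces.csv", "raster.txt", "implant.json"):
        manifest.add_output(out / f)
    return result


PROTOCOLS = {
    "fig2": dict(kind="decay", preset_name="in_vitro", rate=1.0,
                 n_synapses=400, duration=900.0),
    "fig3": dict(kind="bistable", preset_name="in_vivo", rate=1.0),
    "fig5_scaled": dict(kind="implant", preset_name="in_vitro",
                        potential="flat", duration=300.0),
    "fig6_scaled": dict(kind="implant", preset_name="in_vivo",
                        potential="double_well", duration=600.0),
}


def run_figure_protocol(figure_id: str, out_dir, seed: int = 0,
                        overrides: dict | None = None) -> dict:
    """Run one named protocol, writing traces, fits and a manifest to
    ``out_dir``; returns the summary dict."""
    if figure_id not in PROTOCOLS:
        raise ValueError(f"unknown protocol {figure_id!r}; "
                         f"available: {sorted(PROTOCOLS)}")
    spec = dict(PROTOCOLS[figure_id])
    kind = spec.pop("kind")
    if overrides:
        spec.update(overrides)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = io.RunManifest(command=f"figure {figure_id}",
                              config={"figure_id": figure_id, **spec},
                              seed=seed)
    runner = {"decay": _decay_protocol, "bistable": _bistable_protocol,
              "implant": _implant_protocol}[kind]
    result = runner(out, manifest, seed=seed, **spec)
    manifest.write(out / "manifest.json")
    return result
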