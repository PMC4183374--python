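"""Model constants, published parameter presets and calcium-amplitude scaling.

The synapse model couples a postsynaptic calcium variable ``c`` (dimensionless,
the thresholds set the scale) to an efficacy variable ``rho``.  Calcium jumps by
``C_pre`` on each presynaptic spike (after an NMDA-rise delay ``D``) and by
``C_post`` on each postsynaptic spike, and decays exponentially with time
constant ``tau_Ca`` in between.  Whenever ``c`` exceeds the depression threshold
``theta_d`` the efficacy is depressed at rate ``gamma_d``; above the potentiation
threshold ``theta_p`` it is additionally potentiated at rate ``gamma_p``
(``gamma_p > gamma_d``, so potentiation wins in that region).  An activity-gated
noise of amplitude ``sigma`` acts whenever ``c > theta_d`` and grows by a factor
``sqrt(2)`` above ``theta_p``.  With the double-well potential the efficacy is
bistable (stable states at 0 and 1, barrier at ``rho_star``); with the flat
potential every value in [0, 1] is marginally stable.

Two presets are shipped: ``in_vitro`` (fit to cortical-slice plasticity data at
2.5 mM extracellular calcium) and ``in_vivo`` (same parameters with the calcium
amplitudes scaled by the concentration ratio 1.5/2.5 = 0.6).

Units: calcium amplitudes and efficacies are dimensionless; ``tau_Ca`` and ``D``
are stored in milliseconds at the user boundary and converted to seconds by the
``tau_ca_s`` / ``delay_s`` helpers; ``tau_rho`` is in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum


class Potential(str, Enum):
    """Shape of the bare efficacy potential."""

    FLAT = "flat"
    DOUBLE_WELL = "double_well"


@dataclass(frozen=True)
class PlasticityParams:
    C_pre: float          # calcium jump per presynaptic spike (dimensionless)
    C_post: float         # calcium jump per postsynaptic spike
    tau_Ca: float         # calcium decay time constant (ms)
    D: float              # delay of the presynaptically evoked transient (ms)
    theta_d: float        # depression threshold
    theta_p: float        # potentiation threshold
    gamma_d: float        # depression rate
    gamma_p: float        # potentiation rate
    sigma: float          # activity-gated noise amplitude
    tau_rho: float        # efficacy time constant (s)
    rho_star: float = 0.5  # barrier position of the double well
    potential: Potential = Potential.FLAT

    def __post_init__(self) -> None:
        if not (self.theta_p > self.theta_d > 0):
            raise ValueError("thresholds must satisfy theta_p > theta_d > 0")
        if not (self.gamma_p > self.gamma_d > 0):
            raise ValueError("rates must satisfy gamma_p > gamma_d > 0")
        for name in ("C_pre", "C_post", "tau_Ca", "tau_rho", "D"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0 (zero = noise-free synapse)")
        if not (0.0 < self.rho_star < 1.0):
            raise ValueError("rho_star must lie in (0, 1)")
        # accept plain strings for convenience
        object.__setattr__(self, "potential", Potential(self.potential))

    # -- unit helpers -----------------------------------------------------
    @property
    def tau_ca_s(self) -> float:
        """Calcium decay time constant in seconds."""
        return self.tau_Ca * 1e-3

    @property
    def delay_s(self) -> float:
        """Presynaptic calcium delay in seconds."""
        return self.D * 1e-3

    def with_potential(self, potential: Potential | str) -> "PlasticityParams":
        return replace(self, potential=Potential(potential))

    def with_sigma(self, sigma: float) -> "PlasticityParams":
        return replace(self, sigma=sigma)


#: Parameter set fit to cortical-slice plasticity data (2.5 mM extracellular Ca).
_IN_VITRO = dict(
    C_pre=0.56175,
    C_post=1.23964,
    tau_Ca=22.6936,
    D=4.6098,
    theta_d=1.0,
    theta_p=1.3,
    gamma_d=331.909,
    gamma_p=725.085,
    sigma=3.3501,
    tau_rho=346.3615,
    rho_star=0.5,
)

#: Same model at the estimated physiological calcium level (amplitudes x 0.6).
_IN_VIVO = dict(_IN_VITRO, C_pre=0.33705, C_post=0.74378)

_PRESETS = {"in_vitro": _IN_VITRO, "in_vivo": _IN_VIVO}


def preset(name: str, potential: Potential | str = Potential.FLAT) -> PlasticityParams:
    """Return one of the published parameter sets, ``in_vitro`` or ``in_vivo``."""
    try:
        values = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None
    return PlasticityParams(**values, potential=Potential(potential))


def scale_calcium(p: PlasticityParams, extracellular_ratio: float) -> PlasticityParams:
    """Scale both calcium-transient amplitudes by an extracellular-concentration ratio.

    A proportional relation between extracellular calcium and the influx per
    spike means that changing the bath concentration multiplies ``C_pre`` and
    ``C_post`` by the concentration ratio while leaving every other model
    constant untouched.
    """
    if extracellular_ratio <= 0:
        raise ValueError("extracellular_ratio must be > 0")
    return replace(
        p,
        C_pre=p.C_pre * extracellular_ratio,
        C_post=p.C_post * extracellular_ratio,
    )


@dataclass(frozen=True)
class ExperimentConfig:
    """A single-synapse (ensemble) background-activity experiment.

    Pre- and postsynaptic neurons fire independent Poisson trains at
    ``nu_pre`` / ``nu_post`` spikes per second for ``duration`` seconds.
    """

    nu_pre: float
    nu_post: float
    duration: float
    n_synapses: int = 1
    seed: int = 0
    rho_init: float = 1.0

    def __post_init__(self) -> None:
        if self.nu_pre < 0 or self.nu_post < 0:
            raise ValueError("rates must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.n_synapses < 1:
            raise ValueError("n_synapses must be >= 1")
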