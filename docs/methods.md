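# Methods

## The model

A synapse is described by two variables: the postsynaptic calcium
concentration `c` and the synaptic efficacy `ρ` (dimensionless, nominally in
[0, 1]).

**Calcium** is a shot-noise process: each presynaptic spike adds `C_pre`
(after a delay `D ≈ 4.6 ms` that stands for the slow NMDA-receptor rise),
each postsynaptic spike adds `C_post` immediately, and between spikes the
trace decays exponentially with time constant `τ_Ca ≈ 23 ms`.  Calcium is
dimensionless — the plasticity thresholds set its scale.

**Efficacy** follows calcium-gated drift–diffusion dynamics,

```
τ_ρ dρ = [ −U′(ρ) + γ_p (1−ρ) H(c−θ_p) − γ_d ρ H(c−θ_d) ] dt
         + σ √τ_ρ √( H(c−θ_d) + H(c−θ_p) ) dW ,
```

with `H` the step function.  Above the depression threshold `θ_d` the
efficacy is depressed at rate `γ_d`; above the potentiation threshold
`θ_p > θ_d` it is additionally potentiated at rate `γ_p > γ_d`, so
potentiation wins in the high-calcium region.  The noise is active only when
calcium is above `θ_d` and its variance doubles above `θ_p` (amplitude
`σ√2`), consistent with the effective noise used by the escape-time theory
below.  `U` is either flat (`U ≡ 0`; every efficacy marginally stable) or the
symmetric quartic double well `U(ρ) = ρ²(1−ρ)²/4`, whose minima at 0 and 1
realise synaptic bistability with a barrier at `ρ* = 1/2`.

Two parameter sets ship as presets.  `in_vitro` is the published fit of this
model to cortical-slice plasticity data recorded at 2.5 mM extracellular
calcium.  `in_vivo` is the same set with both calcium amplitudes multiplied
by 1.5/2.5 = 0.6, the estimated ratio of physiological to slice calcium,
under the assumption that influx per spike is proportional to the bath
concentration (`scale_calcium` exposes the rule for other ratios).  The key
structural difference: in vitro a single postsynaptic spike crosses `θ_d`
(`C_post = 1.24 > 1`), in vivo no single spike does — at least two must
nearly coincide within `~τ_Ca`.

## Exact event-based propagation

Between calcium events the calcium trace is a monotone decaying exponential,
so an inter-event interval splits into at most three epochs with closed-form
durations (crossing times `τ_Ca ln(c₀/θ)` clipped to the interval): above
`θ_p`, between the thresholds, below `θ_d`.  During the suprathreshold
epochs the quartic term is negligible against `γ_p, γ_d ≫ 1` and the
efficacy is an exact Ornstein–Uhlenbeck (OU) transition — Gaussian with
closed-form mean and variance (above `θ_p`: target `γ_p/(γ_p+γ_d)`,
relaxation rate `(γ_p+γ_d)/τ_ρ`, noise `σ√2`; between: target 0, rate
`γ_d/τ_ρ`, noise `σ`).  The subthreshold epoch is deterministic: identity for
the flat potential, and for the double well the logistic closed form obtained
from the substitution `u = (ρ−1/2)²`.  The update is therefore exact from
event to event; there is no integration step.  Tests verify each epoch update
against a stiff ODE solution (tolerance 1e-12) and full trajectories against
a 0.001 ms brute-force Euler integration.

Conventions: in flat-potential mode the efficacy is clipped to [0, 1] after
each stochastic epoch (the bounds make the process a truncated OU, and the
asymptote formula below assumes exactly this); in double-well mode the
quartic confines the trajectory and no clipping is applied.  Calcium events
closer than 1e-12 s are merged into one jump of summed amplitude, so
coincident arrivals neither depend on sort order nor consume extra noise
draws.  Ensemble runs give every synapse its own random stream keyed by
(seed, synapse index), so results are independent of execution order.

## Stationary calcium statistics

For independent Poisson pre/post trains the stationary density `p(c)`
satisfies a master equation with two delayed arguments.  Writing
`r_x = ν_x τ_Ca` and `R = r_pre + r_post`, the cumulative form

```
F′(c) = [ R F(c) − r_pre F(c−C_pre) − r_post F(c−C_post) ] / c
```

is integrated forward from the exact branch `F(c) = c^R` (valid below the
smaller amplitude).  Numerical choices that matter:

- `p(c) ~ c^(R−1)` diverges integrably at 0 for `R < 1`; at 1/s most of the
  probability sits below the first grid point.  The object therefore carries
  an explicit near-zero point mass plus a density, and threshold fractions
  are read from the stored cumulative, not from quadrature of the density.
- The density has infinite-slope cusps at every lattice point
  `n·C_pre + m·C_post`.  The grid step is chosen commensurate with both
  amplitudes (the larger amplitude snapped onto the lattice within a relative
  1e-4, via a continued-fraction approximation of the ratio), so every cusp
  falls on a node.
- The cusps still limit the RK4 order to `min(4, 1+R)`; two solves at `h` and
  `h/2` with Richardson extrapolation in that known order recover the lost
  accuracy.  Against the exact equal-amplitude closed form the extrapolated
  fractions agree to ~1e-9; against long Monte-Carlo event simulations they
  agree within statistical error for random parameter draws.
- The pre-spike delay `D` shifts one Poisson stream in time, and a shifted
  Poisson process is Poisson, so stationary statistics ignore it.

For equal amplitudes the first two panels have closed forms
(`p = R c^(R−1)` and a Gauss-hypergeometric correction); beyond `2C` the same
integrator continues from the exact history.  Low-rate expansions derived
from the panel solution give `α ≈ r ln(C/θ)` when one spike suffices and
`α ≈ r² ∫_θ^{2C} ln(C/(c−C)) dc/c` (a dilogarithm) when two are needed; the
exact fractions converge to these as the rate → 0.

A caution on the spike-count heuristic: `k = ceil(θ/C)` assumes the k jumps
arrive before appreciable decay.  If `k·C` only marginally exceeds `θ` the
crossing needs an extra spike in practice — with `C = θ/3` exactly, the
measured low-rate exponent is 4, not 3 — so the three-spike regression test
uses `C = 0.4` (3C = 1.2 clears θ_d = 1 with margin).

## Memory time scales

**Flat potential.**  Averaging the gated dynamics over the stationary calcium
law gives net rates `Γ_p = γ_p α_p`, `Γ_d = γ_d α_d`, where `α_d, α_p` are
the fractions of time above the two thresholds.  The mean efficacy relaxes
exponentially with `τ_eff = τ_ρ / (Γ_p + Γ_d)` towards the mean of a Gaussian
with centre `Γ_p/(Γ_p+Γ_d)` and standard deviation
`σ √(α_d+α_p) / √(2(Γ_p+Γ_d))`, truncated to [0, 1] (evaluated with
`scipy.stats.truncnorm`).  At the published parameters and 1/s this pipeline
gives ~2.6 minutes (in vitro) and ~2.0 hours (in vivo), and an in-vitro
asymptote of ~0.19.  At low rates `α_d ∝ ν^k` with `k` the number of
near-coincident spikes needed to clear `θ_d`, hence the power law
`τ_eff ∝ ν^(−k)`: `k = 1` in vitro, `k = 2` in vivo.

The truncated-OU mean started *at* the bound ρ = 1 is not exactly a single
exponential; with 1000 synapses at 1/s the ensemble mean deviates from the
fitted exponential by up to ~0.03 at mid-times while the fitted time constant
stays within ~6% of `τ_eff`.  Tolerances in the tests (15% on τ, 0.05 on the
plateau, 0.05 on the trajectory) reflect this.

**Double well.**  The same averaging adds two quadratic terms to the bare
potential, `U_eff(ρ) = U(ρ) + Γ_d ρ²/2 + Γ_p (1−ρ)²/2`, and an effective
noise `σ_eff = σ √(α_d+α_p)`.  Depression deepens the DOWN well; as the rate
grows the UP minimum disappears through a saddle-node bifurcation — at
~1.3/s for the in-vivo set (printed as below 1.4/s), and already at ~0.04/s
in vitro, where the larger transients make `Γ_d` grow much faster.  Fixed
points are found by a 2000-point scan of `dU_eff/dρ` on [−0.2, 1.2] plus
bisection.  Below the bifurcation the UP→DOWN memory lifetime is the Kramers
mean first-passage time

```
T = 2π τ_ρ / sqrt( U_eff″(ρ_min) |U_eff″(ρ_saddle)| ) · exp( 2ΔU / σ_eff² ),
```

the standard result for `τ_ρ dρ = −U_eff′ dt + σ_eff √τ_ρ dW`.  At in-vivo
parameters and 1/s this gives ~3.9e6 s — the order of one month.  Direct
validation at that noise level is infeasible (months of model time), so the
implementation is validated in an elevated-noise regime (σ×5), where ~300
simulated first passages land within the factor-3 band of the formula; note
the barrier-to-noise ratio there is ~0.24, at the edge of Kramers validity,
which is why the band is as wide as a factor 3.  A corollary worth knowing:
the *equilibrium* efficacy distribution `∝ exp(−2U_eff/σ_eff²)` at in-vivo
1/s puts weight ~1e-8 on the UP well — the UP state is metastable, not
equilibrium-populated, which is precisely why its escape time is so long.
Inverse-CDF initialisation from that law is therefore effectively the DOWN
state; implant experiments place the tagged fraction at ρ = 1 explicitly.

## The scaled network

The reference system is 8000 excitatory + 2000 inhibitory leaky
integrate-and-fire neurons at connection probability 0.05 with plastic E→E
synapses (weight `J_EE_max·ρ`), simulated for up to two hours.  That is not
reproducible at desk scale, so the shipped network is 800 E + 200 I at
p = 0.2 — the same expected in-degrees (160 E, 40 I) — with an Euler step of
0.1 ms (delay = one step) rather than 0.01 ms.  Runs are minutes of model
time, chosen so each experiment finishes in a few minutes on one core.

Voltage parameters are this package's own defaults, not published values:
`V_L = −70`, `V_th = −50`, `V_r = −60` mV (an intermediate reset), `τ_m = 20`
ms, zero refractory period, external drive `μ_ext = 13.5` mV with white-noise
amplitude `σ_ext = 4` mV, and jumps `J_EE_max = 0.25`, `J_IE = 0.25`,
`J_EI = J_II = −1` mV.  They were chosen once, with the mean-field solver, to
put the network in an inhibition-dominated asynchronous-irregular state near
1 spike/s; every value is config-exposed and no result below depends on the
specific choice, only on mean-field/simulation consistency.

Plasticity in the network is the same exact event engine: postsynaptic
calcium jumps at the spike step, presynaptic jumps `D` later via a ring
buffer (D rounded to 46 steps of 0.1 ms).  The voltage integration is the
only discretised part.  With the synapse noise off, replaying any synapse's
spike trains through the stand-alone engine reproduces the network's
efficacy exactly — the equivalence is a test.

Known discretisation effects: the 0.1 ms Euler threshold crossing biases
single-neuron rates down by ~5–9% relative to the exact transfer function
(the transfer-function unit test uses 0.02 ms, where the bias is ~5%); in the
recurrent loop the biases partially compensate, and the simulated E rate sits
~10% below the mean-field prediction, on the same side as the reference
behaviour.

**Mean field.**  The fixed point solves three coupled equations: the two
population rates through the zero-refractory LIF transfer function
`ν = [τ_m √π ∫_{y_r}^{y_th} erfcx(−u) du]^{−1}` (input mean/variance from the
expected in-degrees, the mean E→E weight `J_EE_max·ρ̄`, and the external
drive), and `ρ̄` through the flat-potential asymptote at `ν_E` assuming
Poisson firing.  Damped fixed-point iteration (factor 0.5) converges to
residual < 1e-8.  The Poisson assumption is the known source of bias: LIF
neurons with a hyperpolarised-side reset produce fewer short inter-spike
intervals than a Poisson process, so calcium transients summate less often
and the realised mean efficacy falls below `ρ̄` (the ISI tests reproduce the
sign flip when the reset is moved toward threshold).

## What the synthetic inputs do and do not emulate

All inputs are seeded homogeneous Poisson trains or the network's own
spikes.  Real background activity is non-Poissonian (refractoriness, rate
fluctuations, correlations), and the theory here is exact only for
independent Poisson drive; the network experiments quantify exactly the
LIF-versus-Poisson part of that gap.  Correlated pre/post trains,
non-stationary rates, renewal-process corrections to the efficacy asymptote,
and nonlinear extracellular-calcium-to-influx mappings are out of scope.

## Degenerate inputs and guards

Zero rates give a calcium point mass at 0, `τ_eff = ∞` and an undefined
asymptote (error).  `σ = 0` is allowed and makes trajectories deterministic
(dwell times below the bifurcation are then infinite, reported as censored).
The equal-amplitude closed form refuses unequal amplitudes and points to the
numeric solver.  Monostable landscapes refuse the Kramers formula and point
to the flat-potential decay time.  The stationary solver rejects grids too
coarse to resolve the smallest jump amplitude.
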