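# Methods

## Model overview

All neurons are rate units with a rectified linear gain
(G(x) = 0.3·x, clipped at zero) and 1 ms time constants, integrated by
forward Euler at dt = 1 ms.  Because dt = τ, each population relaxes to
its input within a step; updates are staged in feedforward order within
a step — layer IV from the current drive, inhibitory units from current
layer IV, excitatory units from current layer IV and inhibition plus the
previous step's recurrent excitation.  A synchronous (previous-step)
scheme was evaluated and rejected: with instantaneous relaxation it
introduces a one-step disinhibition transient at every stimulus onset
(inhibition lags excitation by one step), and the resulting once-per-
cycle plasticity pulses dominate the weight dynamics rather than the
settled rates the rules are designed around.  Steady states are
identical under both schemes.

Ocularity enters only through the layer IV eye weights
w_ipsi = clip(0.30 + 0.35ζ, 0, 1), w_contra = 1 − w_ipsi: every L4 unit
receives the same total drive with a different ocular balance.  Visual
input is a square-wave schedule, 20 ms ON at constant amplitudes
(A^CL = A^IL = 10, background B = 10) and 30 ms OFF; in the network one
of five feature groups is stimulated per cycle (deterministic
round-robin; the presentation order is immaterial because plasticity
only sees settled rates).

## Plasticity rules and their parameters

| parameter | value | role |
|---|---|---|
| θ_H | 26 Hz² | LTP/LTD crossover of the E→E product rule |
| θ_L | 15 Hz² | no-plasticity floor (double-threshold mode) |
| η_EE | 12·10⁻⁵ /step | E→E increment; full weight swing ≈ 170 ON-steps |
| w_EE range | [w_max/2000, 1/50] | hard bounds, no soft bounding |
| η (E→I) | 3.75·10⁻⁷ | BCM-type rule on L4→I synapses |
| ρ_target | 6 Hz (×0.1 after deprivation) | sliding-threshold set point |
| τ_avg | 12.5 s | low-pass for ⟨ρ_post⟩ (the sliding threshold uses ⟨ρ_post⟩²/ρ_target) |
| E→I bounds | [0.2, 1]·(1/50) | see "inhibitory floor" below |
| η (I→E) | 3.75·10⁻⁴ | rate-capping rule |
| φ_H, φ_L | 6·x Hz, φ_H − 0.75 | per-neuron cap; x is the rate-heterogeneity factor |
| heterogeneity x | 1 + 0.1ζ | scales all presynaptic rates of an E neuron and its φ_H |

The three rules interlock: with rates pinned near 6 Hz by the I→E cap,
visually driven products sit at ≈36x² (LTP), background-driven products
at ≈18x² (LTD window), and inactivated products below θ_L.  The BCM
trace is low-passed from the instantaneous inhibitory rate; a
per-stimulus peak detector is an alternative reading of the same
average, indistinguishable here because OFF-period rates are zero.
The trace is initialized at ρ_target, so inhibitory potentiation
engages only as the trace relaxes to the actual activity level — this
is what makes inhibition mature slowly (~10 s) and leaves the
pre-critical-period network (2 s of development) with immature
inhibition.  E→E updates are applied during stimulus-ON steps (during
OFF all rates are zero; under the single-threshold rule un-gated
updates would depress continuously through every OFF period).  E→I and
I→E updates run every step; their increments vanish at zero rates.

## Calibrated quantities

Three numbers are deliberate calibrations rather than direct
prescriptions, fixed once on the mechanism and not tuned per
experiment:

* **Feedforward gain multiplier (network) = 7.5.**  The multiplier
  stands in for a larger input population.  The mature operating point
  is insensitive to it (the I→E cap pins stimulus-driven rates at
  φ_H = 6x), but the immature state is not: the bootstrap product from
  the 0.4·w_max initial same-group weights must exceed θ_H for
  selectivity to develop, and the post-deprivation disinhibited state
  must land in the open-LTP/closed-LTD window.  Both require ≈7.5;
  smaller values leave every operating point 10–25% below threshold and
  development stalls.
* **E→I lower bound = 0.2·w_max.**  The deprived-state BCM equilibrium
  rate is ρ*, where (0.4·ρ*)²/ρ_target,dep = ρ*, i.e. ρ* ≈ 3.75 Hz
  (0.4 is the stimulus ON fraction).  A floor at 0.4·w_max puts the
  floor-imposed inhibitory rate exactly at this fixed point, leaving no
  headroom for the post-drop recovery; a floor at 0.08·w_max drops
  inhibition so deep that every neuron's open-eye pathway is boosted
  into LTP and counter-intuitive shifts disappear.  0.2·w_max yields
  the observed phenomenology: a rapid drop to ~20%, recovery
  predominantly of open-eye-driven inhibition, robust population
  shifts, and a low-rate counter-intuitive subpopulation.
* **Simplified-circuit statics.**  The single-pair circuit's
  feedforward gain (1.6), static E→I weight (0.02) and I→E weight
  (2.0) are set so that the baseline rate is in the LTP regime of all
  afferents, deprivation drops it out of LTP, and the one-third E→I cut
  restores it into the window where deprived-eye products are in LTD
  and open-eye products in LTP.  The E→I cut follows deprivation by
  50 ms (one stimulus cycle): E→I action must be fast relative to the
  ≈0.4 s E→E weight swing, or the open-eye pathway depresses before the
  cut can protect it.

## Measurement conventions

Ocular dominance and selectivity are computed from *probe responses*
(settled rates under constant stimulation with plasticity frozen),
never from weights.  Probes present one eye's visual amplitude without
the background — ocular dominance is defined on visually evoked
responses, and including the background compresses the index range to
±1/3 and hides the monocular tails of the distribution.  Network ODI
probes use the development-end inhibitory weights (the simplified
circuit likewise probes at the un-cut E→I scale): this isolates
feedforward-pathway plasticity from the transient inhibitory state,
which would otherwise imprint a spurious ≈0.05–0.1 index drift on
paradigms that leave the excitatory pathway ocularity-balanced.  The
inhibitory population's own eye-specific responses — the quantity of
interest for the disinhibition transient — are probed with current
weights.  A neuron's "firing rate" for shift/rate analyses is its
development-phase average (its characteristic visually evoked level,
set by φ_H = 6x), normalized to the population mean.  Neurons whose
probe responses are both zero have undefined ODI and are excluded from
population statistics.  A shift counts as such when |ΔODI| > 0.15;
movement toward the deprived eye's pole is "toward-closed"
(counter-intuitive).

## What the synthetic drives do and do not emulate

The generator reproduces the statistical skeleton of the biology —
contralateral bias of thalamocortical ocularity, feature-specific
channels, step-like stimulation, residual (background) retinal drive
through closed lids, TTX silencing — but not natural image statistics,
temporal correlations within/between eyes, conduction delays, spiking
variability, or retinotopy.  Passing tests therefore demonstrate that
the *rule interactions* produce the right qualitative plasticity
phenomenology under controlled drive, not that the model quantitatively
predicts cortical responses to natural vision.

## Numerical choices

Weight updates are hard-clipped to class bounds each step.  Batched
matrix updates are exactly element-wise (verified against scalar
application).  The network inner loop exploits the drive structure:
only the active feature group's afferents carry nonzero rates during
ON, all rates are zero two steps into OFF (recurrence decays with
spectral radius ≈ 0.1/step), and plasticity increments vanish at zero
rates, so OFF-period work reduces to the trace decay.  Connectivity is
enforced by index lists; masked-out synapses are never touched.  Ties
in ocularity ranking (clipped extremes) are broken by stable sort, so
builds are reproducible by seed and iteration-order invariant.
Problem sizes follow the reference conditions throughout: 10 s
simplified runs, 50 s + 50 s network phases, 50-seed deprivation
batteries, and 50-repeat threshold-jitter sweeps (θ_H, θ_L drawn
independently with 5% s.d.).

## Known limitations

* **Simplified circuit, ipsilateral-eye deprivation.**  The
  single-postsynaptic circuit cannot express a contralateral-ward shift
  under MD-IL at any calibration that also produces the MD-CL shift.
  The two deprivations differ structurally: closing the contralateral
  eye removes more drive *and* more feedforward inhibition (the
  inhibitory unit is wired contra-biased, 150/100), so the
  post-reduction rate under MD-IL always sits ≈1.5–2 Hz above the
  MD-CL operating point.  The closed-eye LTD window (rate in ≈(5, 8.7)
  Hz) cannot contain both; equalizing the two operating points requires
  inhibition exceeding the total normal-vision drive, which silences
  the circuit.  MD-IL weights stay pinned at the upper bound and the
  index does not move.  The full network, whose I→E plasticity adapts
  inhibition per neuron, shifts correctly under both deprivations.
* **Simplified circuit, single-threshold rule, long runs.**  Without
  the no-plasticity floor, any post-deprivation steady state eventually
  has all products below θ_H (the surviving open-eye drive cannot hold
  the postsynaptic rate above θ_H/ρ_pre), so all weights reach the
  lower bound and the ODI becomes undefined over a 10 s run.  The
  single-threshold variant is therefore characterized by its
  pre-reduction signature (uniform depression of ~all weights), and the
  double-threshold variant carries the ODI battery.
* **Ipsilaterally dominated neurons lose their closed-eye responses
  under MD-CL.**  Their rates stay near the cap (open-eye drive
  intact), so their few contralateral afferents sit squarely in the LTD
  window and the (small) contralateral response is lost.  The
  initial-ODI dependence this model does reproduce is on the other
  tail: neurons driven almost exclusively by the deprived eye lose
  drive as under BD, freeze below θ_L, and show no shift toward the
  open eye.
* The model covers only the first, response-depression phase of
  deprivation; the later open-eye response potentiation (homeostatic
  in origin) is out of scope, as are spiking dynamics, thalamic and
  layer IV plasticity, and retinotopic structure.
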