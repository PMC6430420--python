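# odplast

Rate-based simulations of ocular dominance (OD) plasticity in visual
cortex layer II/III: why closing one eye during the critical period
shifts cortical responses toward the open eye, why binocular deprivation
and retinal silencing do not, why some neurons shift paradoxically
toward the closed eye, and why the shift disappears before and after the
critical period.

The package is aimed at computational neuroscientists studying cortical
plasticity: it provides the circuit builders, the three interacting
synaptic plasticity rules, the deprivation/stage protocols, and the
measurement conventions (ocular dominance index, input selectivity
index, shift classification) as a library plus a small CLI.

## Model

All units are firing-rate neurons,

```
τ dρᵢ/dt = −ρᵢ + G(Σⱼ wᵢⱼ ρⱼ + driveᵢ),     G(x) = g·x  (g = 0.3, rectified)
```

integrated by forward Euler at dt = τ = 1 ms.  Layer IV neurons carry
stochastic ocular dominance weights w_ipsi = clip(0.30 + 0.35ζ, 0, 1),
w_contra = 1 − w_ipsi, and are driven by step currents
w_contra·A^CL + w_ipsi·A^IL + B in 20 ms ON / 30 ms OFF cycles.

Three plasticity rules act on the four synapse classes:

* **E→E (feedforward and recurrent)** — Hebbian on the rate product
  q = ρ_pre·ρ_post with two thresholds: Δw = +η for q > θ_H (LTP),
  −η for θ_L < q < θ_H (LTD), 0 for q < θ_L (no plasticity);
  θ_H = 26 Hz², θ_L = 15 Hz².  A single-threshold variant
  (Δw = η·sgn(q − θ_H)) is available for comparison.
* **E→I** — a BCM-type rule Δw = η·φ_pre·ρ_post·(ρ_post − θ_BCM) with
  sliding threshold θ_BCM = ⟨ρ_post⟩²/ρ_target.  The presynaptic factor
  is asymmetric: constant (2 Hz) on the depression side — so deprivation
  depresses *all* inhibitory drive — and gated at 3.2 Hz on the
  potentiation side, which lets only visually driven (≈6 Hz), not
  background-driven (≈3 Hz), inputs recover.
* **I→E** — a rate-capping rule (after Vogels et al.):
  Δw = η·ρ_pre·(ρ_post − φ_H) for ρ_post > φ_L = φ_H − 0.75 Hz, else 0;
  it limits excitatory rates near φ_H = 6 Hz but performs no
  homeostatic rescue after deprivation-induced rate drops.

Monocular deprivation (MD) zeroes one eye's visual amplitude and keeps
the background; binocular deprivation (BD) zeroes both; monocular
inactivation (MI, TTX-like) zeroes the contralateral amplitude *and*
the background.  The ocular dominance index is
ODI = (CL − IL)/(CL + IL) on maximum visually evoked responses; input
selectivity is one minus the circular variance of the five
feature-group responses.

Two circuits are provided: a *simplified* circuit (1250 L4 units → one
excitatory + one inhibitory unit, only L4→E plastic, deprivation at
0.5 s followed by a one-third cut of the static E→I weights) and the
*network* (1000 L4 units in five feature groups → 100 E + 20 I units,
all four synapse classes plastic, 50 s development + 50 s deprivation,
with pre-critical-period and adult variants).

## Worked example

```python
from odplast import simplified_battery, EEMode

results = simplified_battery(seed=1, ee_mode=EEMode.DOUBLE)
for kind, r in results.items():
    print(f"{kind.value:6s}  ODI {r.odi_initial:+.3f} -> {r.odi_final:+.3f}")
```

prints

```
md-cl   ODI +0.433 -> -1.000
md-il   ODI +0.433 -> +0.433
bd      ODI +0.433 -> +0.458
mi      ODI +0.433 -> +0.433
none    ODI +0.433 -> +0.433
```

The shared circuit starts contralaterally biased (ODI +0.43).  Closing
the contralateral eye (md-cl) shifts the neuron fully to the open
ipsilateral eye — but only after the E→I cut boosts the postsynaptic
rate so that open-eye products cross θ_H while closed-eye products sit
in the LTD window.  BD and MI leave the index essentially unchanged
(all products move together, or fall below θ_L and freeze).  MD of the
ipsilateral eye leaves this circuit unshifted — a structural limitation
of the single-postsynaptic-neuron circuit discussed in
`docs/methods.md`; the full network does shift under MD-IL.

The same experiment from the shell:

```
odplast battery --model simplified --rule double --seed 1 --out results/
odplast run --model network --deprivation md-cl --stage cp --seed 1 --out results/net
```

Network runs write per-neuron shift records (CSV) and a JSON summary
with the population ODI before/after and counter-intuitive-shifter
counts.

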