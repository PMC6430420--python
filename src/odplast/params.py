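"""Model parameters and run configuration.

All default values correspond to the reference parameter set of the model:
rate units with linear gain g = 0.3 and time constants of 1 ms, a
double-threshold Hebbian rule for excitatory-to-excitatory synapses, a
BCM-type rule with sliding threshold for excitatory-to-inhibitory synapses,
and an inhibitory-to-excitatory rule that caps excitatory firing rates.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum


class Deprivation(str, Enum):
    """Visual deprivation paradigms.

    NONE
        normal binocular vision throughout.
    MD_CL / MD_IL
        monocular deprivation: the contralateral / ipsilateral eye's
        visual drive is set to zero; background drive is kept (residual
        retinal activity through the sutured lid).
    BD
        binocular deprivation: both eyes' visual drives removed,
        background kept.
    MI
        monocular inactivation (TTX-like): contralateral visual drive
        *and* background drive removed.
    """

    NONE = "none"
    MD_CL = "md-cl"
    MD_IL = "md-il"
    BD = "bd"
    MI = "mi"


class Stage(str, Enum):
    """Developmental stage of the simulated animal.

    CP     critical period: full plasticity, standard drives.
    PRE_CP pre-critical-period: short development phase (immature
           inhibition), high background-to-visual drive ratio.
    ADULT  post-critical-period: excitatory-to-inhibitory plasticity is
           frozen during deprivation, low background-to-visual ratio.
    """

    CP = "cp"
    PRE_CP = "pre-cp"
    ADULT = "adult"


class EEMode(str, Enum):
    """Excitatory-to-excitatory rule variant.

    SINGLE  one threshold theta_H separating LTD from LTP.
    DOUBLE  additional lower threshold theta_L below which no
            plasticity occurs.
    """

    SINGLE = "single"
    DOUBLE = "double"


@dataclass
class GainSpec:
    """Linear gain function G(x) = g*x, optionally rectified at zero.

    Rectification is on by default: firing rates are non-negative, and
    net input transiently goes negative under strong inhibition.
    """

    g: float = 0.3
    rectify: bool = True

    def __post_init__(self) -> None:
        if not self.g > 0:
            raise ValueError(f"gain slope must be positive, got {self.g}")


@dataclass
class EEPlasticityParams:
    """Hebbian E-to-E rule on the product q = rho_pre * rho_post.

    double mode: dw = +eta if q > theta_H; -eta if theta_L < q < theta_H;
    0 if q < theta_L.  single mode: dw = eta * sgn(q - theta_H).
    Weights are hard-clipped to [w_min, w_max]; eta is the per-timestep
    increment at dt = 1 ms.
    """

    theta_h: float = 26.0       # Hz^2, LTD/LTP crossover
    theta_l: float = 15.0       # Hz^2, no-plasticity floor (double mode)
    eta: float = 12e-5          # weight increment per 1-ms step
    w_max: float = 1.0 / 50.0   # 1/N_ffw
    w_min: float = (1.0 / 50.0) / 2000.0
    mode: EEMode = EEMode.DOUBLE

    def validate(self) -> None:
        if not 0 <= self.theta_l < self.theta_h:
            raise ValueError(
                f"need 0 <= theta_l < theta_h, got {self.theta_l}, {self.theta_h}")
        if not 0 <= self.w_min < self.w_max:
            raise ValueError(f"need 0 <= w_min < w_max, got {self.w_min}, {self.w_max}")
        if not self.eta > 0:
            raise ValueError("eta must be positive")


@dataclass
class EIPlasticityParams:
    """BCM-type rule for L4 excitatory -> LII/III inhibitory synapses.

    dw = eta * phi_pre * rho_post * (rho_post - theta_BCM), with the
    sliding threshold theta_BCM = <rho_post>^2 / rho_target.  The
    presynaptic factor is asymmetric: on the depression side
    (rho_post <= theta_BCM) phi_pre = 2 Hz regardless of the presynaptic
    rate, so deprivation depresses *all* E-to-I inputs; on the
    potentiation side phi_pre = rho_pre gated at 3.2 Hz, which excludes
    background-driven (3 Hz) inputs from recovery.
    """

    eta: float = 3.75e-7
    phi_pre_dep: float = 2.0     # Hz, depression-side presynaptic factor
    phi_pre_gate: float = 3.2    # Hz, potentiation-side gate
    rho_target: float = 6.0      # Hz; multiplied by 0.1 after deprivation
    target_drop: float = 0.1
    tau_avg: float = 12500.0     # ms, BCM trace time constant
    w_max: float = 1.0 / 50.0
    # E-to-I floor: deep enough below the deprived-state BCM fixed point
    # (~3.75 Hz) that the post-deprivation drop leaves headroom for the
    # open-eye recovery, shallow enough that inhibition does not vanish
    w_min: float = 0.2 / 50.0

    def validate(self) -> None:
        if not self.rho_target > 0:
            raise ValueError("rho_target must be positive")
        if not self.tau_avg > 0:
            raise ValueError("tau_avg must be positive")
        if not self.w_min <= self.w_max:
            raise ValueError("inverted E-to-I bounds")


@dataclass
class IEPlasticityParams:
    """Inhibitory-to-excitatory rule (rate-cap variant of Vogels et al.).

    dw = eta * rho_pre * (rho_post - phi_H) if rho_post > phi_L, else 0.
    With phi_L close below phi_H this caps excitatory rates near phi_H
    but performs no homeostatic rescue after sudden rate drops.
    phi_H is per-neuron (mean 6 Hz, scaled by the heterogeneity factor);
    phi_L = phi_H - 0.75 Hz.  No upper bound on the weight.
    """

    eta: float = 3.75e-4
    phi_h_mean: float = 6.0      # Hz
    phi_gap: float = 0.75        # phi_L = phi_H - phi_gap
    w_min: float = 0.06 / 20.0   # 0.06 / NI_L3

    def validate(self) -> None:
        if not self.phi_gap > 0:
            raise ValueError("phi_L must lie strictly below phi_H")


@dataclass
class DriveParams:
    """Step-current visual drive to layer IV.

    Each 50 ms stimulus cycle is 20 ms ON (constant amplitudes) followed
    by 30 ms OFF (all inputs zero).  During ON, L4 neuron i receives
    w_contra_i * a_cl + w_ipsi_i * a_il + b.  In the network model only
    one feature group is active per cycle.
    """

    a_cl: float = 10.0   # Hz, contralateral-eye amplitude
    a_il: float = 10.0   # Hz, ipsilateral-eye amplitude
    b: float = 10.0      # Hz, background amplitude
    on_ms: int = 20
    off_ms: int = 30

    @property
    def cycle_ms(self) -> int:
        return self.on_ms + self.off_ms

    def validate(self) -> None:
        if min(self.a_cl, self.a_il, self.b) < 0:
            raise ValueError("drive amplitudes must be non-negative")
        if self.on_ms <= 0 or self.off_ms <= 0:
            raise ValueError("on/off durations must be positive")


@dataclass
class SimplifiedParams:
    """Geometry and static weights of the simplified (single postsynaptic
    E + single I) circuit.

    The feedforward gain multiplier and the static E-to-I / I-to-E
    magnitudes are calibrated once so that (i) the baseline excitatory
    rate sits in the LTP regime of all afferents, (ii) after monocular
    deprivation of the contralateral eye the rate falls out of the LTP
    regime, and (iii) the one-third E-to-I reduction restores it into
    the window where deprived-eye products are in LTD while open-eye
    products are in LTP.
    """

    n_l4: int = 1250
    n_ffw: int = 250             # afferents of the excitatory neuron
    n_inh_contra: int = 150      # I afferents: most contralateral ...
    n_inh_ipsi: int = 100        # ... plus most ipsilateral
    ffw_gain: float = 1.6        # feedforward multiplier onto LII/III
    w_ei_static: float = 0.02    # static L4->I weight
    w_ie_static: float = 2.0     # static I->E weight magnitude
    duration_ms: int = 10_000
    deprivation_onset_ms: int = 500
    reduction_delay_ms: int = 50     # E->I cut this long after deprivation
    reduction_factor: float = 1.0 / 3.0


# Table-2-style ocularity allocation: (n_neurons, counts per ocularity
# quintile O1..O5, O1 most contralateral).  Each row sums to 50 synapses;
# the neuron counts sum to 100.
OCULARITY_ALLOCATION: tuple[tuple[int, tuple[int, int, int, int, int]], ...] = (
    (10, (5, 5, 5, 10, 25)),
    (10, (5, 10, 10, 10, 15)),
    (20, (10, 10, 10, 10, 10)),
    (20, (10, 15, 10, 10, 5)),
    (20, (10, 15, 15, 5, 5)),
    (20, (25, 10, 5, 5, 5)),
)


@dataclass
class NetworkParams:
    """Geometry of the full layer II/III network."""

    n_l4: int = 1000
    n_groups: int = 5
    n_exc: int = 100
    n_inh: int = 20
    n_ffw_per_group: int = 50
    ffw_gain: float = 7.5            # "larger input population" multiplier
    same_group_init: float = 0.4     # fraction of w_max
    cross_group_init: float = 0.04   # "ten times smaller"
    rec_init_scale: float = 0.05     # N(mu, sd) with mu = sd = scale*w_max
    w_ie_init: float = 0.06 / 20.0   # I->E start at the lower bound
    inh_contra_per_group: int = 30
    inh_ipsi_per_group: int = 20
    het_sd: float = 0.1              # x = 1 + het_sd * zeta
    phase1_ms: int = 50_000
    phase2_ms: int = 50_000
    precp_phase1_ms: int = 2_000

    @property
    def group_size(self) -> int:
        return self.n_l4 // self.n_groups

    @property
    def exc_group_size(self) -> int:
        return self.n_exc // self.n_groups


@dataclass
class EyemapParams:
    """Stochastic layer-IV ocular dominance weights.

    w_ipsi = clip(mean + sd * zeta, 0, 1) with zeta standard normal;
    w_contra = 1 - w_ipsi, so every L4 neuron receives the same total
    drive with a different ocular balance.
    """

    mean: float = 0.30
    sd: float = 0.35


@dataclass
class ModelParams:
    """Complete parameter bundle for one simulation."""

    dt: float = 1.0              # ms
    tau: float = 1.0             # ms, E and I time constants
    gain: GainSpec = field(default_factory=GainSpec)
    eyemap: EyemapParams = field(default_factory=EyemapParams)
    drive: DriveParams = field(default_factory=DriveParams)
    ee: EEPlasticityParams = field(default_factory=EEPlasticityParams)
    ei: EIPlasticityParams = field(default_factory=EIPlasticityParams)
    ie: IEPlasticityParams = field(default_factory=IEPlasticityParams)
    simplified: SimplifiedParams = field(default_factory=SimplifiedParams)
    network: NetworkParams = field(default_factory=NetworkParams)

    def validate(self) -> None:
        if self.dt <= 0 or self.tau <= 0:
            raise ValueError("dt and tau must be positive")
        self.drive.validate()
        self.ee.validate()
        self.ei.validate()
        self.ie.validate()
        if self.simplified.n_ffw > self.simplified.n_l4:
            raise ValueError("more afferents requested than L4 neurons")
        counts = sum(n for n, _ in OCULARITY_ALLOCATION)
        if counts != self.network.n_exc:
            raise ValueError("ocularity allocation rows must cover all E neurons")
        for n, ys in OCULARITY_ALLOCATION:
            if sum(ys) != self.network.n_ffw_per_group:
                raise ValueError("each allocation row must sum to n_ffw_per_group")


def stage_drive(stage: Stage, base: DriveParams) -> DriveParams:
    """Developmental shift in visual input statistics.

    Pre-CP animals have a higher background-to-visual ratio (background
    15, visual 5); adults the opposite (background 5, visual 15).  The
    total ON-period input to L4 is unchanged (20 Hz-equivalent), so
    baseline rates match across stages.
    """
    if stage is Stage.PRE_CP:
        return dataclasses.replace(base, a_cl=5.0, a_il=5.0, b=15.0)
    if stage is Stage.ADULT:
        return dataclasses.replace(base, a_cl=15.0, a_il=15.0, b=5.0)
    return dataclasses.replace(base)
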