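"""Simulation engines for the simplified circuit and the full network.

The simplified circuit is integrated in plain numpy (one excitatory and
one inhibitory postsynaptic unit); the network delegates its inner loop
to the numba kernel in :mod:`odplast._kernel` and is driven in blocks so
that protocol events (deprivation onset, target-rate drop, probing)
happen between blocks.

Both engines share the measurement convention: ocular dominance and
selectivity are computed from *probe responses* — settled rates under
one-eye-only stimulation with plasticity frozen — never from weights.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import _kernel
from .build import Eyemap, HeterogeneityMap, WeightSet
from .params import Deprivation, DriveParams, EEMode, ModelParams

__all__ = [
    "apply_deprivation", "l4_drive", "l4_rates",
    "SimplifiedSimulator", "NetworkSimulator", "probe_responses",
]


def apply_deprivation(drive: DriveParams, kind: Deprivation) -> DriveParams:
    """Return the drive amplitudes of a deprivation paradigm.

    MD removes one eye's visual amplitude, BD both (background kept),
    MI removes the contralateral amplitude and the background.
    """
    if kind is Deprivation.NONE:
        return dataclasses.replace(drive)
    if kind is Deprivation.MD_CL:
        return dataclasses.replace(drive, a_cl=0.0)
    if kind is Deprivation.MD_IL:
        return dataclasses.replace(drive, a_il=0.0)
    if kind is Deprivation.BD:
        return dataclasses.replace(drive, a_cl=0.0, a_il=0.0)
    if kind is Deprivation.MI:
        return dataclasses.replace(drive, a_cl=0.0, b=0.0)
    raise ValueError(f"unknown deprivation kind: {kind!r}")


def l4_drive(eyemap: Eyemap, drive: DriveParams) -> np.ndarray:
    """ON-period external input to every L4 neuron:
    w_contra*A_CL + w_ipsi*A_IL + B."""
    return eyemap.w_contra * drive.a_cl + eyemap.w_ipsi * drive.a_il + drive.b


def l4_rates(eyemap: Eyemap, drive: DriveParams, g: float = 0.3) -> np.ndarray:
    """Settled ON-period L4 rates (rectified linear gain of the drive)."""
    return np.maximum(g * l4_drive(eyemap, drive), 0.0)


# ---------------------------------------------------------------------------
# simplified circuit
# ---------------------------------------------------------------------------

@dataclass
class SimplifiedState:
    r_e: float = 0.0
    r_i: float = 0.0
    t: int = 0


class SimplifiedSimulator:
    """Single postsynaptic E/I pair driven by 1250 L4 units.

    Only the L4->E weights are plastic.  The E->I weights are static up
    to a scalar ``ei_scale`` that the protocol cuts to one third to
    model the transient reduction of inhibition after deprivation.
    """

    def __init__(self, eyemap: Eyemap, weights: WeightSet, params: ModelParams):
        self.eyemap = eyemap
        self.weights = weights
        self.p = params
        self.state = SimplifiedState()
        self.ei_scale = 1.0
        sp = params.simplified
        self._aff = np.flatnonzero(weights.mask_ffw_e[0])
        self._i_aff = np.flatnonzero(weights.mask_ffw_i[0])
        self._kE = sp.ffw_gain
        self._w_ie = float(weights.w_ie[0, 0])

    def settled_rates(self, drive: DriveParams, w: np.ndarray | None = None,
                      ei_scale: float | None = None) -> tuple[float, float]:
        """Fixed point of the staged feedforward dynamics for constant drive."""
        g = self.p.gain.g
        r4 = l4_rates(self.eyemap, drive, g)
        w = self.weights.w_ffw_e[0] if w is None else w
        scale = self.ei_scale if ei_scale is None else ei_scale
        r_i = max(0.0, g * scale * self.weights.w_ffw_i[0, self._i_aff] @ r4[self._i_aff])
        r_e = max(0.0, g * (self._kE * w[self._aff] @ r4[self._aff]
                            - self._w_ie * r_i))
        return r_e, r_i

    def run(self, duration_ms: int, drive: DriveParams, plastic: bool = True,
            mode: EEMode | None = None) -> None:
        """Advance the circuit; E-to-E plasticity gated to stimulus-ON."""
        p = self.p
        g = p.gain.g
        ee = p.ee
        mode = ee.mode if mode is None else mode
        single = mode is EEMode.SINGLE
        r4_on = l4_rates(self.eyemap, drive, g)
        aff = self._aff
        r4_aff = r4_on[aff]
        i_drive_on = float(self.weights.w_ffw_i[0, self._i_aff] @ r4_on[self._i_aff])
        w = self.weights.w_ffw_e[0]
        st = self.state
        on_ms, cycle = p.drive.on_ms, p.drive.cycle_ms
        for _ in range(duration_ms):
            on = (st.t % cycle) < on_ms
            if on:
                r_i = max(0.0, g * self.ei_scale * i_drive_on)
                r_e = max(0.0, g * (self._kE * w[aff] @ r4_aff - self._w_ie * r_i))
                if plastic:
                    q = r4_aff * r_e
                    dw = ee.eta * np.sign(q - ee.theta_h)
                    if not single:
                        dw = np.where(q > ee.theta_l, dw, 0.0)
                    w[aff] = np.clip(w[aff] + dw, ee.w_min, ee.w_max)
            else:
                r_i = 0.0
                r_e = 0.0
            st.r_e, st.r_i = r_e, r_i
            st.t += 1

    def probe(self, baseline_ei: bool = True) -> tuple[float, float]:
        """Maximum responses to CL-only and IL-only visual stimulation.

        Probes present one eye's visual amplitude alone (no background:
        ocular dominance is defined on visually evoked responses) and,
        by default, use the baseline (unreduced) E->I scale so
        before/after comparisons reflect feedforward weight changes.
        """
        d = self.p.drive
        scale = 1.0 if baseline_ei else self.ei_scale
        cl, _ = self.settled_rates(dataclasses.replace(d, a_il=0.0, b=0.0),
                                   ei_scale=scale)
        il, _ = self.settled_rates(dataclasses.replace(d, a_cl=0.0, b=0.0),
                                   ei_scale=scale)
        return cl, il


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

class NetworkSimulator:
    """Five-feature-group LII/III network with all four plastic classes."""

    def __init__(self, eyemap: Eyemap, weights: WeightSet,
                 het: HeterogeneityMap, params: ModelParams):
        self.eyemap = eyemap
        self.weights = weights
        self.het = het
        self.p = params
        np_ = params.network
        self.r_e = np.zeros(np_.n_exc)
        self.r_i = np.zeros(np_.n_inh)
        # the sliding threshold starts at the homeostatic set point, so
        # inhibitory potentiation engages only as the trace relaxes to
        # the actual activity level (slow inhibitory maturation)
        self.trace = np.full(np_.n_inh, params.ei.rho_target)
        self.t = 0
        self.rate_accum = np.zeros(np_.n_exc)
        self.rate_steps = 0
        gsz = np_.group_size
        self._idx_e = self._local_indices(weights.mask_ffw_e, np_.n_groups, gsz)
        self._idx_i = self._local_indices(weights.mask_ffw_i, np_.n_groups, gsz)
        self.phi_h = het.phi_h.copy()
        self.phi_l = self.phi_h - params.ie.phi_gap

    @staticmethod
    def _local_indices(mask: np.ndarray, n_groups: int, gsz: int) -> np.ndarray:
        n = mask.shape[0]
        counts = {int(mask[k, g * gsz:(g + 1) * gsz].sum())
                  for k in range(n) for g in range(n_groups)}
        (n_syn,) = counts  # identical per-group in-degree by construction
        idx = np.empty((n, n_groups, n_syn), dtype=np.int64)
        for k in range(n):
            for g in range(n_groups):
                idx[k, g] = np.flatnonzero(mask[k, g * gsz:(g + 1) * gsz])
        return idx

    def l4_by_group(self, drive: DriveParams) -> np.ndarray:
        """Settled ON-period L4 rates, one row per feature group."""
        rates = l4_rates(self.eyemap, drive, self.p.gain.g)
        return rates.reshape(self.p.network.n_groups, -1)

    def run(self, duration_ms: int, drive: DriveParams, rho_target: float,
            plastic_ee: bool = True, plastic_ei: bool = True,
            plastic_ie: bool = True) -> None:
        """Advance the network by ``duration_ms`` 1-ms steps."""
        p = self.p
        w = self.weights
        ee, ei, ie = p.ee, p.ei, p.ie
        _kernel.run_block(
            self.t, duration_ms,
            w.w_ffw_e, w.w_ffw_i, w.w_rec_ee, w.w_ie,
            self._idx_e, self._idx_i,
            self.l4_by_group(drive),
            self.het.x, self.phi_h, self.phi_l,
            self.trace, self.r_e, self.r_i,
            self.rate_accum,
            p.gain.g, p.network.ffw_gain,
            ee.eta, ee.theta_h, ee.theta_l, ee.w_min, ee.w_max,
            ee.mode is EEMode.SINGLE,
            ei.eta, ei.phi_pre_gate, ei.phi_pre_dep, rho_target, ei.tau_avg,
            ei.w_min, ei.w_max,
            ie.eta, ie.w_min,
            p.drive.on_ms, p.drive.cycle_ms, p.network.n_groups,
            plastic_ee and w.plastic["ffw_e"],
            plastic_ei and w.plastic["ffw_i"],
            plastic_ie and w.plastic["ie"],
        )
        self.t += duration_ms
        self.rate_steps += duration_ms

    def mean_rates(self, reset: bool = False) -> np.ndarray:
        """Per-neuron excitatory rate averaged over the accumulated steps."""
        out = self.rate_accum / max(self.rate_steps, 1)
        if reset:
            self.rate_accum = np.zeros_like(self.rate_accum)
            self.rate_steps = 0
        return out

    def _settled_presentation(self, drive: DriveParams, group: int,
                              n_iter: int = 40,
                              inhibition: tuple[np.ndarray, np.ndarray] | None = None,
                              ) -> tuple[np.ndarray, np.ndarray]:
        """Settled (rE, rI) for one feature group under constant drive.

        ``inhibition`` substitutes (w_ffw_i, w_ie) matrices, letting
        probes measure the feedforward excitatory pathway under a fixed
        inhibitory configuration.
        """
        p = self.p
        g = p.gain.g
        kE = p.network.ffw_gain
        gsz = p.network.group_size
        sl = slice(group * gsz, (group + 1) * gsz)
        l4 = l4_rates(self.eyemap, drive, g)[sl]
        w = self.weights
        w_ffw_i, w_ie = ((w.w_ffw_i, w.w_ie) if inhibition is None else inhibition)
        r_i = np.maximum(0.0, g * kE * (w_ffw_i[:, sl] @ l4))
        r_e = np.zeros_like(self.r_e)
        for _ in range(n_iter):
            exc = kE * (w.w_ffw_e[:, sl] @ l4) + w.w_rec_ee @ r_e
            r_e = np.maximum(0.0, g * self.het.x * (exc - w_ie @ r_i))
        return r_e, r_i

    def probe(self, drive: DriveParams,
              inhibition: tuple[np.ndarray, np.ndarray] | None = None,
              ) -> dict[str, np.ndarray]:
        """Frozen-plasticity probe battery.

        Presents every feature group under contralateral-only and
        ipsilateral-only visual drive (no background) and under the full
        binocular drive, and records settled rates.  Returns per-neuron maximum responses per
        eye, per-feature binocular responses, and the same for the
        inhibitory population.  Network state is untouched (the probe
        computes fixed points without advancing the simulator).
        """
        n_groups = self.p.network.n_groups
        out_e = {"cl": [], "il": [], "feat": []}
        out_i = {"cl": [], "il": []}
        cl_drive = dataclasses.replace(drive, a_il=0.0, b=0.0)
        il_drive = dataclasses.replace(drive, a_cl=0.0, b=0.0)
        for grp in range(n_groups):
            e_cl, i_cl = self._settled_presentation(cl_drive, grp,
                                                    inhibition=inhibition)
            e_il, i_il = self._settled_presentation(il_drive, grp,
                                                    inhibition=inhibition)
            e_bi, _ = self._settled_presentation(drive, grp,
                                                 inhibition=inhibition)
            out_e["cl"].append(e_cl)
            out_e["il"].append(e_il)
            out_e["feat"].append(e_bi)
            out_i["cl"].append(i_cl)
            out_i["il"].append(i_il)
        return {
            "resp_cl": np.max(out_e["cl"], axis=0),
            "resp_il": np.max(out_e["il"], axis=0),
            "features": np.stack(out_e["feat"], axis=0),       # (groups, nE)
            "resp_cl_inh": np.max(out_i["cl"], axis=0),
            "resp_il_inh": np.max(out_i["il"], axis=0),
        }


def probe_responses(sim, drive: DriveParams | None = None):
    """Probe a simulator with plasticity frozen (measurement protocol).

    For the simplified circuit returns ``(resp_cl, resp_il)``; for the
    network a dict of per-neuron response arrays.
    """
    if isinstance(sim, SimplifiedSimulator):
        return sim.probe()
    if isinstance(sim, NetworkSimulator):
        return sim.probe(drive if drive is not None else sim.p.drive)
    raise TypeError(f"cannot probe {type(sim).__name__}")
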