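"""Experimental protocols: deprivation paradigms and developmental stages.

Simplified battery
    10 s runs at 1 ms steps.  Deprivation starts at 500 ms; the
    feedforward E-to-I weights are cut to one third of their initial
    value shortly afterwards (default 50 ms), modelling the observed
    transient reduction of inhibition.  Ocular dominance is probed at
    the start, at the moment of the E-to-I cut, and at the end.

Network protocol
    Phase 1 (development, 50 s): all plasticity on, inhibitory target
    rate 6 Hz; feedforward and recurrent excitation become feature-
    selective while E-to-I connections saturate unselectively.
    Phase 2 (deprivation, 50 s): drive amplitudes per paradigm, target
    rate dropped to 10%.  Stage variants: pre-CP shortens phase 1 to
    2 s and uses background-heavy drives; adult freezes E-to-I
    plasticity during deprivation and uses visual-heavy drives.
"""
from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .build import build_network, build_simplified
from .metrics import ShiftClass, ShiftRecord, classify_shift, compute_odi, compute_si
from .params import Deprivation, DriveParams, EEMode, ModelParams, Stage, stage_drive
from .simulate import NetworkSimulator, SimplifiedSimulator, apply_deprivation

__all__ = [
    "ProtocolSpec", "SimplifiedResult", "NetworkResult",
    "run_simplified", "simplified_battery",
    "develop_network", "run_deprivation", "run_network", "network_battery",
    "jitter_thresholds",
]


@dataclass
class ProtocolSpec:
    """What to simulate: model variant, rule mode, paradigm, stage."""

    deprivation: Deprivation = Deprivation.MD_CL
    stage: Stage = Stage.CP
    ee_mode: EEMode = EEMode.DOUBLE
    seed: int = 1


# ---------------------------------------------------------------------------
# simplified model
# ---------------------------------------------------------------------------

@dataclass
class SimplifiedResult:
    spec: ProtocolSpec
    odi_initial: float
    odi_at_reduction: float
    odi_final: float
    w_initial: np.ndarray
    w_at_reduction: np.ndarray
    w_final: np.ndarray
    afferent_ipsi: np.ndarray          # w_ipsi of the 250 afferents
    rate_trace: np.ndarray             # settled ON-period rE, one per cycle

    @property
    def odi_shift(self) -> float:
        return self.odi_final - self.odi_initial


def run_simplified(spec: ProtocolSpec, params: ModelParams | None = None
                   ) -> SimplifiedResult:
    """Run one 10 s simplified-model experiment."""
    p = params or ModelParams()
    sp = p.simplified
    eyemap, weights = build_simplified(spec.seed, p)
    sim = SimplifiedSimulator(eyemap, weights, p)

    base = p.drive
    dep = apply_deprivation(base, spec.deprivation)
    t_dep = sp.deprivation_onset_ms
    t_red = t_dep + sp.reduction_delay_ms
    t_end = sp.duration_ms
    w = weights.w_ffw_e[0]
    aff = np.flatnonzero(weights.mask_ffw_e[0])

    w_initial = w[aff].copy()
    odi_initial = compute_odi(*sim.probe())
    rates = []

    def run_span(t_from: int, t_to: int, drive: DriveParams) -> None:
        # advance cycle by cycle so the settled ON rate can be recorded
        cycle = p.drive.cycle_ms
        t = t_from
        while t < t_to:
            span = min(cycle - (t % cycle) or cycle, t_to - t)
            sim.run(span, drive, plastic=True, mode=spec.ee_mode)
            t += span
            if t % cycle == 0 or t == t_to:
                rates.append(sim.settled_rates(drive)[0])

    run_span(0, t_dep, base)
    if spec.deprivation is Deprivation.NONE:
        run_span(t_dep, t_end, base)
        w_at_red = w[aff].copy()
        odi_at_red = odi_initial
    else:
        run_span(t_dep, t_red, dep)
        w_at_red = w[aff].copy()
        odi_at_red = compute_odi(*sim.probe())
        sim.ei_scale = sp.reduction_factor
        run_span(t_red, t_end, dep)

    return SimplifiedResult(
        spec=spec,
        odi_initial=odi_initial,
        odi_at_reduction=odi_at_red,
        odi_final=compute_odi(*sim.probe()),
        w_initial=w_initial,
        w_at_reduction=w_at_red,
        w_final=w[aff].copy(),
        afferent_ipsi=eyemap.w_ipsi[aff].copy(),
        rate_trace=np.asarray(rates),
    )


def simplified_battery(seed: int = 1, ee_mode: EEMode = EEMode.DOUBLE,
                       params: ModelParams | None = None
                       ) -> dict[Deprivation, SimplifiedResult]:
    """All four deprivations (plus control) with one shared instantiation."""
    out = {}
    for kind in (Deprivation.MD_CL, Deprivation.MD_IL, Deprivation.BD,
                 Deprivation.MI, Deprivation.NONE):
        out[kind] = run_simplified(
            ProtocolSpec(deprivation=kind, ee_mode=ee_mode, seed=seed), params)
    return out


# ---------------------------------------------------------------------------
# network model
# ---------------------------------------------------------------------------

@dataclass
class NetworkResult:
    spec: ProtocolSpec
    records: list[ShiftRecord]
    odi_before: np.ndarray
    odi_after: np.ndarray
    mean_rate_norm: np.ndarray          # phase-2 mean rate / population mean
    si_exc_before: np.ndarray
    si_inh_trace: np.ndarray | None = None
    inh_probe_times: np.ndarray | None = None
    inh_probe_cl: np.ndarray | None = None   # I population CL response over phase 2
    inh_probe_il: np.ndarray | None = None
    resp_cl_before: np.ndarray | None = None
    resp_cl_after: np.ndarray | None = None
    resp_il_before: np.ndarray | None = None
    resp_il_after: np.ndarray | None = None

    @property
    def population_shift(self) -> float:
        good = ~(np.isnan(self.odi_before) | np.isnan(self.odi_after))
        return float(np.mean(self.odi_after[good] - self.odi_before[good]))


@dataclass
class DevelopedNetwork:
    """Snapshot of a network at the end of the development phase."""

    sim: NetworkSimulator
    spec_stage: Stage
    drive: DriveParams
    si_exc_trace: np.ndarray
    si_inh_trace: np.ndarray
    rate_norm: np.ndarray | None = None   # development-phase mean rate / pop mean

    def clone_sim(self) -> NetworkSimulator:
        sim = self.sim
        new = NetworkSimulator(sim.eyemap, sim.weights.copy(), sim.het, sim.p)
        new.r_e = sim.r_e.copy()
        new.r_i = sim.r_i.copy()
        new.trace = sim.trace.copy()
        new.t = sim.t
        return new


def develop_network(seed: int, stage: Stage = Stage.CP,
                    params: ModelParams | None = None,
                    si_checkpoints: int = 6) -> DevelopedNetwork:
    """Phase 1: run development under normal binocular vision."""
    p = params or ModelParams()
    eyemap, weights, het = build_network(seed, p)
    sim = NetworkSimulator(eyemap, weights, het, p)
    drive = stage_drive(stage, p.drive)
    dur = (p.network.precp_phase1_ms if stage is Stage.PRE_CP
           else p.network.phase1_ms)
    si_e, si_i = [], []

    def snapshot_si() -> None:
        probe = sim.probe(drive)
        feats_e = probe["features"]                      # (groups, nE)
        si_e.append(np.nanmean([compute_si(feats_e[:, k])
                                for k in range(feats_e.shape[1])]))
        feats_i = np.stack([sim._settled_presentation(drive, g)[1]
                            for g in range(p.network.n_groups)])
        si_i.append(np.nanmean([compute_si(feats_i[:, i])
                                for i in range(feats_i.shape[1])]))

    snapshot_si()
    block = max(dur // si_checkpoints, 1)
    done = 0
    while done < dur:
        span = min(block, dur - done)
        sim.run(span, drive, rho_target=p.ei.rho_target)
        done += span
        snapshot_si()
    dev_rates = sim.mean_rates(reset=True)
    pop = dev_rates.mean()
    return DevelopedNetwork(sim=sim, spec_stage=stage, drive=drive,
                            si_exc_trace=np.asarray(si_e),
                            si_inh_trace=np.asarray(si_i),
                            rate_norm=dev_rates / pop if pop > 0 else dev_rates)


def run_deprivation(dev: DevelopedNetwork, kind: Deprivation,
                    probe_every_ms: int | None = None) -> NetworkResult:
    """Phase 2: apply a deprivation paradigm to a developed network.

    The inhibitory target rate drops to 10% of its normal-vision value
    for every paradigm; adult networks additionally freeze E-to-I
    plasticity.
    """
    sim = dev.clone_sim()
    p = sim.p
    stage = dev.spec_stage
    dep_drive = apply_deprivation(dev.drive, kind)
    rho_target = p.ei.rho_target * (1.0 if kind is Deprivation.NONE
                                    else p.ei.target_drop)
    plast_ei = stage is not Stage.ADULT
    # ODI probes measure the feedforward excitatory pathway under the
    # development-end inhibitory configuration; the transient inhibitory
    # state is reported separately (inh_probe_* use current weights)
    inh_ref = (sim.weights.w_ffw_i.copy(), sim.weights.w_ie.copy())

    before = sim.probe(dev.drive, inhibition=inh_ref)
    odi_before = compute_odi(before["resp_cl"], before["resp_il"])
    si_before = np.array([compute_si(before["features"][:, k])
                          for k in range(p.network.n_exc)])

    times, icl, iil = [], [], []
    dur = p.network.phase2_ms
    block = probe_every_ms or dur
    done = 0
    while done < dur:
        span = min(block, dur - done)
        sim.run(span, dep_drive, rho_target=rho_target, plastic_ei=plast_ei)
        done += span
        if probe_every_ms:
            pr = sim.probe(dev.drive)
            times.append(done)
            icl.append(pr["resp_cl_inh"].mean())
            iil.append(pr["resp_il_inh"].mean())

    after = sim.probe(dev.drive, inhibition=inh_ref)
    odi_after = compute_odi(after["resp_cl"], after["resp_il"])
    # a neuron's characteristic rate is its development-phase average
    # (the I->E cap pins stimulus-driven rates at phi_H = 6x, so this is
    # the heterogeneity-determined visually evoked activity level)
    rate_norm = dev.rate_norm if dev.rate_norm is not None else sim.mean_rates()

    records = [
        ShiftRecord(
            neuron=k,
            odi_before=float(odi_before[k]),
            odi_after=float(odi_after[k]),
            mean_rate=float(rate_norm[k]),
            shift_class=classify_shift(float(odi_before[k]),
                                       float(odi_after[k]), kind),
        )
        for k in range(p.network.n_exc)
    ]
    spec = ProtocolSpec(deprivation=kind, stage=stage, seed=-1)
    return NetworkResult(
        spec=spec, records=records,
        odi_before=odi_before, odi_after=odi_after,
        mean_rate_norm=rate_norm,
        si_exc_before=si_before,
        si_inh_trace=dev.si_inh_trace,
        inh_probe_times=np.asarray(times) if times else None,
        inh_probe_cl=np.asarray(icl) if icl else None,
        inh_probe_il=np.asarray(iil) if iil else None,
        resp_cl_before=before["resp_cl"], resp_cl_after=after["resp_cl"],
        resp_il_before=before["resp_il"], resp_il_after=after["resp_il"],
    )


def run_network(spec: ProtocolSpec, params: ModelParams | None = None,
                probe_every_ms: int | None = None) -> NetworkResult:
    """Develop then deprive: the full two-phase network experiment."""
    dev = develop_network(spec.seed, spec.stage, params)
    res = run_deprivation(dev, spec.deprivation, probe_every_ms)
    res.spec = dataclasses.replace(res.spec, seed=spec.seed,
                                   ee_mode=spec.ee_mode)
    return res


def network_battery(seed: int, stage: Stage = Stage.CP,
                    params: ModelParams | None = None,
                    kinds: tuple[Deprivation, ...] = (
                        Deprivation.MD_CL, Deprivation.MD_IL,
                        Deprivation.BD, Deprivation.MI),
                    ) -> dict[Deprivation, NetworkResult]:
    """One development phase shared across all deprivation paradigms."""
    dev = develop_network(seed, stage, params)
    out = {}
    for kind in kinds:
        res = run_deprivation(dev, kind)
        res.spec = dataclasses.replace(res.spec, seed=seed)
        out[kind] = res
    return out


def jitter_thresholds(seed: int, n_repeats: int = 50, jitter_sd: float = 0.05,
                      params: ModelParams | None = None,
                      kinds: tuple[Deprivation, ...] = (
                          Deprivation.MD_CL, Deprivation.MD_IL,
                          Deprivation.BD, Deprivation.MI),
                      ) -> dict[Deprivation, np.ndarray]:
    """Robustness sweep: population ODI shift under jittered thresholds.

    Each repeat draws theta_H and theta_L independently from normals
    centred on their defaults with sd = 5% of the default, then runs the
    full two-phase network protocol for every paradigm.
    """
    if n_repeats < 1:
        raise ValueError("need at least one repeat")
    base = params or ModelParams()
    rng = np.random.default_rng(seed)
    shifts: dict[Deprivation, list[float]] = {k: [] for k in kinds}
    for rep in range(n_repeats):
        p = copy.deepcopy(base)
        if jitter_sd > 0:
            p.ee.theta_h = float(rng.normal(base.ee.theta_h,
                                            jitter_sd * base.ee.theta_h))
            p.ee.theta_l = float(rng.normal(base.ee.theta_l,
                                            jitter_sd * base.ee.theta_l))
        rep_seed = int(rng.integers(0, 2**31 - 1))
        results = network_battery(rep_seed, params=p, kinds=kinds)
        for kind in kinds:
            shifts[kind].append(results[kind].population_shift)
    return {k: np.asarray(v) for k, v in shifts.items()}
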