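"""Numba inner loop for the network simulation.

One kernel call advances the network through a contiguous block of 1-ms
steps with fixed drive amplitudes, plasticity flags and BCM target rate;
phase orchestration (deprivation onset, probing, stage gating) happens
in Python between calls.  The update order within a step is feedforward-
staged: L4 rates from the current drive, inhibitory rates from current
L4, excitatory rates from current L4 and I plus previous-step recurrent
excitation.  E-to-E plasticity is gated to stimulus-ON steps; E-to-I and
I-to-E run every step (their increments vanish when rates are zero).
"""
from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_block"]


@njit(cache=True)
def run_block(t0, n_steps,                       # absolute step offset, block length
              w_ffw_e, w_ffw_i, w_rec, w_ie,     # weight matrices (in-place)
              idx_e, idx_i,                      # (nE,5,50), (nI,5,50) local indices
              l4_by_group,                       # (5, group_size) ON-period L4 rates
              x, phi_h, phi_l,                   # heterogeneity, I->E thresholds
              trace, r_e, r_i,                   # state (in-place)
              rate_accum,                        # (nE,) accumulated rE (in-place)
              g, ffw_gain,
              eta_ee, th_h, th_l, ee_min, ee_max, ee_single,
              eta_ei, phi_gate, phi_dep, rho_target, tau_avg, ei_min, ei_max,
              eta_ie, ie_min,
              on_ms, cycle_ms, n_groups,
              plast_ee, plast_ei, plast_ie):
    n_e = r_e.shape[0]
    n_i = r_i.shape[0]
    n_syn = idx_e.shape[2]
    gsz = l4_by_group.shape[1]
    r_e_new = np.empty(n_e)
    r_i_new = np.empty(n_i)
    decay = 1.0 - 1.0 / tau_avg

    for s in range(n_steps):
        t = t0 + s
        on = (t % cycle_ms) < on_ms
        grp = (t // cycle_ms) % n_groups
        base = grp * gsz

        if on:
            l4a = l4_by_group[grp]
            for i in range(n_i):
                acc = 0.0
                for c in range(n_syn):
                    j = idx_i[i, grp, c]
                    acc += w_ffw_i[i, base + j] * l4a[j]
                v = g * ffw_gain * acc
                r_i_new[i] = v if v > 0.0 else 0.0
            for k in range(n_e):
                acc = 0.0
                for c in range(n_syn):
                    j = idx_e[k, grp, c]
                    acc += w_ffw_e[k, base + j] * l4a[j]
                acc *= ffw_gain
                for j2 in range(n_e):
                    acc += w_rec[k, j2] * r_e[j2]
                inh = 0.0
                for i in range(n_i):
                    inh += w_ie[k, i] * r_i_new[i]
                v = g * x[k] * (acc - inh)
                r_e_new[k] = v if v > 0.0 else 0.0
        else:
            for i in range(n_i):
                r_i_new[i] = 0.0
            live = False
            for k in range(n_e):
                if r_e[k] > 1e-12:
                    live = True
                    break
            if live:
                for k in range(n_e):
                    acc = 0.0
                    for j2 in range(n_e):
                        acc += w_rec[k, j2] * r_e[j2]
                    v = g * x[k] * acc
                    r_e_new[k] = v if v > 0.0 else 0.0
            else:
                for k in range(n_e):
                    r_e_new[k] = 0.0

        for i in range(n_i):
            trace[i] = trace[i] * decay + r_i_new[i] / tau_avg

        if plast_ee and on:
            for k in range(n_e):
                a = x[k] * r_e_new[k]
                if a > 0.0:
                    for c in range(n_syn):
                        j = idx_e[k, grp, c]
                        q = a * l4_by_group[grp, j]
                        if q > th_h:
                            w = w_ffw_e[k, base + j] + eta_ee
                            w_ffw_e[k, base + j] = w if w < ee_max else ee_max
                        elif q < th_h and (q > th_l or ee_single):
                            w = w_ffw_e[k, base + j] - eta_ee
                            w_ffw_e[k, base + j] = w if w > ee_min else ee_min
                    for j2 in range(n_e):
                        if j2 != k:
                            q = a * r_e_new[j2]
                            if q > th_h:
                                w = w_rec[k, j2] + eta_ee
                                w_rec[k, j2] = w if w < ee_max else ee_max
                            elif q < th_h and (q > th_l or ee_single):
                                w = w_rec[k, j2] - eta_ee
                                w_rec[k, j2] = w if w > ee_min else ee_min

        if plast_ei:
            for i in range(n_i):
                if r_i_new[i] <= 0.0 and trace[i] <= 0.0:
                    continue
                theta = trace[i] * trace[i] / rho_target
                post = r_i_new[i]
                if post > theta:
                    if on:
                        drive_fac = eta_ei * post * (post - theta)
                        for c in range(n_syn):
                            j = idx_i[i, grp, c]
                            pre = l4_by_group[grp, j]
                            if pre > phi_gate:
                                w = w_ffw_i[i, base + j] + drive_fac * pre
                                w_ffw_i[i, base + j] = w if w < ei_max else ei_max
                elif post > 0.0:
                    dw = eta_ei * phi_dep * post * (post - theta)
                    for gg in range(n_groups):
                        b2 = gg * gsz
                        for c in range(n_syn):
                            j = idx_i[i, gg, c]
                            w = w_ffw_i[i, b2 + j] + dw
                            w_ffw_i[i, b2 + j] = w if w > ei_min else ei_min

        if plast_ie:
            for k in range(n_e):
                if r_e_new[k] > phi_l[k]:
                    d = eta_ie * x[k] * (r_e_new[k] - phi_h[k])
                    for i in range(n_i):
                        if r_i_new[i] > 0.0:
                            w = w_ie[k, i] + d * r_i_new[i]
                            w_ie[k, i] = w if w > ie_min else ie_min

        for k in range(n_e):
            r_e[k] = r_e_new[k]
            rate_accum[k] += r_e_new[k]
        for i in range(n_i):
            r_i[i] = r_i_new[i]
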