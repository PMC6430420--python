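"""The three synaptic plasticity rules.

Every rule is written element-wise over numpy arrays; scalar and batched
application are the same code path, so batched updates are exactly
equivalent to per-synapse application.  All rules hard-clip to the
weight bounds of their synapse class; there is no soft bounding.
"""
from __future__ import annotations

import numpy as np

from .params import EEMode, EEPlasticityParams, EIPlasticityParams, IEPlasticityParams

__all__ = ["clip_to_bounds", "ee_update", "ei_update", "ie_update", "bcm_threshold"]


def clip_to_bounds(w, w_min: float, w_max: float):
    """Hard lower and upper weight bounds."""
    if w_min > w_max:
        raise ValueError(f"inverted bounds: w_min={w_min} > w_max={w_max}")
    return np.clip(w, w_min, w_max)


def ee_update(w, rho_pre, rho_post, p: EEPlasticityParams):
    """Hebbian E-to-E update driven by the rate product q = pre * post.

    Double-threshold mode: q above theta_H potentiates by +eta, q
    between theta_L and theta_H depresses by -eta, q below theta_L
    leaves the weight untouched (no-plasticity region).  Single-
    threshold mode: dw = eta * sgn(q - theta_H), so any sub-threshold
    activity depresses.  The increment is weight-independent; the
    result is clipped to the class bounds.
    """
    rho_pre = np.asarray(rho_pre, dtype=float)
    rho_post = np.asarray(rho_post, dtype=float)
    if np.any(rho_pre < 0) or np.any(rho_post < 0):
        raise ValueError("negative firing rate")
    q = rho_pre * rho_post
    dw = p.eta * np.sign(q - p.theta_h)
    if p.mode is EEMode.DOUBLE:
        dw = np.where(q > p.theta_l, dw, 0.0)
    out = clip_to_bounds(np.asarray(w, dtype=float) + dw, p.w_min, p.w_max)
    return out if out.ndim else float(out)


def bcm_threshold(trace, rho_target: float):
    """Sliding threshold theta_BCM = <rho_post>^2 / rho_target."""
    if rho_target <= 0:
        raise ValueError("rho_target must be positive")
    return np.asarray(trace, dtype=float) ** 2 / rho_target


def ei_update(w, rho_pre, rho_post, trace, p: EIPlasticityParams,
              rho_target: float | None = None):
    """BCM-type E-to-I update with asymmetric presynaptic factor.

    dw = eta * phi_pre * rho_post * (rho_post - theta_BCM) where
    theta_BCM = trace^2 / rho_target.  On the potentiation side
    (rho_post > theta_BCM) phi_pre = rho_pre if rho_pre > 3.2 Hz else 0;
    on the depression side phi_pre = 2 Hz independent of the presynaptic
    rate, so silenced inputs are depressed too.
    """
    rho_pre = np.asarray(rho_pre, dtype=float)
    rho_post = np.asarray(rho_post, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if np.any(trace < 0):
        raise ValueError("negative BCM trace")
    theta = bcm_threshold(trace, p.rho_target if rho_target is None else rho_target)
    pot = rho_post > theta
    phi_pre = np.where(pot,
                       np.where(rho_pre > p.phi_pre_gate, rho_pre, 0.0),
                       p.phi_pre_dep)
    dw = p.eta * phi_pre * rho_post * (rho_post - theta)
    out = clip_to_bounds(np.asarray(w, dtype=float) + dw, p.w_min, p.w_max)
    return out if out.ndim else float(out)


def ie_update(w, rho_pre, rho_post, p: IEPlasticityParams,
              phi_h: float | np.ndarray | None = None):
    """Inhibitory-to-excitatory update capping excitatory rates.

    dw = eta * rho_pre * (rho_post - phi_H) when rho_post > phi_L
    (= phi_H - 0.75 Hz), else 0.  Strengthens inhibition when the
    excitatory neuron fires above phi_H, weakly releases it just below,
    and does nothing for low rates: no homeostatic rescue after
    deprivation-induced rate drops.  Clipped below at w_min only.
    """
    rho_pre = np.asarray(rho_pre, dtype=float)
    rho_post = np.asarray(rho_post, dtype=float)
    if np.any(rho_pre < 0) or np.any(rho_post < 0):
        raise ValueError("negative firing rate")
    ph = np.asarray(p.phi_h_mean if phi_h is None else phi_h, dtype=float)
    pl = ph - p.phi_gap
    dw = np.where(rho_post > pl, p.eta * rho_pre * (rho_post - ph), 0.0)
    out = np.maximum(np.asarray(w, dtype=float) + dw, p.w_min)
    return out if out.ndim else float(out)
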