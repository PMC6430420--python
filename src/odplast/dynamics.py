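"""Rate dynamics: linear gain units and the slow BCM trace.

All populations are rate units obeying

    tau * drho/dt = -rho + G(sum_j w_ij rho_j + drive_i),

integrated by forward Euler.  With the default dt = tau = 1 ms the
update reduces to direct assignment rho <- G(input): each population
tracks its instantaneous input.  Inhibitory presynaptic contributions
enter the input sum with negative sign; weights themselves are stored as
non-negative magnitudes.
"""
from __future__ import annotations

import numpy as np

from .params import GainSpec

__all__ = ["gain", "euler_rate_step", "bcm_trace_step"]


def gain(x, spec: GainSpec | None = None):
    """Linear (optionally rectified) gain G(x) = g*x.

    Parameters
    ----------
    x : float or ndarray
        Summed synaptic input.
    spec : GainSpec
        Slope and rectification flag; defaults to g = 0.3, rectified.

    Returns
    -------
    Firing rate(s) in Hz, same shape as ``x``.
    """
    spec = spec or GainSpec()
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite synaptic input")
    out = spec.g * x
    if spec.rectify:
        out = np.maximum(out, 0.0)
    return out if out.ndim else float(out)


def euler_rate_step(rho, total_input, dt: float, tau: float,
                    spec: GainSpec | None = None):
    """One forward-Euler step of the rate equation.

    rho(t+dt) = rho + (dt/tau) * (G(total_input) - rho).  With dt = tau
    this is exactly ``gain(total_input)``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rho = np.asarray(rho, dtype=float)
    target = gain(total_input, spec)
    out = rho + (dt / tau) * (np.asarray(target) - rho)
    if spec is None or spec.rectify:
        out = np.maximum(out, 0.0)
    return out


def bcm_trace_step(trace, rho_post, dt: float, tau_avg: float):
    """Low-pass filter of the postsynaptic rate (sliding-threshold trace).

    tau_avg * d<rho>/dt = -<rho> + rho_post, forward Euler.  The trace
    converges monotonically toward a constant rho_post and never
    overshoots for dt <= tau_avg.
    """
    if tau_avg <= 0 or dt <= 0:
        raise ValueError("dt and tau_avg must be positive")
    trace = np.asarray(trace, dtype=float)
    out = trace + (dt / tau_avg) * (np.asarray(rho_post, dtype=float) - trace)
    return out if out.ndim else float(out)
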