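"""Ocular dominance and selectivity metrics, and OD-shift classification.

The ocular dominance index is computed from evoked *responses* (probe
stimulation with plasticity frozen), not from weights:

    ODI = (CL - IL) / (CL + IL)

where CL and IL are the maximum responses to contralateral-only and
ipsilateral-only visual input.  ODI = +1 is fully contralateral,
-1 fully ipsilateral.

The input selectivity index is one minus the circular variance of the
responses to the N = 5 feature groups, computed on descending-sorted
responses weighted by the N-th roots of unity:

    SI = | sum_n a_n exp(i 2 pi n / N) | / sum_n a_n,  n = 1..N

SI = 1 for a neuron responding to a single feature, 0 for uniform
responses.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .params import Deprivation

__all__ = [
    "compute_odi", "compute_si", "classify_shift", "ShiftClass", "ShiftRecord",
    "UNDEFINED",
]

#: Sentinel returned when both responses are zero (excluded from
#: population statistics).
UNDEFINED = float("nan")

#: ODI-difference threshold above which a neuron counts as shifted.
SHIFT_THRESHOLD = 0.15


class ShiftClass(str, Enum):
    TOWARD_OPEN = "toward-open"
    TOWARD_CLOSED = "toward-closed"
    NONE = "none"


def compute_odi(resp_cl, resp_il):
    """Ocular dominance index from per-eye maximum responses.

    Returns NaN where both responses are zero.  Vectorized over arrays.
    """
    cl = np.asarray(resp_cl, dtype=float)
    il = np.asarray(resp_il, dtype=float)
    if np.any(cl < 0) or np.any(il < 0):
        raise ValueError("responses must be non-negative")
    tot = cl + il
    with np.errstate(invalid="ignore", divide="ignore"):
        odi = np.where(tot > 0, (cl - il) / np.where(tot > 0, tot, 1.0), UNDEFINED)
    return odi if odi.ndim else float(odi)


def compute_si(responses):
    """Selectivity index (one minus circular variance) over feature responses.

    Responses are sorted in descending order, the n-th largest weighted
    by exp(i*2*pi*n/N) for n = 1..N, summed and normalized by the total.
    Scale- and permutation-invariant; in [0, 1] for non-negative input.
    Returns NaN for all-zero responses.
    """
    a = np.sort(np.asarray(responses, dtype=float))[::-1]
    if np.any(a < 0):
        raise ValueError("responses must be non-negative")
    total = a.sum()
    if total <= 0:
        return UNDEFINED
    n = np.arange(1, a.size + 1)
    r = np.sum(a * np.exp(1j * 2 * np.pi * n / a.size)) / total
    return float(np.abs(r))


@dataclass
class ShiftRecord:
    """Per-neuron ocular dominance before/after a deprivation protocol."""

    neuron: int
    odi_before: float
    odi_after: float
    mean_rate: float        # time-averaged rate, normalized to population mean
    shift_class: ShiftClass = ShiftClass.NONE


def classify_shift(odi_before: float, odi_after: float,
                   deprivation: Deprivation,
                   threshold: float = SHIFT_THRESHOLD) -> ShiftClass:
    """Classify an OD shift relative to the deprived eye.

    A shift counts only if |ODI_after - ODI_before| exceeds the
    threshold (0.15).  Movement of the ODI toward the deprived eye's
    pole (+1 for contralateral deprivation, -1 for ipsilateral) is a
    counter-intuitive "toward-closed" shift; movement away is
    "toward-open".  BD/MI/none have no deprived eye: always NONE.
    """
    if np.isnan(odi_before) or np.isnan(odi_after):
        return ShiftClass.NONE
    delta = odi_after - odi_before
    if deprivation is Deprivation.MD_CL:
        toward_closed = delta > threshold
        toward_open = delta < -threshold
    elif deprivation is Deprivation.MD_IL:
        toward_closed = delta < -threshold
        toward_open = delta > threshold
    else:
        return ShiftClass.NONE
    if toward_closed:
        return ShiftClass.TOWARD_CLOSED
    if toward_open:
        return ShiftClass.TOWARD_OPEN
    return ShiftClass.NONE
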