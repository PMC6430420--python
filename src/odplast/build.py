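"""Network construction: ocularity maps, wiring, initial weights.

Two circuits are built here:

* the *simplified* circuit — 1250 layer IV units feeding one layer
  II/III excitatory and one inhibitory unit; only the 250 L4->E weights
  are plastic, everything else static;
* the *network* — 1000 L4 units in five feature groups, 100 LII/III
  excitatory units (five groups of 20) and 20 inhibitory units, with
  plastic feedforward E-to-E, recurrent E-to-E, feedforward E-to-I and
  I-to-E synapse classes.

Every L4 neuron carries an ocular dominance pair (w_contra, w_ipsi)
with w_contra + w_ipsi = 1, drawn from a clipped normal (mean ipsi
weight 0.30, sd 0.35): the sole source of ocularity structure.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import (
    OCULARITY_ALLOCATION,
    EyemapParams,
    ModelParams,
)

__all__ = [
    "Eyemap", "WeightSet", "HeterogeneityMap",
    "generate_eyemap", "build_simplified", "build_network",
    "eyemap_to_csv", "eyemap_from_csv",
]


@dataclass
class Eyemap:
    """Per-L4-neuron ocular dominance weights and feature-group labels."""

    w_ipsi: np.ndarray
    group: np.ndarray | None = None   # feature group label (network model)

    @property
    def w_contra(self) -> np.ndarray:
        return 1.0 - self.w_ipsi

    @property
    def n(self) -> int:
        return self.w_ipsi.size


@dataclass
class WeightSet:
    """All synapse classes of one built circuit.

    Matrices are dense with explicit connectivity masks; masked-out
    entries are exactly zero and stay zero through every plasticity
    step.  Weights are stored as non-negative magnitudes; the inhibitory
    sign is applied in the input summation.
    """

    w_ffw_e: np.ndarray            # (n_exc, n_l4) L4 -> E
    mask_ffw_e: np.ndarray         # bool, same shape
    w_ffw_i: np.ndarray            # (n_inh, n_l4) L4 -> I
    mask_ffw_i: np.ndarray
    w_ie: np.ndarray               # (n_exc, n_inh) I -> E magnitude
    w_rec_ee: np.ndarray | None = None   # (n_exc, n_exc), network only
    mask_rec_ee: np.ndarray | None = None
    plastic: dict = field(default_factory=lambda: {
        "ffw_e": True, "ffw_i": False, "ie": False, "rec_ee": False})

    def copy(self) -> "WeightSet":
        return WeightSet(
            w_ffw_e=self.w_ffw_e.copy(), mask_ffw_e=self.mask_ffw_e,
            w_ffw_i=self.w_ffw_i.copy(), mask_ffw_i=self.mask_ffw_i,
            w_ie=self.w_ie.copy(),
            w_rec_ee=None if self.w_rec_ee is None else self.w_rec_ee.copy(),
            mask_rec_ee=self.mask_rec_ee,
            plastic=dict(self.plastic),
        )


@dataclass
class HeterogeneityMap:
    """Per-excitatory-neuron rate heterogeneity.

    x = 1 + 0.1*zeta scales all presynaptic rates seen by the neuron
    (both in the input sum and in the plasticity rules) and its
    inhibitory-plasticity rate cap phi_H = 6*x; phi_L stays a fixed
    0.75 Hz below phi_H.
    """

    x: np.ndarray
    phi_h: np.ndarray

    @classmethod
    def draw(cls, n: int, rng: np.random.Generator, sd: float = 0.1,
             phi_h_mean: float = 6.0) -> "HeterogeneityMap":
        x = 1.0 + sd * rng.standard_normal(n)
        x = np.maximum(x, 0.0)
        return cls(x=x, phi_h=phi_h_mean * x)


def generate_eyemap(n: int, params: EyemapParams | None = None,
                    rng: np.random.Generator | int | None = None,
                    groups: int | None = None) -> Eyemap:
    """Draw per-neuron ocularity weights from the clipped normal.

    w_ipsi = clip(mean + sd*zeta, 0, 1); w_contra = 1 - w_ipsi.  With
    ``groups`` set, neurons are labelled with contiguous feature groups
    of equal size.
    """
    if n <= 0:
        raise ValueError("need at least one neuron")
    p = params or EyemapParams()
    if p.sd < 0:
        raise ValueError("sd must be non-negative")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    w_ipsi = np.clip(p.mean + p.sd * rng.standard_normal(n), 0.0, 1.0)
    group = None
    if groups:
        group = np.repeat(np.arange(groups), n // groups)
    return Eyemap(w_ipsi=w_ipsi, group=group)


def build_simplified(seed: int, params: ModelParams | None = None
                     ) -> tuple[Eyemap, WeightSet]:
    """Build the single-postsynaptic-pair circuit.

    The excitatory neuron receives 250 distinct afferents chosen
    uniformly at random, initialized at the upper bound; the inhibitory
    neuron is wired to the 150 most contralateral and the 100 most
    ipsilateral L4 neurons with static weights.  The same seed yields
    the identical instantiation for every deprivation paradigm.
    """
    p = params or ModelParams()
    sp = p.simplified
    if sp.n_ffw > sp.n_l4:
        raise ValueError("n_ffw exceeds the L4 population")
    rng = np.random.default_rng(seed)
    eyemap = generate_eyemap(sp.n_l4, p.eyemap, rng)

    aff = rng.choice(sp.n_l4, size=sp.n_ffw, replace=False)
    mask_e = np.zeros((1, sp.n_l4), dtype=bool)
    mask_e[0, aff] = True
    w_ffw_e = np.where(mask_e, p.ee.w_max, 0.0)

    # stable argsort => deterministic tie-breaking for clipped extremes
    by_contra = np.argsort(eyemap.w_contra, kind="stable")
    by_ipsi = np.argsort(eyemap.w_ipsi, kind="stable")
    i_aff = np.concatenate([by_contra[-sp.n_inh_contra:], by_ipsi[-sp.n_inh_ipsi:]])
    mask_i = np.zeros((1, sp.n_l4), dtype=bool)
    mask_i[0, i_aff] = True
    w_ffw_i = np.where(mask_i, sp.w_ei_static, 0.0)

    w_ie = np.full((1, 1), sp.w_ie_static)
    return eyemap, WeightSet(
        w_ffw_e=w_ffw_e, mask_ffw_e=mask_e,
        w_ffw_i=w_ffw_i, mask_ffw_i=mask_i,
        w_ie=w_ie,
        plastic={"ffw_e": True, "ffw_i": False, "ie": False, "rec_ee": False},
    )


def _ocularity_bins(w_contra: np.ndarray, idx: np.ndarray, n_bins: int = 5
                    ) -> list[np.ndarray]:
    """Equal-size ocularity quintiles of one feature group.

    Bin O1 holds the most contralateral neurons (rank by descending
    w_contra, stable order for reproducibility).
    """
    order = idx[np.argsort(-w_contra[idx], kind="stable")]
    return list(np.array_split(order, n_bins))


def build_network(seed: int, params: ModelParams | None = None
                  ) -> tuple[Eyemap, WeightSet, HeterogeneityMap]:
    """Build the full five-feature-group network.

    Feedforward E connectivity follows the ocularity-quintile allocation
    table: within each LII/III group of 20 neurons the rows are dealt in
    table order (scaled 2, 2, 4, 4, 4, 4 neurons), and a neuron's row
    fixes how many of its 50 afferents per input group come from each
    ocularity quintile of that group.  Same-feature-group weights start
    at 0.4*w_max, others ten times smaller.  Recurrent E-to-E weights
    are drawn from N(0.05*w_max, 0.05*w_max) with sub-minimum draws
    reset to the minimum.  Each inhibitory neuron has one randomly
    preferred group wired at w_max, all other groups at the E-to-I
    floor, with afferents restricted to the 30 most contralateral and
    20 most ipsilateral neurons per group.  All feedforward strengths
    are multiplied by the input-population gain factor at simulation
    time, not stored in the matrices.
    """
    p = params or ModelParams()
    np_ = p.network
    rng = np.random.default_rng(seed)
    eyemap = generate_eyemap(np_.n_l4, p.eyemap, rng, groups=np_.n_groups)
    gsz = np_.group_size
    w_contra = eyemap.w_contra

    bins_per_group = []
    for g in range(np_.n_groups):
        idx = np.arange(g * gsz, (g + 1) * gsz)
        bins_per_group.append(_ocularity_bins(w_contra, idx))

    # deal allocation rows to the neurons of each LII/III group in table
    # order, scaled from 100 neurons to the 20 of one group
    scale = np_.n_exc // sum(n for n, _ in OCULARITY_ALLOCATION)
    rows: list[tuple[int, ...]] = []
    for n_neurons, ys in OCULARITY_ALLOCATION:
        rows.extend([ys] * (n_neurons * scale // np_.n_groups))
    assert len(rows) == np_.exc_group_size

    w_max = p.ee.w_max
    mask_e = np.zeros((np_.n_exc, np_.n_l4), dtype=bool)
    w_ffw_e = np.zeros((np_.n_exc, np_.n_l4))
    for k in range(np_.n_exc):
        own_group = k // np_.exc_group_size
        ys = rows[k % np_.exc_group_size]
        for g in range(np_.n_groups):
            chosen = [rng.choice(b, size=y, replace=False)
                      for b, y in zip(bins_per_group[g], ys) if y > 0]
            sel = np.concatenate(chosen)
            mask_e[k, sel] = True
            init = np_.same_group_init if g == own_group else np_.cross_group_init
            w_ffw_e[k, sel] = init * w_max

    # recurrent E-to-E: normal init, floor at the minimum weight
    w_rec = np_.rec_init_scale * w_max * (1.0 + rng.standard_normal((np_.n_exc, np_.n_exc)))
    w_rec = np.maximum(w_rec, p.ee.w_min)
    mask_rec = ~np.eye(np_.n_exc, dtype=bool)
    w_rec[~mask_rec] = 0.0

    # inhibitory afferents: most contra / most ipsi of each group
    mask_i = np.zeros((np_.n_inh, np_.n_l4), dtype=bool)
    w_ffw_i = np.zeros((np_.n_inh, np_.n_l4))
    pref = rng.integers(0, np_.n_groups, size=np_.n_inh)
    for i in range(np_.n_inh):
        for g in range(np_.n_groups):
            idx = np.arange(g * gsz, (g + 1) * gsz)
            by_c = idx[np.argsort(w_contra[idx], kind="stable")]
            by_i = idx[np.argsort(eyemap.w_ipsi[idx], kind="stable")]
            sel = np.concatenate([by_c[-np_.inh_contra_per_group:],
                                  by_i[-np_.inh_ipsi_per_group:]])
            mask_i[i, sel] = True
            w_ffw_i[i, sel] = p.ei.w_max if g == pref[i] else p.ei.w_min

    w_ie = np.full((np_.n_exc, np_.n_inh), np_.w_ie_init)
    het = HeterogeneityMap.draw(np_.n_exc, rng, sd=np_.het_sd,
                                phi_h_mean=p.ie.phi_h_mean)
    weights = WeightSet(
        w_ffw_e=w_ffw_e, mask_ffw_e=mask_e,
        w_ffw_i=w_ffw_i, mask_ffw_i=mask_i,
        w_ie=w_ie, w_rec_ee=w_rec, mask_rec_ee=mask_rec,
        plastic={"ffw_e": True, "ffw_i": True, "ie": True, "rec_ee": True},
    )
    return eyemap, weights, het


def eyemap_to_csv(eyemap: Eyemap, path, seed: int | None = None) -> None:
    """Write an eyemap as columnar text with header metadata."""
    import pandas as pd
    df = pd.DataFrame({"w_ipsi": eyemap.w_ipsi})
    if eyemap.group is not None:
        df["group"] = eyemap.group
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)


def eyemap_from_csv(path) -> Eyemap:
    import pandas as pd
    df = pd.read_csv(path, comment="#")
    group = df["group"].to_numpy() if "group" in df.columns else None
    return Eyemap(w_ipsi=df["w_ipsi"].to_numpy(), group=group)
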