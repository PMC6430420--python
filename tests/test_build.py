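"""Circuit construction: eyemaps, wiring counts, initial weights."""
import numpy as np
import pytest

from odplast.build import build_network, build_simplified, generate_eyemap
from odplast.metrics import compute_odi
from odplast.params import OCULARITY_ALLOCATION, EyemapParams, ModelParams

# closed-form mean of clip(N(0.30, 0.35), 0, 1), frozen from the
# truncated-normal expectation evaluated independently
CLIPPED_MEAN = 0.33502667827505206


class TestEyemap:
    def test_complementarity_and_range(self):
        em = generate_eyemap(5000, rng=0)
        assert np.allclose(em.w_ipsi + em.w_contra, 1.0)
        assert np.all((em.w_ipsi >= 0) & (em.w_ipsi <= 1))

    def test_degenerate_sd_gives_constant(self):
        em = generate_eyemap(100, EyemapParams(sd=0.0), rng=0)
        assert np.allclose(em.w_ipsi, 0.30)

    def test_extreme_draws_are_clipped_to_unit_interval(self):
        em = generate_eyemap(200, EyemapParams(mean=-2.0, sd=0.01), rng=0)
        assert np.all(em.w_ipsi == 0.0) and np.all(em.w_contra == 1.0)

    def test_sample_mean_matches_clipped_normal_closed_form(self):
        n = 100_000
        em = generate_eyemap(n, rng=12345)
        # s.e. of the clipped variate is below the raw sd / sqrt(n)
        se = 0.35 / np.sqrt(n)
        assert abs(em.w_ipsi.mean() - CLIPPED_MEAN) < 3 * se

    def test_rejects_empty_population(self):
        with pytest.raises(ValueError):
            generate_eyemap(0)


class TestSimplifiedBuild:
    def test_afferent_counts(self):
        _, w = build_simplified(1, ModelParams())
        assert w.mask_ffw_e.sum() == 250
        assert w.mask_ffw_i.sum() == 250  # 150 most contra + 100 most ipsi

    def test_inhibitory_wiring_selects_ocular_extremes(self):
        em, w = build_simplified(3, ModelParams())
        i_aff = np.flatnonzero(w.mask_ffw_i[0])
        others = np.setdiff1d(np.arange(em.n), i_aff)
        contra_sel = np.sort(em.w_contra[i_aff])[-150:]
        # brute-force check: the 150 most contralateral afferents all
        # dominate every unselected neuron in w_contra
        assert contra_sel.min() >= em.w_contra[others].max() - 1e-12

    def test_seed_determinism(self):
        _, w1 = build_simplified(7, ModelParams())
        _, w2 = build_simplified(7, ModelParams())
        assert np.array_equal(w1.w_ffw_e, w2.w_ffw_e)
        assert np.array_equal(w1.mask_ffw_i, w2.mask_ffw_i)

    def test_plastic_weights_start_at_upper_bound(self):
        p = ModelParams()
        _, w = build_simplified(1, p)
        assert np.all(w.w_ffw_e[w.mask_ffw_e] == p.ee.w_max)

    def test_rejects_more_afferents_than_l4(self):
        p = ModelParams()
        p.simplified.n_ffw = p.simplified.n_l4 + 1
        with pytest.raises(ValueError):
            build_simplified(1, p)


class TestAllocationTable:
    def test_row_sums(self):
        assert sum(n for n, _ in OCULARITY_ALLOCATION) == 100
        for _, ys in OCULARITY_ALLOCATION:
            assert sum(ys) == 50


@pytest.fixture(scope="module")
def net():
    p = ModelParams()
    return p, *build_network(11, p)


class TestNetworkBuild:

    def test_per_group_in_degrees(self, net):
        p, em, w, het = net
        gsz = p.network.group_size
        for k in range(p.network.n_exc):
            for g in range(p.network.n_groups):
                assert w.mask_ffw_e[k, g * gsz:(g + 1) * gsz].sum() == 50
        for i in range(p.network.n_inh):
            for g in range(p.network.n_groups):
                assert w.mask_ffw_i[i, g * gsz:(g + 1) * gsz].sum() == 50

    def test_same_group_weights_ten_times_cross_group(self, net):
        p, em, w, het = net
        gsz, egsz = p.network.group_size, p.network.exc_group_size
        w_max = p.ee.w_max
        for k in (0, 37, 99):
            own = k // egsz
            for g in range(p.network.n_groups):
                sl = slice(g * gsz, (g + 1) * gsz)
                vals = w.w_ffw_e[k, sl][w.mask_ffw_e[k, sl]]
                expect = (p.network.same_group_init if g == own
                          else p.network.cross_group_init) * w_max
                assert np.allclose(vals, expect)

    def test_recurrent_weights_floor_and_no_self_connections(self, net):
        p, em, w, het = net
        assert np.all(np.diag(w.w_rec_ee) == 0)
        assert np.all(w.w_rec_ee[w.mask_rec_ee] >= p.ee.w_min)

    def test_heterogeneity_scales_rate_cap(self, net):
        p, em, w, het = net
        assert np.allclose(het.phi_h, p.ie.phi_h_mean * het.x)

    def test_initial_odi_broader_than_random_wiring(self, net):
        """The ocularity-quintile allocation widens the LII/III ODI
        distribution relative to 50 uniform random draws per group."""
        p, em, w, het = net
        gsz = p.network.group_size

        def weight_odi(mask_row):
            wc = em.w_contra[mask_row]
            wi = em.w_ipsi[mask_row]
            return compute_odi(wc.sum(), wi.sum())

        odi_struct = [weight_odi(w.mask_ffw_e[k]) for k in range(100)]
        rng = np.random.default_rng(0)
        odi_rand = []
        for _ in range(100):
            sel = np.concatenate([
                g * gsz + rng.choice(gsz, 50, replace=False)
                for g in range(p.network.n_groups)])
            mask = np.zeros(em.n, dtype=bool)
            mask[sel] = True
            odi_rand.append(weight_odi(mask))
        assert np.ptp(odi_struct) > 2 * np.ptp(odi_rand)

    def test_connectivity_mask_preserved_by_plasticity(self, net):
        from odplast.simulate import NetworkSimulator
        p, em, w, het = net
        sim = NetworkSimulator(em, w.copy(), het, p)
        sim.run(500, p.drive, rho_target=p.ei.rho_target)
        assert np.all(sim.weights.w_ffw_e[~w.mask_ffw_e] == 0.0)
        assert np.all(sim.weights.w_ffw_i[~w.mask_ffw_i] == 0.0)
        assert np.all(np.diag(sim.weights.w_rec_ee) == 0.0)


def test_eyemap_csv_round_trip(tmp_path):
    em = generate_eyemap(500, rng=3, groups=5)
    path = tmp_path / "eyemap.csv"
    from odplast.build import eyemap_from_csv, eyemap_to_csv
    eyemap_to_csv(em, path, seed=3)
    em2 = eyemap_from_csv(path)
    assert np.allclose(em.w_ipsi, em2.w_ipsi)
    assert np.array_equal(em.group, em2.group)
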