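"""Dip statistic, Gaussian mixtures, component selection, length classes."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gyriconn.lengths import (
    MixtureModel,
    class_cutoffs,
    dip_pvalue,
    dip_statistic,
    fit_gmm_em,
    select_k_crossval,
    split_short_long,
)
from gyriconn.tracts import StreamlineSet

from _oracles import dip_brute_force


def three_component_sample(n, seed):
    rng = np.random.default_rng(seed)
    lam = np.array([0.60, 0.35, 0.05])
    mu = np.array([22.0, 55.0, 110.0])
    sd = np.array([5.0, 12.0, 20.0])
    comp = rng.choice(3, size=n, p=lam)
    return rng.normal(mu[comp], sd[comp]), (lam, mu, sd)


class TestDip:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        """The fast GCM/LCM dip equals the per-modal-point brute force
        (qhull) on random samples including ties."""
        rng = np.random.default_rng(seed)
        for kind in range(4):
            n = int(rng.integers(4, 50))
            x = {
                0: rng.uniform(size=n),
                1: np.concatenate([rng.normal(0, 1, n // 2), rng.normal(6, 1, n - n // 2)]),
                2: rng.integers(0, 5, n).astype(float),
                3: rng.exponential(size=n),
            }[kind]
            assert dip_statistic(x) == pytest.approx(dip_brute_force(x), abs=1e-12)

    def test_degenerate_sample_attains_floor(self):
        assert dip_statistic(np.ones(10)) == pytest.approx(1.0 / 20.0)

    def test_bimodal_exceeds_uniform(self):
        rng = np.random.default_rng(0)
        uni = rng.uniform(size=500)
        bi = np.concatenate([rng.normal(0, 1, 250), rng.normal(8, 1, 250)])
        assert dip_statistic(bi) > dip_statistic(uni)

    @given(st.floats(min_value=0.01, max_value=100.0), st.floats(-50, 50))
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(99)
        x = np.concatenate([rng.normal(0, 1, 40), rng.normal(5, 1, 40)])
        assert dip_statistic(a * x + b) == pytest.approx(dip_statistic(x), rel=1e-9)

    def test_range_and_minimum_n(self):
        rng = np.random.default_rng(1)
        for n in (4, 10, 200):
            d = dip_statistic(rng.uniform(size=n))
            assert 0.0 < d <= 0.25
        with pytest.raises(ValueError):
            dip_statistic([1.0, 2.0, 3.0])


class TestDipPvalue:
    def test_deterministic(self):
        p1 = dip_pvalue(0.05, 100, n_boot=1000, seed=3)
        p2 = dip_pvalue(0.05, 100, n_boot=1000, seed=3)
        assert p1 == p2

    def test_bimodal_power(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(0, 1, 500), rng.normal(8, 1, 500)])
        p = dip_pvalue(dip_statistic(x), len(x), n_boot=1000, seed=5)
        assert p < 0.001 + 1e-9

    def test_nboot_floor(self):
        with pytest.raises(ValueError):
            dip_pvalue(0.05, 100, n_boot=10, seed=0)


class TestGmmEm:
    def test_k1_closed_form(self, rng):
        x = rng.normal(3.0, 2.0, 500)
        m = fit_gmm_em(x, 1, seed=0)
        assert m.weights[0] == pytest.approx(1.0)
        assert m.means[0] == pytest.approx(x.mean(), abs=1e-6)
        assert m.sds[0] == pytest.approx(x.std(), rel=1e-3)  # MLE (ddof 0)

    def test_single_gaussian_recovery_within_2se(self):
        rng = np.random.default_rng(7)
        mu, sd, n = 50.0, 8.0, 2000
        x = rng.normal(mu, sd, n)
        m = fit_gmm_em(x, 1, seed=0)
        assert abs(m.means[0] - mu) < 2 * sd / np.sqrt(n)
        assert abs(m.sds[0] - sd) < 2 * sd / np.sqrt(2 * n)

    def test_three_component_recovery(self):
        x, (lam, mu, sd) = three_component_sample(5000, seed=11)
        m = fit_gmm_em(x, 3, seed=0)
        assert np.allclose(m.means, mu, rtol=0.10)
        assert np.allclose(m.sds, sd, rtol=0.25)
        assert np.allclose(m.weights, lam, rtol=0.30)

    def test_agrees_with_sklearn(self):
        """Independent cross-check: sklearn's EM on the same data reaches
        the same log-likelihood and parameters."""
        from sklearn.mixture import GaussianMixture

        x, _ = three_component_sample(3000, seed=13)
        ours = fit_gmm_em(x, 3, seed=0)
        sk = GaussianMixture(3, n_init=5, random_state=0, tol=1e-6).fit(x[:, None])
        order = np.argsort(sk.means_.ravel())
        assert np.allclose(ours.means, sk.means_.ravel()[order], rtol=0.03)
        assert np.allclose(ours.weights, sk.weights_[order], atol=0.02)
        ll_sk = sk.score(x[:, None]) * len(x)
        assert ours.log_likelihood == pytest.approx(ll_sk, rel=1e-3)

    def test_needs_enough_data(self):
        with pytest.raises(ValueError):
            fit_gmm_em(np.arange(20.0), 2, seed=0)

    def test_weights_sum_to_one_enforced(self):
        with pytest.raises(ValueError):
            MixtureModel([0.5, 0.4], [0.0, 1.0], [1.0, 1.0], 0.0)
        with pytest.raises(ValueError):
            MixtureModel([0.5, 0.5], [1.0, 0.0], [1.0, 1.0], 0.0)  # unsorted means


class TestSelectK:
    def test_single_gaussian_selects_k1(self):
        rng = np.random.default_rng(21)
        x = rng.normal(40.0, 10.0, 3000)
        k, scores = select_k_crossval(x, (1, 2, 3), seed=0)
        assert k == 1
        assert set(scores) == {1, 2, 3}

    def test_three_component_selects_k3(self):
        x, _ = three_component_sample(5000, seed=23)
        k, _ = select_k_crossval(x, (1, 2, 3, 4), seed=0)
        assert k == 3

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            select_k_crossval(np.arange(100.0), (), seed=0)


class TestCutoffs:
    def test_symmetric_midpoint_exact(self):
        m = MixtureModel([0.5, 0.5], [20.0, 60.0], [5.0, 5.0], 0.0)
        assert class_cutoffs(m)[0] == pytest.approx(40.0, abs=1e-9)

    def test_unequal_weights_shift_toward_lighter(self):
        heavy_left = MixtureModel([0.8, 0.2], [20.0, 60.0], [5.0, 5.0], 0.0)
        cut = class_cutoffs(heavy_left)[0]
        assert cut > 40.0  # boundary moves toward the lighter component

    @pytest.mark.parametrize(
        "w,mu,sd",
        [
            ([0.6, 0.4], [20.0, 60.0], [4.0, 12.0]),
            ([0.3, 0.7], [25.0, 50.0], [6.0, 8.0]),
            ([0.6, 0.35, 0.05], [22.0, 55.0, 110.0], [5.0, 12.0, 20.0]),
        ],
    )
    def test_matches_grid_scan_oracle(self, w, mu, sd):
        """Cutoffs agree with a fine-grid scan for the weighted-density
        crossing between adjacent components."""
        m = MixtureModel(w, mu, sd, 0.0)
        cuts = class_cutoffs(m)
        for i, cut in enumerate(cuts):
            grid = np.linspace(mu[i], mu[i + 1], 200001)
            d1 = w[i] * np.exp(-0.5 * ((grid - mu[i]) / sd[i]) ** 2) / sd[i]
            d2 = w[i + 1] * np.exp(-0.5 * ((grid - mu[i + 1]) / sd[i + 1]) ** 2) / sd[i + 1]
            crossing = grid[np.argmin(np.abs(d1 - d2))]
            assert cut == pytest.approx(crossing, abs=(mu[i + 1] - mu[i]) * 1e-3)
        assert np.all(cuts > np.array(mu)[:-1]) and np.all(cuts < np.array(mu)[1:])

    def test_k1_rejected(self):
        with pytest.raises(ValueError):
            class_cutoffs(MixtureModel([1.0], [10.0], [1.0], 0.0))


def _streams_of_lengths(lengths):
    lines = [np.column_stack([np.linspace(0, L, int(L) + 1), np.zeros(int(L) + 1), np.zeros(int(L) + 1)]) for L in lengths]
    return StreamlineSet(lines)


class TestSplit:
    def test_boundary_semantics(self):
        s = _streams_of_lengths([25.0, 30.0, 100.0, 160.0])
        res = split_short_long(s, cutoff_mm=30.0, upper_mm=150.0)
        assert sorted(res.short.lengths()) == [25.0]
        assert sorted(res.long.lengths()) == [30.0, 100.0]
        assert res.n_excluded == 1

    def test_cutoff_at_minimum_empties_short(self):
        s = _streams_of_lengths([25.0, 30.0, 40.0])
        res = split_short_long(s, cutoff_mm=25.0)
        assert res.short.count == 0

    def test_conservation(self):
        lengths = [21.0, 29.0, 31.0, 55.0, 149.0, 151.0, 200.0]
        s = _streams_of_lengths(lengths)
        res = split_short_long(s, cutoff_mm=30.0, upper_mm=150.0)
        assert res.short.count + res.long.count + res.n_excluded == len(lengths)
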