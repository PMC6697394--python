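"""Cluster-mass permutation machinery against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import bistream as bs
from bistream.cluster import _max_mass_rows, _pooled_t


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_clusters(tvals, sig, min_len):
    """Enumerate same-sign suprathreshold runs by direct scanning."""
    out = []
    i = 0
    n = len(tvals)
    while i < n:
        if sig[i] and tvals[i] != 0:
            s = np.sign(tvals[i])
            j = i
            while j < n and sig[j] and np.sign(tvals[j]) == s:
                j += 1
            if j - i >= min_len:
                out.append((i, j, int(s), float(tvals[i:j].sum())))
            i = j
        else:
            i += 1
    return out


def brute_bh(p, q):
    """Textbook Benjamini-Hochberg step-up."""
    m = len(p)
    order = np.argsort(p)
    reject = np.zeros(m, dtype=bool)
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= q * rank / m:
            k_max = rank
    reject[order[:k_max]] = True
    return reject


# ---------------------------------------------------------------------------


class TestPointwiseT:
    def test_matches_scipy(self, rng):
        x1 = rng.standard_normal((14, 50))
        x2 = rng.standard_normal((9, 50)) + 0.3
        t, p = _pooled_t(x1, x2)
        ref = stats.ttest_ind(x1, x2, axis=0, equal_var=True)
        assert np.allclose(t, ref.statistic)
        assert np.allclose(p, ref.pvalue)

    def test_large_offset_gives_large_t(self, rng):
        x1 = rng.standard_normal((200, 20))
        x2 = rng.standard_normal((200, 20))
        x2[:, 5:10] += 10.0
        t, _ = _pooled_t(x1, x2)
        assert np.all(np.abs(t[5:10]) > 50)
        assert np.all(np.abs(t[:5]) < 10)

    def test_null_calibration(self, rng):
        """Under identical class distributions, ~5% of points reach p<0.05."""
        x1 = rng.standard_normal((60, 4000))
        x2 = rng.standard_normal((60, 4000))
        _, p = _pooled_t(x1, x2)
        frac = (p < 0.05).mean()
        assert 0.035 < frac < 0.065

    def test_zero_variance_untestable(self):
        x1 = np.full((2, 10), 1.0)
        x2 = np.full((2, 10), 1.0)
        t, p = _pooled_t(x1, x2)
        assert np.all(t == 0) and np.all(p == 1)

    def test_epochs_interface(self, small_epochs):
        pw = bs.pointwise_t(small_epochs)
        assert pw.tmat.shape == (small_epochs.n_sites, 600)
        assert pw.testable.all()
        assert np.all((pw.praw > 0) & (pw.praw <= 1))

    def test_trial_order_invariance(self, small_epochs):
        """Permuting trial order leaves all observed statistics unchanged."""
        perm = np.random.default_rng(0).permutation(small_epochs.n_trials)
        shuffled = small_epochs.select_trials(perm)
        a = bs.pointwise_t(small_epochs)
        b = bs.pointwise_t(shuffled)
        assert np.allclose(a.tmat, b.tmat, equal_nan=True)


class TestFormClusters:
    def _run(self, tvals, sig, min_len):
        praw = np.where(sig, 0.01, 0.5)
        return bs.form_clusters(np.asarray(tvals, float), praw, min_len=min_len)

    def test_long_run_kept(self):
        t = np.zeros(100)
        t[10:35] = 3.0
        cl = self._run(t, t != 0, 20)
        assert len(cl) == 1 and (cl[0].start, cl[0].stop) == (10, 35)
        assert cl[0].mass == pytest.approx(75.0)

    def test_short_run_dropped(self):
        t = np.zeros(100)
        t[10:25] = 3.0  # 15 samples < 20
        assert self._run(t, t != 0, 20) == []

    def test_sign_flip_splits_run(self):
        t = np.zeros(100)
        t[10:35] = 3.0
        t[22:35] = -3.0  # runs of 12 and 13, both below 20
        assert self._run(t, t != 0, 20) == []

    def test_matches_brute_force(self, rng):
        """Random instances: clustering equals direct run enumeration."""
        for _ in range(50):
            t = rng.standard_normal(80) * 3
            sig = rng.random(80) < 0.5
            min_len = int(rng.integers(1, 8))
            got = [(c.start, c.stop, c.sign, c.mass) for c in self._run(t, sig, min_len)]
            want = brute_clusters(t, sig, min_len)
            assert got == pytest.approx(want)

    def test_cluster_mass_op(self):
        t = np.array([0.0, 2.5, 2.5, 2.5, 0.0])
        c = bs.Cluster(1, 4, 1, 7.5)
        assert bs.cluster_mass(c, t) == pytest.approx(7.5)
        t2 = np.array([-3.0, -3.0])
        assert bs.cluster_mass(bs.Cluster(0, 2, -1, -6.0), t2) == pytest.approx(-6.0)


class TestMaxMassRows:
    def test_matches_scalar_path(self, rng):
        """Vectorized permutation clustering equals the scalar reference."""
        t_crit = 2.0
        for _ in range(20):
            t = rng.standard_normal((7, 60)) * 2.5
            min_len = int(rng.integers(1, 6))
            got = _max_mass_rows(t, t_crit, min_len)
            for row in range(7):
                cl = brute_clusters(t[row], np.abs(t[row]) > t_crit, min_len)
                want = max((m for *_, m in cl), key=abs, default=0.0)
                assert got[row] == pytest.approx(want)


class TestPermutationNull:
    def test_deterministic_under_seed(self, rng):
        x = rng.standard_normal((30, 100))
        labels = np.array([1] * 15 + [2] * 15)
        a = bs.permutation_null(x, labels, n_perm=200, min_len=5, rng=7)
        b = bs.permutation_null(x, labels, n_perm=200, min_len=5, rng=7)
        assert np.array_equal(a, b)

    def test_label_invariant_data_gives_zero(self):
        x = np.tile(np.linspace(0, 1, 50), (20, 1))  # all trials identical
        labels = np.array([1] * 10 + [2] * 10)
        null = bs.permutation_null(x, labels, n_perm=100, min_len=5)
        assert np.all(null == 0)

    def test_monte_carlo_p_never_zero(self, rng):
        x = rng.standard_normal((24, 80))
        x[:12] += 5.0
        labels = np.array([1] * 12 + [2] * 12)
        null = bs.permutation_null(x, labels, n_perm=300, min_len=5, rng=0)
        assert bs.monte_carlo_p(1e9, null) > 0


class TestMonteCarloP:
    def test_printed_formula(self):
        assert bs.monte_carlo_p(0.0, np.zeros(10)) == 1.0  # r = n
        null = np.zeros(10_000)
        assert bs.monte_carlo_p(5.0, null) == pytest.approx(1 / 10_001)
        null2 = np.concatenate([np.full(499, 9.0), np.zeros(9_500)])
        assert bs.monte_carlo_p(5.0, null2) == pytest.approx(0.05)


class TestAdjustedP:
    def test_members_inherit_cluster_p(self):
        clusters = [bs.Cluster(60, 131, 1, 50.0), bs.Cluster(300, 340, -1, -30.0)]
        p_row = bs.assign_adjusted_p(clusters, [0.03, 0.2], 600)
        assert np.all(p_row[60:131] == 0.03)
        assert np.all(p_row[300:340] == 0.2)
        outside = np.ones(600, bool)
        outside[60:131] = outside[300:340] = False
        assert np.all(p_row[outside] == 1.0)

    def test_no_clusters_all_one(self):
        assert np.all(bs.assign_adjusted_p([], [], 100) == 1.0)


class TestFdr:
    def test_examples(self):
        assert list(bs.fdr_across_sites(np.array([0.001, 0.2, 0.9]), q=0.01)) == [
            True, False, False,
        ]
        assert not bs.fdr_across_sites(np.ones(10), q=0.01).any()
        assert bs.fdr_across_sites(np.full(25, 1e-6), q=0.01).all()

    def test_matches_brute_force(self, rng):
        """BH step-up equals the textbook procedure on random p-vectors."""
        for _ in range(1000):
            m = int(rng.integers(1, 30))
            p = rng.random(m) ** rng.uniform(0.5, 3)
            q = float(rng.uniform(0.005, 0.2))
            assert np.array_equal(bs.fdr_across_sites(p, q), brute_bh(p, q))

    def test_nan_untestable_never_rejected(self):
        p = np.array([1e-6, np.nan, 1e-6])
        rej = bs.fdr_across_sites(p, q=0.05)
        assert list(rej) == [True, False, True]


class TestSiteTest:
    def test_detects_injected_effect(self, rng):
        x = rng.standard_normal((120, 300))
        labels = np.array([1] * 60 + [2] * 60)
        x[labels == 2, 100:160] += 1.2
        res = bs.cluster_test_site(x, labels, n_perm=300, rng=1)
        assert res.p_site < 0.01
        best = max(res.clusters, key=lambda c: abs(c.mass))
        assert best.start < 160 and best.stop > 100

    def test_untestable_site(self):
        x = np.zeros((5, 50))
        labels = np.array([1, 1, 1, 1, 2])  # class 2 has a single trial
        res = bs.cluster_test_site(x, labels, n_perm=10)
        assert not res.testable and np.isnan(res.p_site)

    def test_epochs_driver(self, small_epochs, small_synth):
        # n_perm sets the p-value floor at 1/(n+1); 999 keeps it below the
        # BH threshold q * 1/m for m = 8 sites.
        m = bs.aep_cluster_test(small_epochs, n_perm=999, seed=5)
        assert len(m.table) == small_epochs.n_sites
        hits = set(np.flatnonzero(m.table["q_reject"].to_numpy()))
        assert set(small_synth.effect_sites) <= hits
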