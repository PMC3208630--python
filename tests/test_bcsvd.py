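"""The simultaneous Bayesian test: standardization, SVD, Gibbs, permutation."""

import numpy as np
import pytest
import statsmodels.api as sm

from pamethyl import bcsvd
from pamethyl.bcsvd import SamplerSettings
from pamethyl.types import BetaMatrix


def _make_beta(x):
    n, p = x.shape
    return BetaMatrix(x, [f"s{i}" for i in range(n)], [f"p{j}" for j in range(p)])


LABELS_3V3 = np.array([0, 0, 0, 1, 1, 1])


class TestStandardize:
    def test_constant_probe_dropped_and_logged(self, rng):
        x = rng.uniform(0.2, 0.8, (6, 5))
        x[:, 2] = 0.5
        design = bcsvd.standardize(_make_beta(x), LABELS_3V3)
        assert design.dropped_probe_ids == ["p2"]
        assert design.z.shape == (6, 4)

    def test_columns_centered_and_scaled(self, small_dataset):
        beta, _, _, labels = small_dataset
        design = bcsvd.standardize(beta, labels)
        assert np.abs(design.z.mean(axis=0)).max() < 1e-8
        assert np.abs(design.z.var(axis=0) - 1).max() < 1e-6

    def test_dimensions_preserved_minus_dropped(self, rng):
        x = rng.uniform(0.2, 0.8, (12, 200))
        const = rng.choice(200, size=7, replace=False)
        x[:, const] = 0.4
        labels = np.r_[np.zeros(5, int), np.ones(7, int)]
        design = bcsvd.standardize(_make_beta(x), labels)
        assert design.z.shape[1] == 200 - 7
        assert len(design.dropped_probe_ids) == 7

    def test_small_class_rejected(self, rng):
        x = rng.uniform(0, 1, (4, 5))
        with pytest.raises(ValueError):
            bcsvd.standardize(_make_beta(x), np.array([0, 1, 1, 1]))


class TestSvdReduce:
    def test_rank_one_matrix(self):
        u = np.array([1.0, -1.0, 2.0, -2.0, 0.5, -0.5])
        v = np.linspace(1, 2, 8)
        z = np.outer(u - u.mean(), v)
        z = (z - z.mean(0)) / z.std(0)
        design = bcsvd.DesignMatrix(
            z, LABELS_3V3, [f"p{j}" for j in range(8)], [f"s{i}" for i in range(6)],
            np.zeros(8), np.ones(8),
        )
        assert bcsvd.svd_reduce(design).r == 1

    def test_rank_bounded_by_n_minus_one(self, small_dataset):
        beta, _, _, labels = small_dataset
        decomp = bcsvd.svd_reduce(bcsvd.standardize(beta, labels))
        assert decomp.r <= beta.n_samples - 1

    def test_reconstruction_and_orthonormal_loadings(self, small_dataset):
        beta, _, _, labels = small_dataset
        design = bcsvd.standardize(beta, labels)
        d = bcsvd.svd_reduce(design)
        recon = d.scores @ d.loadings.T
        assert np.abs(recon - design.z).max() < 1e-8
        gram = d.loadings.T @ d.loadings
        assert np.abs(gram - np.eye(d.r)).max() < 1e-8

    def test_singular_values_match_gram_eigendecomposition(self, rng):
        x = rng.uniform(0.1, 0.9, (8, 30))
        labels = np.r_[np.zeros(4, int), np.ones(4, int)]
        design = bcsvd.standardize(_make_beta(x), labels)
        d = bcsvd.svd_reduce(design)
        w = np.linalg.eigvalsh(design.z @ design.z.T)[::-1]
        sv_oracle = np.sqrt(np.clip(w[: d.r], 0, None))
        assert np.abs(d.singular_values - sv_oracle).max() < 1e-8

    def test_all_zero_matrix_rejected(self):
        design = bcsvd.DesignMatrix(
            np.zeros((6, 4)), LABELS_3V3, list("abcd"),
            [f"s{i}" for i in range(6)], np.zeros(4), np.ones(4),
        )
        with pytest.raises(ValueError):
            bcsvd.svd_reduce(design)


class TestGibbs:
    def test_null_posterior_mean_near_zero_in_the_long_run(self):
        """y independent of scores => gamma posterior centered at 0,
        averaged over datasets (any one dataset shows chance association).
        200 datasets x 100 kept draws = 20,000 posterior draws total."""
        means = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            scores = r.normal(0, 1, (12, 2))
            y = r.permutation(np.r_[np.zeros(6, int), np.ones(6, int)])
            draws = bcsvd.gibbs_fit(
                scores, y,
                SamplerSettings(prior_variance=1.0, n_iter=150, burn_in=50),
                seed=seed,
            )
            means.append(draws.gamma_draws.mean(axis=0))
        means = np.array(means)
        grand = means.mean(axis=0)
        se = means.std(axis=0, ddof=1) / np.sqrt(len(means))
        assert np.all(np.abs(grand) < 3 * se + 1e-3)

    def test_separable_scores_one_signed_posterior(self):
        scores = np.linspace(-2, 2, 8).reshape(-1, 1)
        y = (scores[:, 0] > 0).astype(int)
        draws = bcsvd.gibbs_fit(
            scores, y, SamplerSettings(n_iter=4000, burn_in=500), seed=1
        )
        assert (draws.gamma_draws[:, 0] > 0).mean() > 0.99

    def test_identical_seed_identical_draws(self, rng):
        scores = rng.normal(0, 1, (10, 4))
        y = np.r_[np.zeros(5, int), np.ones(5, int)]
        s = SamplerSettings(n_iter=500, burn_in=100)
        d1 = bcsvd.gibbs_fit(scores, y, s, seed=3)
        d2 = bcsvd.gibbs_fit(scores, y, s, seed=3)
        assert np.array_equal(d1.gamma_draws, d2.gamma_draws)
        assert np.array_equal(d1.intercept_draws, d2.intercept_draws)

    def test_nonbinary_labels_rejected(self, rng):
        with pytest.raises(ValueError):
            bcsvd.gibbs_fit(rng.normal(0, 1, (6, 2)), np.array([0, 1, 2, 0, 1, 2]))

    def test_reduced_rank_probit_equals_full_probit_likelihood(self, rng):
        """With p < n and full rank, the MLE fit on scores matches the fit
        on the original probes (same column space)."""
        x = rng.uniform(0.2, 0.8, (14, 5))
        y = rng.integers(0, 2, 14)
        y[:3], y[-3:] = 0, 1
        labels = y
        design = bcsvd.standardize(_make_beta(x), labels)
        d = bcsvd.svd_reduce(design)
        full = sm.Probit(labels, sm.add_constant(design.z)).fit(disp=0, maxiter=500)
        red = sm.Probit(labels, sm.add_constant(d.scores)).fit(disp=0, maxiter=500)
        assert red.llf == pytest.approx(full.llf, abs=1e-6)


class TestProbeStatistics:
    def test_zero_posterior_gives_zero_statistics(self, small_dataset):
        beta, _, _, labels = small_dataset
        design = bcsvd.standardize(beta, labels)
        d = bcsvd.svd_reduce(design)
        draws = bcsvd.PosteriorDraws(
            gamma_draws=np.zeros((50, d.r)),
            intercept_draws=np.zeros(50),
            settings=SamplerSettings(n_iter=100, burn_in=50),
            seed=0,
        )
        assert np.all(bcsvd.probe_statistics(draws, d) == 0)

    def test_planted_probe_dominates(self, rng):
        """A single strongly differential probe tops the probe-space
        posterior-mean effects."""
        x = rng.uniform(0.4, 0.6, (12, 200))
        labels = np.r_[np.zeros(5, int), np.ones(7, int)]
        x[labels == 1, 17] += 0.35
        x = x.clip(0, 1)
        design = bcsvd.standardize(_make_beta(x), labels)
        d = bcsvd.svd_reduce(design)
        draws = bcsvd.gibbs_fit(d.scores, labels, seed=5)
        stat = bcsvd.probe_statistics(draws, d)
        assert np.argmax(np.abs(stat)) == 17

    def test_statistic_length_matches_retained_probes(self, small_dataset):
        beta, _, _, labels = small_dataset
        design = bcsvd.standardize(beta, labels)
        d = bcsvd.svd_reduce(design)
        draws = bcsvd.gibbs_fit(d.scores, labels, SamplerSettings(n_iter=300, burn_in=100))
        assert len(bcsvd.probe_statistics(draws, d)) == len(design.probe_ids)


class TestPermutation:
    def test_perfect_probe_hits_pvalue_floor(self, rng):
        x = rng.uniform(0.45, 0.55, (12, 40))
        labels = np.r_[np.zeros(5, int), np.ones(7, int)]
        x[labels == 1, 0] += 0.4
        x = x.clip(0, 1)
        design = bcsvd.standardize(_make_beta(x), labels)
        res = bcsvd.permutation_pvalues(design, b=99, seed=2)
        assert res[0].empirical_p == pytest.approx(1 / 100)

    def test_exhaustive_enumeration_small_n(self, rng):
        """3 vs 3: all 20 distinct assignments are enumerated."""
        x = rng.uniform(0.3, 0.7, (6, 15))
        x[3:, 4] += 0.25
        x = x.clip(0, 1)
        design = bcsvd.standardize(_make_beta(x), LABELS_3V3)
        res = bcsvd.permutation_pvalues(design, b=10_000, seed=0)
        # p-values are multiples of 1/21 (20 permutations + add-one)
        for r in res:
            assert (r.empirical_p * 21) == pytest.approx(round(r.empirical_p * 21))
        assert min(r.empirical_p for r in res) >= 1 / 21

    def test_deterministic_given_seed(self, rng):
        x = rng.uniform(0.3, 0.7, (8, 25))
        labels = np.r_[np.zeros(4, int), np.ones(4, int)]
        design = bcsvd.standardize(_make_beta(x), labels)
        s = SamplerSettings(n_iter=300, burn_in=60)
        r1 = bcsvd.permutation_pvalues(design, b=29, seed=8, settings=s,
                                       permutation_settings=s)
        r2 = bcsvd.permutation_pvalues(design, b=29, seed=8, settings=s,
                                       permutation_settings=s)
        assert [r.empirical_p for r in r1] == [r.empirical_p for r in r2]

    def test_growing_b_preserves_earlier_permutations(self, rng):
        """The counter seed scheme: the first K permutations of a larger run
        equal the smaller run's, so p-values stay consistent in distribution.
        Checked indirectly: rerunning with the same B is identical and the
        permutation label streams are prefixes of each other."""
        y = np.r_[np.zeros(5, int), np.ones(7, int)]
        g1 = np.random.default_rng(np.random.SeedSequence(4, spawn_key=(0,)))
        g2 = np.random.default_rng(np.random.SeedSequence(4, spawn_key=(0,)))
        p1 = bcsvd._permutation_labels(y, 30, g1)
        p2 = bcsvd._permutation_labels(y, 60, g2)
        assert all(np.array_equal(a, b) for a, b in zip(p1, p2[:30]))

    def test_relabeling_invariance(self, rng):
        """Swapping case/control labels leaves the inference unchanged up
        to sampler noise: permutation streams are complements, a clearly
        separated probe flips direction but keeps its significance, and
        its seed-averaged p-value agrees between labelings."""
        x = rng.uniform(0.45, 0.55, (12, 20))
        labels = np.r_[np.zeros(5, int), np.ones(7, int)]
        x[labels == 1, 0] += 0.4
        x = x.clip(0, 1)
        d1 = bcsvd.standardize(_make_beta(x), labels)
        d2 = bcsvd.standardize(_make_beta(x), 1 - labels)
        p0_1, p0_2 = [], []
        for seed in range(3):
            r1 = bcsvd.permutation_pvalues(design=d1, b=49, seed=seed)
            r2 = bcsvd.permutation_pvalues(design=d2, b=49, seed=seed)
            assert {r1[0].direction, r2[0].direction} == {"hyper", "hypo"}
            p0_1.append(r1[0].empirical_p)
            p0_2.append(r2[0].empirical_p)
        m1, m2 = np.mean(p0_1), np.mean(p0_2)
        assert m1 < 0.15 and m2 < 0.15
        assert abs(m1 - m2) < 0.08

    def test_too_few_permutations_rejected(self, small_dataset):
        beta, _, _, labels = small_dataset
        design = bcsvd.standardize(beta, labels)
        with pytest.raises(ValueError):
            bcsvd.permutation_pvalues(design, b=5)


class TestSelect:
    def test_all_p_one_empty(self):
        res = [bcsvd.ProbeTestResult("p1", 0.0, "none", 1.0)]
        assert bcsvd.select_significant(res) == []

    def test_alpha_zero_empty(self):
        res = [bcsvd.ProbeTestResult("p1", 3.0, "hyper", 0.001)]
        assert bcsvd.select_significant(res, alpha=0.0) == []

    def test_strict_inequality_at_alpha(self):
        res = [bcsvd.ProbeTestResult("p1", 1.0, "hyper", 0.05)]
        assert bcsvd.select_significant(res, alpha=0.05) == []
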