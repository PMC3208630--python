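"""Phenotype rules, methylation-phenotype regression, multiple testing,
and gene-set over-representation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import comb

from pamethyl import association
from pamethyl.association import (
    bh_fdr,
    bonferroni,
    classify_phenotypes,
    derive_testosterone_threshold,
    enrichment,
    phenotype_regression,
)
from pamethyl.types import BetaMatrix


class TestClassifyPhenotypes:
    def _pheno(self, **cols):
        n = len(next(iter(cols.values())))
        base = {"sample_id": [f"s{i}" for i in range(n)]}
        base.update(cols)
        return pd.DataFrame(base)

    def test_cycle_length_rule(self):
        out = classify_phenotypes(self._pheno(cycle_length=[43, 34, 26, None]))
        assert out["cycle_status"].tolist()[:3] == [
            "intermittent", "normal", "normal",
        ]
        assert pd.isna(out["cycle_status"].iloc[3])

    def test_testosterone_threshold_inclusive(self):
        out = classify_phenotypes(self._pheno(testosterone=[0.32, 0.31, None]))
        assert out["hyperandrogenic"].tolist()[:2] == [True, False]
        assert pd.isna(out["hyperandrogenic"].iloc[2])

    def test_follicle_count_boundary(self):
        out = classify_phenotypes(self._pheno(follicle_count=[9, 10, 15]))
        assert out["pco"].tolist() == [False, True, True]

    def test_derived_threshold_is_control_mean_plus_sd(self):
        pheno = pd.DataFrame(
            {
                "sample_id": list("abcdef"),
                "group": ["control"] * 4 + ["PA"] * 2,
                "testosterone": [0.1, 0.2, 0.2, 0.3, 0.5, 0.6],
            }
        )
        t = pheno["testosterone"][:4]
        assert derive_testosterone_threshold(pheno) == pytest.approx(
            t.mean() + t.std(ddof=1)
        )

    def test_derived_threshold_needs_controls(self):
        pheno = pd.DataFrame(
            {"sample_id": ["a"], "group": ["PA"], "testosterone": [0.4]}
        )
        with pytest.raises(ValueError):
            derive_testosterone_threshold(pheno)


def _beta_and_pheno(values, phenotype):
    n, p = values.shape
    beta = BetaMatrix(values, [f"s{i}" for i in range(n)], [f"pr{j}" for j in range(p)])
    pheno = pd.DataFrame(
        {"sample_id": beta.sample_ids, "testosterone": phenotype}
    )
    return beta, pheno


class TestRegression:
    def test_perfect_linear_relationship(self):
        t = np.linspace(0.1, 0.5, 7)
        values = (0.2 + 1.0 * t).reshape(-1, 1)
        beta, pheno = _beta_and_pheno(values, t)
        out = phenotype_regression(beta, pheno, "testosterone", np.ones(7, bool))
        assert out.loc[0, "r"] == pytest.approx(1.0)
        assert out.loc[0, "p_raw"] < 1e-10

    def test_sign_antisymmetry_under_phenotype_negation(self, rng):
        values = rng.uniform(0.2, 0.8, (8, 5))
        t = rng.uniform(0.1, 0.6, 8)
        beta, pheno = _beta_and_pheno(values, t)
        out_pos = phenotype_regression(beta, pheno, "testosterone", np.ones(8, bool))
        pheno_neg = pheno.assign(testosterone=-pheno["testosterone"])
        out_neg = phenotype_regression(beta, pheno_neg, "testosterone", np.ones(8, bool))
        assert np.allclose(out_pos["r"], -out_neg["r"])
        assert np.allclose(out_pos["p_raw"], out_neg["p_raw"])

    def test_planted_slope_recovered_across_seeds(self):
        """Slope 0.5 with small noise at n=7: the average estimate sits
        within 3 standard errors of the truth."""
        estimates = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            t = r.uniform(0.1, 0.7, 7)
            y = (0.1 + 0.5 * t + r.normal(0, 0.02, 7)).clip(0, 1)
            beta, pheno = _beta_and_pheno(y.reshape(-1, 1), t)
            out = phenotype_regression(beta, pheno, "testosterone", np.ones(7, bool))
            estimates.append(out.loc[0, "slope"])
        mean = np.mean(estimates)
        se = np.std(estimates, ddof=1) / 10
        assert abs(mean - 0.5) < 3 * se

    def test_zero_variance_phenotype_skipped_with_reason(self):
        values = np.linspace(0.1, 0.8, 6).reshape(-1, 1)
        beta, pheno = _beta_and_pheno(values, np.full(6, 0.3))
        out = phenotype_regression(beta, pheno, "testosterone", np.ones(6, bool))
        assert out.loc[0, "skipped_reason"] == "constant_phenotype"
        assert np.isnan(out.loc[0, "p_raw"])

    def test_subset_restricts_samples(self):
        t = np.r_[np.linspace(0.1, 0.4, 5), np.linspace(0.1, 0.4, 5)]
        values = np.r_[0.2 + t[:5], np.full(5, 0.5)].reshape(-1, 1)
        beta, pheno = _beta_and_pheno(values, t)
        mask = np.r_[np.ones(5, bool), np.zeros(5, bool)]
        out = phenotype_regression(beta, pheno, "testosterone", mask)
        assert out.loc[0, "n"] == 5
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_null_calibration(self):
        """Independent phenotype: ~5% of raw p below 0.05 over replicates."""
        hits, total = 0, 0
        for seed in range(200):
            r = np.random.default_rng(seed)
            values = r.uniform(0.2, 0.8, (8, 5))
            t = r.uniform(0, 1, 8)
            beta, pheno = _beta_and_pheno(values, t)
            out = phenotype_regression(beta, pheno, "testosterone", np.ones(8, bool))
            hits += (out["p_raw"] < 0.05).sum()
            total += len(out)
        frac = hits / total
        assert abs(frac - 0.05) < 0.025  # 1000 correlated-ish tests


class TestCorrections:
    @pytest.mark.parametrize(
        "p,m,expected",
        [(0.01, 10, 0.1), (0.5, 10, 1.0), (0.3, 1, 0.3)],
    )
    def test_bonferroni_examples(self, p, m, expected):
        assert bonferroni(np.array([p]), m)[0] == pytest.approx(expected)

    def test_bonferroni_m_too_small_rejected(self):
        with pytest.raises(ValueError):
            bonferroni(np.array([0.1, 0.2]), 1)

    def test_bh_hand_computed_stepup(self):
        q = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_bh_equal_pvalues_unchanged(self):
        q = bh_fdr(np.full(5, 0.2))
        assert np.allclose(q, 0.2)

    def test_bh_singleton_identity(self):
        assert bh_fdr(np.array([0.37]))[0] == pytest.approx(0.37)

    def test_bh_dominates_raw_p(self, rng):
        p = rng.uniform(0, 1, 50)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-12)

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=2,
            max_size=30,
        )
    )
    def test_bh_invariant_to_input_order(self, pvals):
        p = np.array(pvals)
        q = bh_fdr(p)
        perm = np.random.default_rng(0).permutation(len(p))
        q_perm = bh_fdr(p[perm])
        assert np.allclose(q[perm], q_perm)


class TestEnrichment:
    def test_worked_ratio_example(self):
        """3 hits in a 26-gene set: ratio 0.12 at two decimals."""
        reference = [f"g{i}" for i in range(500)]
        gene_set = reference[:26]
        input_genes = reference[:3] + reference[400:420]
        res = enrichment(input_genes, {"path": gene_set}, reference)[0]
        assert res.k == 3
        assert round(res.ratio, 2) == 0.12

    def test_input_equal_reference_certain_event(self):
        reference = [f"g{i}" for i in range(40)]
        res = enrichment(reference, {"s": reference[:10]}, reference)[0]
        assert res.k == 10
        assert res.p_value == pytest.approx(1.0)

    def test_matches_exhaustive_hypergeometric_sum(self):
        """Reference 100, set 5, list 10, 3 hits: tail summed by hand."""
        reference = [f"g{i}" for i in range(100)]
        gene_set = reference[:5]
        input_genes = reference[:3] + reference[50:57]
        res = enrichment(input_genes, {"s": gene_set}, reference)[0]
        tail = sum(
            comb(5, j, exact=True) * comb(95, 10 - j, exact=True)
            for j in range(3, 6)
        ) / comb(100, 10, exact=True)
        assert res.p_value == pytest.approx(tail, rel=1e-12)

    def test_p_nonincreasing_in_k(self):
        reference = [f"g{i}" for i in range(200)]
        gene_set = reference[:20]
        ps = []
        for k in range(0, 6):
            input_genes = reference[:k] + reference[100 : 100 + (10 - k)]
            res = enrichment(input_genes, {"s": gene_set}, reference)[0]
            assert res.k == k
            ps.append(res.p_value)
        assert all(b <= a + 1e-12 for a, b in zip(ps, ps[1:]))

    def test_genes_outside_reference_dropped(self):
        reference = [f"g{i}" for i in range(50)]
        res = enrichment(
            ["g0", "g1", "NOT_ON_ARRAY"], {"s": reference[:10]}, reference
        )[0]
        assert res.list_size == 2

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            enrichment(["a"], {"s": ["a"]}, [])
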