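import numpy as np
import pytest

from diffperf.associations import (
    AssociationError,
    association_table,
    bh_fdr,
    chi_square_2x2,
    group_compare,
    partial_correlation,
)
from diffperf.synthetic import generate_cohort

from conftest import small_config


class TestPartialCorrelation:
    def test_no_covariates_reduces_to_pearson(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(2, 50))
        r, p = partial_correlation(x, y)
        expect = np.corrcoef(x, y)[0, 1]
        assert r == pytest.approx(expect, abs=1e-12)

    def test_identical_variables_give_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        r, p = partial_correlation(x, x)
        assert r == 1.0 and p == 0.0

    def test_recursive_formula_single_covariate(self):
        """r_xy.z = (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2))."""
        x = np.array([1.0, 2.0, 4.0, 3.5, 5.0, 7.0])
        y = np.array([2.0, 1.5, 3.0, 5.0, 4.0, 6.5])
        z = np.array([0.5, 1.0, 2.5, 2.0, 3.5, 4.0])
        r_xy = np.corrcoef(x, y)[0, 1]
        r_xz = np.corrcoef(x, z)[0, 1]
        r_yz = np.corrcoef(y, z)[0, 1]
        expect = (r_xy - r_xz * r_yz) / np.sqrt(
            (1 - r_xz ** 2) * (1 - r_yz ** 2)
        )
        r, _ = partial_correlation(x, y, z[:, None])
        assert r == pytest.approx(expect, abs=1e-10)

    def test_matches_residualization_oracle_and_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(2)
        for trial in range(10):
            n = 40
            C = rng.normal(size=(n, 3))
            x = C @ [0.5, -0.2, 0.1] + rng.normal(size=n)
            y = C @ [-0.3, 0.4, 0.2] + 0.5 * x + rng.normal(size=n)
            r, p = partial_correlation(x, y, C)
            df = pd.DataFrame(
                np.c_[x, y, C], columns=["x", "y", "c1", "c2", "c3"]
            )
            ref = pingouin.partial_corr(
                df, x="x", y="y", covar=["c1", "c2", "c3"]
            )
            assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
            assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_rank_deficient_covariates_rejected(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=(2, 20))
        C = np.ones((20, 2))  # collinear with the intercept
        with pytest.raises(AssociationError):
            partial_correlation(x, y, C)


class TestBhFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.037]), [0.037])

    def test_step_up_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_step_up_oracle(self):
        """q_(i) = min_{j>=i} p_(j) * m / j, returned in input order."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            p = rng.random(rng.integers(1, 30))
            m = len(p)
            order = np.argsort(p)
            q_sorted = np.minimum.accumulate(
                (p[order] * m / np.arange(1, m + 1))[::-1]
            )[::-1]
            expect = np.empty(m)
            expect[order] = np.minimum(q_sorted, 1.0)
            np.testing.assert_allclose(bh_fdr(p), expect, atol=1e-15)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(5)
        p = rng.random(25)
        assert np.all(bh_fdr(p) >= p)

    def test_out_of_range_rejected(self):
        with pytest.raises(AssociationError):
            bh_fdr([0.5, 1.2])


class TestGroupCompare:
    def test_normal_groups_use_t_branch(self):
        """Groups emulating published MoCA summaries (21.72 +/- 3.43 at
        n=74 vs 26.33 +/- 1.23 at n=39) separate at p < 0.001 via
        Welch's t (t ~ 10 in magnitude)."""
        rng = np.random.default_rng(6)
        g1 = rng.normal(21.72, 3.43, 74)
        g0 = rng.normal(26.33, 1.23, 39)
        vals = np.r_[g1, g0]
        labels = np.r_[np.ones(74), np.zeros(39)].astype(int)
        name, stat, p = group_compare(vals, labels)
        assert name == "welch-t"
        assert p < 0.001
        assert abs(stat) > 5

    def test_identical_groups_rank_sum_p_near_one(self):
        vals = np.r_[np.arange(20.0), np.arange(20.0)]
        # ranks are heavily tied -> rank-sum branch (uniform fails
        # Lilliefors at n=20 occasionally; force via heavy ties instead)
        labels = np.r_[np.ones(20), np.zeros(20)].astype(int)
        name, stat, p = group_compare(vals, labels)
        assert p > 0.9

    def test_heavy_tailed_data_uses_rank_sum(self):
        rng = np.random.default_rng(7)
        vals = rng.standard_cauchy(60)
        labels = rng.integers(0, 2, 60)
        while labels.sum() < 3 or labels.sum() > 57:
            labels = rng.integers(0, 2, 60)
        name, _, _ = group_compare(vals, labels)
        assert name == "wilcoxon-rank-sum"

    def test_constant_group_rejected(self):
        with pytest.raises(AssociationError):
            group_compare(
                np.r_[np.ones(5), np.arange(5.0)],
                np.r_[np.ones(5), np.zeros(5)].astype(int),
            )


class TestChiSquare:
    def test_identical_proportions_give_zero(self):
        stat, p = chi_square_2x2(np.array([[20, 10], [40, 20]]))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_published_sex_table_not_significant(self):
        # male/female counts by group: 57/17 vs 30/9
        stat, p = chi_square_2x2(np.array([[57, 17], [30, 9]]))
        assert p > 0.05

    def test_perfect_association(self):
        stat, p = chi_square_2x2(np.array([[10, 0], [0, 10]]))
        assert stat == pytest.approx(20.0)
        assert p < 0.001

    def test_zero_marginal_rejected(self):
        with pytest.raises(AssociationError):
            chi_square_2x2(np.array([[0, 0], [5, 5]]))


class TestAssociationTable:
    def test_grid_shape(self, small_cohort):
        features = [f.column for f in small_cohort.feature_index[:13]]
        records = association_table(
            small_cohort, features, ["TMT_A", "TMT_B", "Stroop_CT", "VFT"]
        )
        assert len(records) == 52  # 13 features x 4 tests
        assert all(r.group == "vMCI" for r in records)
        assert all(r.p_fdr >= r.p_raw - 1e-15 for r in records)

    def test_planted_association_recovered(self):
        hits, errs = 0, []
        feature = "diffusion__FA__genu_of_corpus_callosum"
        for seed in range(10):
            cohort = generate_cohort(small_config(seed=seed))
            records = association_table(cohort, [feature], ["TMT_B"])
            rec = records[0]
            errs.append(abs(rec.r - (-0.45)))
            hits += rec.significant
        # planted r = -0.45 at n = 40; estimates within sampling error
        assert np.median(errs) < 0.15
        assert hits >= 6

    def test_fdr_family_options(self, small_cohort):
        features = [f.column for f in small_cohort.feature_index[:5]]
        per_test = association_table(
            small_cohort, features, ["TMT_A", "TMT_B"], fdr_family="per_test"
        )
        table = association_table(
            small_cohort, features, ["TMT_A", "TMT_B"], fdr_family="table"
        )
        assert len(per_test) == len(table) == 10
        # raw p identical, adjusted p may differ
        np.testing.assert_allclose(
            [r.p_raw for r in per_test], [r.p_raw for r in table]
        )

    def test_empty_feature_set_rejected(self, small_cohort):
        with pytest.raises(AssociationError):
            association_table(small_cohort, [], ["TMT_A"])
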