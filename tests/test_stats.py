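"""Agreement/discrimination statistics against independent oracles:
pingouin (ICC), scipy (chi-square, Mann-Whitney, Spearman), brute-force
all-pairs AUC, and hand-computed ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hepafe.stats import (
    Contingency2x2,
    chi_square_2x2,
    compare_auc_paired,
    delong_auc_variance,
    group_compare,
    icc_two_way,
    mean_difference_test,
    rating_matrix,
    roc_auc,
    spearman_rho,
    validate_rating_table,
)

pingouin = pytest.importorskip("pingouin")


def allpairs_auc(scores, labels):
    """Brute-force AUC: mean over all (pos, neg) pairs with ties at 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (pos.size * neg.size)


@pytest.fixture
def ratings_df(rng):
    rows = []
    truth = rng.uniform(1, 20, 12)
    for i, t in enumerate(truth):
        for rater in (1, 2):
            for rep in (1, 2) if rater == 1 else (1,):
                rows.append(
                    dict(
                        subject_id=f"S{i:03d}",
                        group="patient" if i < 8 else "control",
                        method="manual_t2s",
                        rater=rater,
                        repeat=rep,
                        estimate=t + rng.normal(0, 0.5),
                    )
                )
    return pd.DataFrame(rows)


class TestRatingTable:
    def test_validate_passes_and_duplicates_rejected(self, ratings_df):
        validate_rating_table(ratings_df)
        dup = pd.concat([ratings_df, ratings_df.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            validate_rating_table(dup)

    def test_matrix_shapes(self, ratings_df):
        by_rater = rating_matrix(ratings_df, "manual_t2s", by="rater")
        by_rep = rating_matrix(ratings_df, "manual_t2s", by="repeat")
        assert by_rater.shape == (12, 2) and by_rep.shape == (12, 2)

    def test_missing_cell_raises(self, ratings_df):
        with pytest.raises(ValueError, match="missing"):
            rating_matrix(ratings_df.iloc[1:], "manual_t2s", by="rater")


class TestICC:
    def table(self, rng, n=30, k=2, noise=1.0):
        truth = rng.uniform(0, 20, n)
        return truth[:, None] + rng.normal(0, noise, (n, k))

    def test_matches_pingouin_a1(self, rng):
        x = self.table(rng)
        got = icc_two_way(x, definition="A-1")
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(x.shape[0]), x.shape[1]),
                "rater": np.tile(np.arange(x.shape[1]), x.shape[0]),
                "score": x.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(df, "subject", "rater", "score")
        ref_row = ref[ref["Type"] == "ICC(A,1)"].iloc[0]
        assert got.icc == pytest.approx(ref_row["ICC"], abs=1e-9)
        # pingouin rounds the CI to 2 decimals
        assert got.ci95[0] == pytest.approx(ref_row["CI95"][0], abs=5e-3)
        assert got.ci95[1] == pytest.approx(ref_row["CI95"][1], abs=5e-3)

    def test_matches_pingouin_c1(self, rng):
        x = self.table(rng)
        got = icc_two_way(x, definition="C-1")
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(x.shape[0]), x.shape[1]),
                "rater": np.tile(np.arange(x.shape[1]), x.shape[0]),
                "score": x.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(df, "subject", "rater", "score")
        ref_row = ref[ref["Type"] == "ICC(C,1)"].iloc[0]
        assert got.icc == pytest.approx(ref_row["ICC"], abs=1e-9)

    def test_identical_raters_perfect_agreement(self):
        x = np.tile(np.arange(10.0)[:, None], (1, 3))
        got = icc_two_way(x)
        assert got.icc == 1.0 and got.ci95 == (1.0, 1.0)

    def test_constant_offset_lowers_absolute_agreement_only(self, rng):
        truth = rng.uniform(0, 20, 40)
        x = np.column_stack([truth, truth + 3.0])
        a1 = icc_two_way(x, definition="A-1").icc
        c1 = icc_two_way(x, definition="C-1").icc
        assert c1 == pytest.approx(1.0, abs=1e-9)
        assert a1 < 0.95

    def test_pure_noise_icc_near_zero(self, rng):
        x = rng.normal(0, 1, (200, 2))
        got = icc_two_way(x)
        assert abs(got.icc) < 0.2
        assert got.ci95[0] < got.icc < got.ci95[1]

    def test_nan_rejected(self):
        x = np.ones((5, 2))
        x[0, 0] = np.nan
        with pytest.raises(ValueError):
            icc_two_way(x)


class TestMeanDifference:
    def test_zero_difference(self):
        a = np.arange(10.0)
        mean, ci, p = mean_difference_test(a, a)
        assert mean == 0 and p == 1.0

    def test_matches_scipy_paired_t(self, rng):
        a = rng.normal(10, 2, 25)
        b = a + rng.normal(0.5, 1, 25)
        mean, ci, p = mean_difference_test(a, b)
        ref = sps.ttest_rel(a, b)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)
        assert mean == pytest.approx((a - b).mean())
        assert ci[0] < mean < ci[1]


class TestROC:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0

    def test_matches_allpairs_oracle_with_ties(self, rng):
        scores = rng.integers(0, 10, 80).astype(float)  # heavy ties
        labels = rng.integers(0, 2, 80)
        labels[:2] = [0, 1]
        res = roc_auc(scores, labels)
        assert res.auc == pytest.approx(allpairs_auc(scores, labels), abs=1e-12)

    def test_delong_variance_against_bootstrap(self, rng):
        scores = rng.normal(0, 1, 100) + np.repeat([0.0, 1.2], 50)
        labels = np.repeat([0, 1], 50)
        auc, var = delong_auc_variance(scores, labels)
        boots = []
        for _ in range(2000):
            idx = rng.integers(0, 100, 100)
            if len(set(labels[idx])) < 2:
                continue
            boots.append(allpairs_auc(scores[idx], labels[idx]))
        assert np.sqrt(var) == pytest.approx(np.std(boots), rel=0.25)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])

    def test_paired_comparison_identical_scores(self, rng):
        s = rng.normal(0, 1, 40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        diff, p = compare_auc_paired(s, s, y)
        assert diff == 0 and p == 1.0

    def test_paired_comparison_detects_noise_channel(self, rng):
        truth = np.repeat([0, 1], 60)
        good = truth + rng.normal(0, 0.3, 120)
        bad = truth + rng.normal(0, 3.0, 120)
        diff, p = compare_auc_paired(good, bad, truth)
        assert diff > 0 and p < 0.01


class TestClassicalTests:
    def test_chi_square_yates_matches_scipy(self):
        tab = Contingency2x2(((23, 30), (12, 9)))
        stat, p = chi_square_2x2(tab)
        ref = sps.chi2_contingency(tab.array, correction=True)
        assert stat == pytest.approx(ref[0]) and p == pytest.approx(ref[1])

    def test_correction_toggle(self):
        tab = ((23, 30), (12, 9))
        _, p_y = chi_square_2x2(np.asarray(tab), correction=True)
        _, p_n = chi_square_2x2(np.asarray(tab), correction=False)
        assert p_y != p_n

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2(np.array([[0, 0], [3, 4]]))

    def test_noninteger_cells_rejected(self):
        with pytest.raises(ValueError):
            Contingency2x2(((1.5, 2), (3, 4)))

    def test_spearman_monotone_transform_invariance(self, rng):
        x = rng.uniform(1, 10, 30)
        y = x**3  # monotone: rho must be exactly 1
        rho, p = spearman_rho(x, y)
        assert rho == pytest.approx(1.0)
        assert p < 1e-10

    def test_spearman_constant_rejected(self, rng):
        with pytest.raises(ValueError):
            spearman_rho(np.ones(10), rng.normal(0, 1, 10))


class TestGroupCompare:
    def test_normal_data_routes_to_t(self, rng):
        v = np.concatenate([rng.normal(0, 1, 40), rng.normal(1, 1, 40)])
        g = np.repeat(["a", "b"], 40)
        res = group_compare(v, g)
        assert res.test == "t"
        ref = sps.ttest_ind(v[:40], v[40:], equal_var=True)
        assert res.p == pytest.approx(ref.pvalue)

    def test_skewed_data_routes_to_mann_whitney(self, rng):
        v = np.concatenate([rng.lognormal(0, 1.2, 50), rng.lognormal(1, 1.2, 50)])
        g = np.repeat(["a", "b"], 50)
        res = group_compare(v, g)
        assert res.test == "mann-whitney"
        assert min(res.shapiro_p) <= 0.05

    def test_three_groups_rejected(self, rng):
        with pytest.raises(ValueError):
            group_compare(rng.normal(0, 1, 9), np.repeat(["a", "b", "c"], 3))
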