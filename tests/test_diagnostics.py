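"""Statistical battery: rank tests, ROC/Youden, logistic fit, sample size."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ihcquant import (
    SampleSizeSpec,
    ValidationError,
    benjamini_hochberg,
    combine_markers,
    kruskal_wallis,
    pairwise_wilcoxon,
    roc,
    sample_size,
    youden,
)

from _oracles import (
    auc_bruteforce,
    bh_bruteforce,
    kruskal_bruteforce,
    ranksum_exact_p,
    ranksum_normal_p,
    ranksum_W,
    youden_bruteforce,
)


def make_table(groups: dict, marker="ACSL4") -> pd.DataFrame:
    rows = []
    for cls, vals in groups.items():
        for i, v in enumerate(vals):
            rows.append({"sample_id": f"{cls}{i}", "tissue_class": cls,
                         "marker": marker, "score": float(v)})
    return pd.DataFrame(rows)


small_scores = st.lists(
    st.integers(0, 6).map(float), min_size=3, max_size=8
)


class TestKruskalWallis:
    def test_three_separated_groups(self):
        tab = make_table({"HCC": [1, 2, 3], "CCA": [4, 5, 6], "MET": [7, 8, 9]})
        res = kruskal_wallis(tab, "ACSL4")
        assert res.H == pytest.approx(7.2)
        assert res.df == 2
        assert res.mean_ranks == {"CCA": 5.0, "HCC": 2.0, "MET": 8.0}

    def test_identical_groups_give_zero(self):
        tab = make_table({"HCC": [1, 2], "CONTROL": [1, 2]})
        res = kruskal_wallis(tab, "ACSL4")
        assert res.H == pytest.approx(0.0, abs=1e-12)

    def test_all_observations_identical(self):
        tab = make_table({"HCC": [3, 3], "CONTROL": [3, 3, 3]})
        res = kruskal_wallis(tab, "ACSL4")
        assert res.H == 0.0 and res.p_value == 1.0

    @given(small_scores, small_scores, small_scores)
    @settings(max_examples=100, deadline=None)
    def test_matches_bruteforce_midranks(self, a, b, c):
        tab = make_table({"A": a, "B": b, "C": c})
        if np.ptp(np.concatenate([a, b, c])) == 0:
            return  # degenerate case covered above
        res = kruskal_wallis(tab, "ACSL4")
        h_oracle, df_oracle = kruskal_bruteforce([a, b, c])
        assert res.H == pytest.approx(h_oracle, abs=1e-9)
        assert res.df == df_oracle
        assert res.p_value == pytest.approx(
            stats.chi2.sf(h_oracle, df_oracle), abs=1e-9
        )


class TestPairwiseWilcoxon:
    def test_small_untied_samples_use_exact_p(self):
        tab = make_table({"HCC": [1, 2], "CONTROL": [3, 4]})
        res = pairwise_wilcoxon(tab, "ACSL4")
        row = res.table.iloc[0]
        assert row["W"] == 3.0  # smaller rank sum
        assert row["p_raw"] == pytest.approx(1 / 3)

    def test_identical_samples_p_one(self):
        tab = make_table({"HCC": [5, 5, 5], "CONTROL": [5, 5]})
        res = pairwise_wilcoxon(tab, "ACSL4")
        assert res.table.iloc[0]["p_raw"] == 1.0

    def test_adjusted_never_below_raw_and_monotone(self, rng):
        tab = make_table({c: rng.lognormal(i * 0.5, 1, 8) for i, c in
                          enumerate(["CONTROL", "CCA", "MET", "HCC"])})
        res = pairwise_wilcoxon(tab, "ACSL4")
        df = res.table.sort_values("p_raw")
        assert (df["p_adj"] >= df["p_raw"] - 1e-15).all()
        assert (df["p_adj"].diff().dropna() >= -1e-15).all()
        assert (df["p_adj"] <= 1).all()

    def test_bonferroni_option(self):
        tab = make_table({"HCC": [1, 2], "CONTROL": [3, 4], "CCA": [2, 3]})
        bh = pairwise_wilcoxon(tab, "ACSL4", adjust="bh").table
        bf = pairwise_wilcoxon(tab, "ACSL4", adjust="bonferroni").table
        assert (bf["p_adj"] >= bh["p_adj"] - 1e-15).all()

    @given(small_scores, small_scores)
    @settings(max_examples=100, deadline=None)
    def test_statistic_and_exact_p_match_enumeration(self, x, y):
        tab = make_table({"A": x, "B": y})
        res = pairwise_wilcoxon(tab, "ACSL4", method="auto")
        row = res.table.iloc[0]
        assert row["W"] == pytest.approx(ranksum_W(x, y), abs=1e-9)
        if np.unique(np.concatenate([x, y])).size == len(x) + len(y):
            # untied small samples: implementation takes the exact path
            assert row["p_raw"] == pytest.approx(ranksum_exact_p(x, y), abs=1e-9)

    @given(
        st.lists(st.integers(0, 1000), min_size=6, max_size=16, unique=True),
        st.integers(3, 8),
    )
    @settings(max_examples=60, deadline=None)
    def test_normal_approximation_close_to_exact_for_small_n(self, pool, n1):
        # continuous (untied) samples, 3-8 per group: the tie-corrected
        # continuity-corrected normal p tracks the exact enumeration p
        n1 = min(n1, len(pool) - 3)
        x = [float(v) for v in pool[:n1]]
        y = [float(v) for v in pool[n1:]]
        tab = make_table({"A": x, "B": y})
        p_asym = pairwise_wilcoxon(tab, "ACSL4", method="asymptotic").table.iloc[0]["p_raw"]
        assert p_asym == pytest.approx(ranksum_normal_p(x, y), abs=1e-9)
        assert abs(p_asym - ranksum_exact_p(x, y)) <= 0.05


class TestBenjaminiHochberg:
    def test_worked_example(self):
        adj = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    @settings(max_examples=100)
    def test_matches_stepup_oracle(self, ps):
        adj = benjamini_hochberg(ps)
        assert adj == pytest.approx(bh_bruteforce(ps), abs=1e-12)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)
        # monotone: adjustment preserves the raw ordering
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestROC:
    def test_pair_counting_example(self):
        res = roc([3, 5, 1, 4], [1, 1, 0, 0])
        assert res.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        res = roc([10, 11, 1, 2], [1, 1, 0, 0])
        assert res.auc == 1.0

    def test_all_ties(self):
        res = roc([5, 5, 5, 5], [1, 1, 0, 0])
        assert res.auc == 0.5

    def test_one_class_errors(self):
        with pytest.raises(ValidationError):
            roc([1, 2, 3], [1, 1, 1])

    def test_ci_contains_auc_and_is_truncated(self, rng):
        s = rng.normal(size=40) + np.repeat([0, 1.5], 20)
        y = np.repeat([0, 1], 20)
        for method in ("delong", "bootstrap"):
            res = roc(s, y, ci=method, seed=11)
            lo, hi = res.auc_ci
            assert 0 <= lo <= res.auc <= hi <= 1

    def test_bootstrap_ci_reproducible(self, rng):
        s = rng.normal(size=30) + np.repeat([0, 1.0], 15)
        y = np.repeat([0, 1], 15)
        a = roc(s, y, ci="bootstrap", seed=5)
        b = roc(s, y, ci="bootstrap", seed=5)
        assert a.auc_ci == b.auc_ci

    @given(
        st.lists(st.integers(0, 8), min_size=1, max_size=8),
        st.lists(st.integers(0, 8), min_size=1, max_size=8),
    )
    @settings(max_examples=150, deadline=None)
    def test_auc_equals_bruteforce_pairs(self, pos, neg):
        scores = np.array(pos + neg, float)
        labels = np.array([1] * len(pos) + [0] * len(neg))
        res = roc(scores, labels)
        assert res.auc == pytest.approx(auc_bruteforce(pos, neg), abs=1e-12)
        # trapezoid along the curve (traversed in threshold order, fpr
        # non-decreasing) equals the pair statistic
        fpr = (1 - res.specificity)[::-1]
        sens = res.sensitivity[::-1]
        assert np.trapezoid(sens, fpr) == pytest.approx(res.auc, abs=1e-12)


class TestYouden:
    def test_tie_broken_toward_lowest_threshold(self):
        res = youden(roc([3, 5, 1, 4], [1, 1, 0, 0]))
        assert res.optimal_threshold == pytest.approx(2.0)
        assert res.sensitivity == 1.0 and res.specificity == 0.5
        assert res.J == pytest.approx(0.5)

    def test_perfect_separation(self):
        res = youden(roc([10, 11, 1, 2], [1, 1, 0, 0]))
        assert res.J == 1.0 and res.sensitivity == 1.0 and res.specificity == 1.0

    def test_identical_scores_give_zero_J(self):
        res = youden(roc([5, 5, 5, 5], [1, 0, 1, 0]))
        assert res.J == pytest.approx(0.0)

    @given(
        st.lists(st.integers(0, 8), min_size=1, max_size=8),
        st.lists(st.integers(0, 8), min_size=1, max_size=8),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_exhaustive_scan(self, pos, neg):
        scores = np.array(pos + neg, float)
        labels = np.array([1] * len(pos) + [0] * len(neg))
        res = youden(roc(scores, labels))
        j, t, sens, spec = youden_bruteforce(pos, neg)
        assert res.J == pytest.approx(j, abs=1e-12)
        assert res.optimal_threshold == pytest.approx(t)
        assert res.sensitivity == pytest.approx(sens)
        assert res.specificity == pytest.approx(spec)


class TestCombineMarkers:
    def test_grouped_2x2_closed_form(self):
        x = np.array([1.0] * 50 + [0.0] * 50)
        y = np.array([1] * 30 + [0] * 20 + [1] * 10 + [0] * 40)
        model = combine_markers(x, np.zeros(100), y, names=("A", "B"))
        assert model.converged and not model.separation
        assert model.coefficients["A"] == pytest.approx(np.log(6), abs=1e-6)
        assert model.intercept == pytest.approx(np.log(10 / 40), abs=1e-6)
        assert model.coefficients["B"] == 0.0  # constant marker dropped

    def test_symmetric_design_zero_intercept(self):
        x = np.array([-2, -1, 1, 2], float)
        y = np.array([0, 0, 1, 1])
        # mirror-symmetric: both label assignments present, odd predictors
        x_full = np.concatenate([x, x])
        y_full = np.concatenate([y, 1 - y])
        model = combine_markers(x_full, x_full**3, y_full, names=("A", "B"))
        assert model.converged
        assert model.intercept == pytest.approx(0.0, abs=1e-8)

    def test_separation_flagged(self):
        x = np.array([0, 1, 2, 10, 11, 12], float)
        y = np.array([0, 0, 0, 1, 1, 1])
        model = combine_markers(x, x[::-1] * 0 + 1.0, y, names=("A", "B"))
        assert model.separation
        assert not model.converged

    def test_matches_statsmodels_ml_fit(self, rng):
        import statsmodels.api as sm

        x1 = rng.normal(size=120)
        x2 = rng.normal(size=120)
        y = (rng.random(120) < 1 / (1 + np.exp(-(0.5 + x1 - 0.7 * x2)))).astype(int)
        model = combine_markers(x1, x2, y, names=("A", "B"))
        ref = sm.Logit(y, np.column_stack([np.ones(120), x1, x2])).fit(disp=0)
        assert model.intercept == pytest.approx(ref.params[0], abs=1e-6)
        assert model.coefficients["A"] == pytest.approx(ref.params[1], abs=1e-6)
        assert model.coefficients["B"] == pytest.approx(ref.params[2], abs=1e-6)

    def test_score_equations_satisfied_at_optimum(self, rng):
        x1 = rng.normal(size=80)
        x2 = rng.normal(size=80)
        logit = -0.3 + 0.8 * x1 + 0.5 * x2
        y = (rng.random(80) < 1 / (1 + np.exp(-logit))).astype(int)
        model = combine_markers(x1, x2, y, names=("A", "B"))
        assert model.converged
        X = np.column_stack([np.ones(80), x1, x2])
        beta = np.array([model.intercept, model.coefficients["A"], model.coefficients["B"]])
        grad = X.T @ (y - 1 / (1 + np.exp(-(X @ beta))))
        assert np.abs(grad).max() <= 1e-8
        assert np.all((model.probabilities > 0) & (model.probabilities < 1))


class TestSampleSize:
    def test_published_unequal_allocation_design(self):
        spec = SampleSizeSpec(p1=0.80, p2=0.20, alpha=0.05, power=0.80, ratio=10)
        assert sample_size(spec) == (43, 4)

    def test_equal_allocation(self):
        spec = SampleSizeSpec(p1=0.80, p2=0.20, alpha=0.05, power=0.80, ratio=1)
        assert sample_size(spec) == (10, 10)

    def test_ceiling_option(self):
        spec = SampleSizeSpec(p1=0.80, p2=0.20, ratio=10)
        assert sample_size(spec, rounding="ceil") == (44, 5)

    def test_monotone_in_effect_size(self):
        sizes = [
            sample_size(SampleSizeSpec(p1=0.5 + d, p2=0.5 - d, ratio=2))
            for d in (0.3, 0.2, 0.1, 0.05)
        ]
        totals = [a + b for a, b in sizes]
        assert totals == sorted(totals)
        assert totals[0] < totals[-1]

    def test_equal_proportions_rejected(self):
        with pytest.raises(ValidationError):
            SampleSizeSpec(p1=0.5, p2=0.5)
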