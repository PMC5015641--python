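"""Cohort statistics: prevalence, agreement, comparison, summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from spiroref import (
    LLNPolicy,
    StratumSpec,
    chi_square,
    cohen_kappa,
    crosstab_flags,
    crosstab_grades,
    interpret_cohort,
    paired_t,
    prevalence,
    severity_distribution,
    summarize_percent_predicted,
    zscore_difference_summary,
)
from spiroref.cohort import DegenerateAgreementError
from spiroref.simulate import scale_median


@pytest.fixture(scope="module")
def interp(small_cohort, lms_set):
    return interpret_cohort(small_cohort, lms_set)


class TestPrevalence:
    def _toy(self, flags, ages=None, sexes=None):
        n = len(flags)
        return pd.DataFrame({
            "id": [str(i) for i in range(n)],
            "sex": sexes if sexes is not None else ["male"] * n,
            "age": ages if ages is not None else [40.0] * n,
            "obstruction": flags,
            "possible_restriction": [False] * n,
            "decreased_vc": [False] * n,
            "isolated_reduced_fev1": [False] * n,
            "extrapolated": [False] * n,
        })

    def test_hand_counted_rate(self):
        interp = self._toy([True] * 3 + [False] * 37)
        table = prevalence(interp, "obstruction", StratumSpec())
        all_row = table[(table.sex == "all") & (table.age_stratum == "all")]
        assert all_row["count"].item() == 3
        assert all_row["n"].item() == 40
        assert all_row["prevalence"].item() == pytest.approx(7.5)

    def test_zero_abnormal_gives_zero_everywhere(self, interp):
        table = prevalence(interp.assign(obstruction=False), "obstruction")
        assert (table["prevalence"].dropna() == 0).all()

    def test_age_stratum_filters_but_all_keeps(self):
        interp = self._toy([True, False], ages=[70.0, 40.0])
        spec = StratumSpec(age_bins=((21, 65),))
        table = prevalence(interp, "obstruction", spec).set_index(
            ["sex", "age_stratum"])
        assert table.loc[("all", "all"), "n"] == 2
        assert table.loc[("all", "21-65"), "n"] == 1
        assert table.loc[("all", "21-65"), "count"] == 0

    def test_empty_stratum_marked_undefined(self):
        interp = self._toy([False], ages=[40.0], sexes=["male"])
        table = prevalence(interp, "obstruction", StratumSpec()).set_index(
            ["sex", "age_stratum"])
        row = table.loc[("female", "all")]
        assert row["n"] == 0
        assert np.isnan(row["prevalence"])

    def test_partitioning_strata_sum_to_all(self, interp):
        spec = StratumSpec(age_bins=((21, 47), (47.000001, 74)))
        table = prevalence(interp, "decreased_vc", spec)
        sub = table[table.sex == "all"].set_index("age_stratum")
        assert (sub.drop(index="all")["count"].sum()
                == sub.loc["all", "count"])
        assert sub.drop(index="all")["n"].sum() == sub.loc["all", "n"]

    def test_overlapping_bins_rejected(self):
        with pytest.raises(ValueError):
            StratumSpec(age_bins=((21, 50), (45, 74)))


class TestCohenKappa:
    def test_perfect_agreement(self):
        res = cohen_kappa(["a", "b", "a", "b"], ["a", "b", "a", "b"])
        assert res.kappa == pytest.approx(1.0)
        assert res.p_o == pytest.approx(1.0)

    def test_hand_computed_symmetric_table(self):
        # confusion matrix [[40, 10], [10, 40]]: p_o = 0.8, p_e = 0.5
        a = [0] * 50 + [1] * 50
        b = [0] * 40 + [1] * 10 + [0] * 10 + [1] * 40
        res = cohen_kappa(a, b)
        assert res.p_o == pytest.approx(0.8)
        assert res.p_e == pytest.approx(0.5)
        assert res.kappa == pytest.approx(0.6)

    def test_constant_rater_gives_zero(self):
        a = ["normal"] * 100
        b = ["normal"] * 50 + ["abnormal"] * 50
        res = cohen_kappa(a, b)
        assert res.p_o == pytest.approx(0.5)
        assert res.p_e == pytest.approx(0.5)
        assert res.kappa == pytest.approx(0.0)

    def test_identical_constants_undefined(self):
        with pytest.raises(DegenerateAgreementError):
            cohen_kappa(["x"] * 10, ["x"] * 10)

    def test_relabelling_invariance(self, rng):
        a = rng.integers(0, 3, size=200)
        b = rng.integers(0, 3, size=200)
        relabel = {0: "u", 1: "v", 2: "w"}
        k1 = cohen_kappa(a, b).kappa
        k2 = cohen_kappa([relabel[x] for x in a],
                         [relabel[x] for x in b]).kappa
        assert k1 == pytest.approx(k2, abs=1e-12)

    def test_matches_sklearn_on_random_vectors(self, rng):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        for _ in range(50):
            a = rng.integers(0, 4, size=100)
            b = (a + rng.integers(0, 2, size=100)) % 4
            res = cohen_kappa(a, b)
            expected = sklearn_metrics.cohen_kappa_score(a, b)
            assert res.kappa == pytest.approx(expected, abs=1e-12)
            assert res.kappa == pytest.approx(
                (res.p_o - res.p_e) / (1 - res.p_e), abs=1e-12)


class TestChiSquare:
    def test_uniform_table_is_null(self):
        stat, p, df = chi_square([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # expected counts all 15 -> statistic 4 * 25/15 = 20/3
        stat, p, df = chi_square([[10, 20], [20, 10]])
        assert stat == pytest.approx(20 / 3)
        assert df == 1

    def test_doubling_cells_doubles_statistic(self, rng):
        table = rng.integers(5, 30, size=(2, 3))
        s1, _, _ = chi_square(table)
        s2, _, _ = chi_square(2 * table)
        assert s2 == pytest.approx(2 * s1)

    def test_zero_expected_suggests_merge(self):
        with pytest.raises(ValueError, match="merge"):
            chi_square([[0, 0], [5, 5]])

    def test_agrees_with_reference_implementation(self, rng):
        for _ in range(100):
            table = rng.integers(1, 50, size=(rng.integers(2, 4),
                                              rng.integers(2, 4)))
            stat, p, df = chi_square(table)
            ref = sps.chi2_contingency(table, correction=False)
            assert stat == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)


class TestPairedT:
    def test_hand_computed(self):
        # differences [1, 1, 1, -1]: mean 0.5, sd 1, t = 0.5/(1/2) = 1
        t, p, df = paired_t([2, 2, 2, 0], [1, 1, 1, 1])
        assert t == pytest.approx(1.0)
        assert df == 3

    def test_reversal_negates_statistic(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        t1, p1, _ = paired_t(a, b)
        t2, p2, _ = paired_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_identical_vectors_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_agrees_with_reference_implementation(self, rng):
        for _ in range(100):
            a = rng.normal(size=25)
            b = a + rng.normal(0.3, 1.0, size=25)
            t, p, df = paired_t(a, b)
            ref = sps.ttest_rel(a, b)
            assert t == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)


class TestSummaries:
    def test_percent_predicted_sd_matches_lms_spread(self, lms_set):
        """Healthy z ~ N(0,1) with L ~ 1: %pred ~ 100(1 + S z), so the
        sample SD of %pred approaches 100 S."""
        from spiroref import CohortConfig, generate_cohort
        config = CohortConfig(seed=5, mode="marginal",
                              strata=[{"centre": "X", "n": 20_000}])
        cohort, _ = generate_cohort(config, lms_set)
        interp = interpret_cohort(cohort, lms_set, drop_invalid=False)
        table = summarize_percent_predicted({"truth": interp})
        for sex in ("male", "female"):
            row = table[(table.sex == sex) & (table["index"] == "fvc")]
            c = lms_set.coefficients[(sex, "fvc")]
            ref_age = 48.0
            S = np.exp(c.s_intercept + c.s_lnage * np.log(ref_age)
                       + np.interp(ref_age, c.spline_age, c.spline_s))
            assert row["pctpred_mean"].item() == pytest.approx(100.0, abs=1.0)
            assert row["pctpred_sd"].item() == pytest.approx(100 * S, rel=0.12)

    def test_single_subject_sd_undefined(self, lms_set):
        cohort = pd.DataFrame({
            "id": ["a"], "sex": ["male"], "age": [40.0], "height": [178.0],
            "fev1": [4.0], "fvc": [5.0]})
        table = summarize_percent_predicted(
            {"x": interpret_cohort(cohort, lms_set)})
        male_fev1 = table[(table.sex == "male") & (table["index"] == "fev1")]
        assert np.isnan(male_fev1["pctpred_sd"].item())

    def test_severity_distribution_partitions(self, interp):
        table = severity_distribution(interp)
        for sex in ("male", "female"):
            total = table[table.sex == sex]["proportion"].sum()
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_all_healthy_cohort_all_normal(self, interp):
        healthy = interp.copy()
        healthy["severity"] = pd.Categorical(
            ["normal"] * len(healthy),
            categories=interp["severity"].cat.categories)
        table = severity_distribution(healthy, by_sex=False)
        normal = table[table.grade == "normal"]["proportion"].item()
        assert normal == pytest.approx(1.0)


class TestCrosstabs:
    def test_self_crosstab_is_diagonal(self, interp):
        table = crosstab_grades(interp, interp)
        mat = table.to_numpy()
        assert mat.sum() == len(interp)
        assert (mat - np.diag(np.diag(mat)) == 0).all()

    def test_kappa_of_self_crosstab(self, interp, lms_set, small_cohort):
        # perturb the model so at least two grades occur, then self-agreement
        shifted = scale_median(lms_set, 1.25)
        interp_b = interpret_cohort(small_cohort, shifted)
        assert interp_b["severity"].nunique() >= 2
        assert cohen_kappa(interp_b["severity"],
                           interp_b["severity"]).kappa == pytest.approx(1.0)

    def test_small_offset_stays_near_diagonal(self, small_cohort, lms_set):
        # 5th-percentile policy: the mild band is non-empty, so all grade
        # bands are wider than the z perturbation a 2% offset induces
        policy = LLNPolicy(5, "convention")
        offset = scale_median(lms_set, 1.02)
        a = interpret_cohort(small_cohort, lms_set, policy)
        b = interpret_cohort(small_cohort, offset, policy)
        table = crosstab_grades(a, b).to_numpy()
        # mass only on the diagonal and its immediate neighbours
        off = table.copy()
        for k in (-1, 0, 1):
            off -= np.diag(np.diag(off, k=k), k=k)
        assert off.sum() == 0

    def test_misaligned_cohorts_rejected(self, interp):
        other = interp.iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError, match="align"):
            crosstab_grades(interp, other)

    def test_flag_crosstab_marginals(self, interp, small_cohort, lms_set):
        b = interpret_cohort(small_cohort, scale_median(lms_set, 1.1))
        table = crosstab_flags(interp, b, "decreased_vc")
        assert table.to_numpy().sum() == len(interp)


class TestZDiffSummary:
    def test_self_comparison_zero(self, interp):
        table = zscore_difference_summary(interp, interp)
        assert (table["mean_delta_z"] == 0).all()
        assert (table["frac_flagged"] == 0).all()

    def test_offset_pair_fully_flagged(self, small_cohort, lms_set):
        # 10% median offset with S ~ 0.12 gives |delta z| ~ 0.8 >> 0.3
        offset = scale_median(lms_set, 1.1)
        a = interpret_cohort(small_cohort, lms_set)
        b = interpret_cohort(small_cohort, offset)
        table = zscore_difference_summary(a, b).set_index("index")
        assert table.loc["fvc", "frac_flagged"] == pytest.approx(1.0)
        # truth z sits ~0.76 SD above the inflated-median model's z
        assert table.loc["fvc", "mean_delta_z"] > 0.3
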