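"""Internal consistency, interrater reliability, correlations, effect sizes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from orsim import (
    DomainError,
    cronbach_alpha,
    effect_size_table,
    icc,
    instrument_effect_sizes,
    item_total_analysis,
    reliability_report,
    spearman,
)
from orsim.psychometrics import FLAG_INCALCULABLE, FLAG_NOT_SIGNIFICANT
from orsim.synthetic import RaterModel, generate_rating_table


# ---------------------------------------------------------------------------
# Independent oracles (plain-loop recomputations, no shared code paths)
# ---------------------------------------------------------------------------

def alpha_oracle(X):
    n, k = X.shape
    totals = [sum(row) for row in X]
    mean_t = sum(totals) / n
    var_t = sum((t - mean_t) ** 2 for t in totals) / (n - 1)
    sum_item_var = 0.0
    for j in range(k):
        col = [row[j] for row in X]
        m = sum(col) / n
        sum_item_var += sum((v - m) ** 2 for v in col) / (n - 1)
    return k / (k - 1) * (1 - sum_item_var / var_t)


def icc_oracle(X, variant):
    n, k = X.shape
    grand = X.mean()
    ssr = sum(k * (X[i].mean() - grand) ** 2 for i in range(n))
    ssc = sum(n * (X[:, j].mean() - grand) ** 2 for j in range(k))
    sst = sum((X[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = (sst - ssr - ssc) / ((n - 1) * (k - 1))
    if variant == "consistency":
        return (msr - mse) / (msr + (k - 1) * mse)
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def midrank(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for idx in order[i : j + 1]:
            ranks[idx] = avg
        i = j + 1
    return ranks


class TestCronbachAlpha:
    def test_identical_items_give_alpha_one(self):
        col = np.random.default_rng(0).normal(size=12)
        X = np.column_stack([col] * 4)
        assert cronbach_alpha(X) == pytest.approx(1.0)

    def test_two_standardized_items_closed_form(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=50)
        x = base + rng.normal(scale=0.8, size=50)
        y = base + rng.normal(scale=0.8, size=50)
        x = (x - x.mean()) / x.std(ddof=1)
        y = (y - y.mean()) / y.std(ddof=1)
        r = float(np.corrcoef(x, y)[0, 1])
        assert cronbach_alpha(np.column_stack([x, y])) == pytest.approx(2 * r / (1 + r), abs=1e-12)

    def test_matches_variance_formula_oracle(self):
        X = np.random.default_rng(11).normal(size=(10, 5))
        assert cronbach_alpha(X) == pytest.approx(alpha_oracle(X), abs=1e-12)

    def test_zero_total_variance_is_incalculable(self):
        X = np.array([[1.0, 2.0], [2.0, 1.0], [1.5, 1.5]])  # constant row sums
        assert np.isnan(cronbach_alpha(X))

    def test_alpha_can_be_negative(self):
        X = np.array([[1.0, 5.0], [2.0, 4.0], [3.0, 3.5], [4.0, 2.0], [5.0, 1.2]])
        assert cronbach_alpha(X) < 0

    def test_too_few_items_rejected(self):
        with pytest.raises(DomainError):
            cronbach_alpha(np.ones((5, 1)))


class TestItemTotal:
    def test_item_equal_to_sum_of_others_correlates_perfectly(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=(2, 15))
        X = np.column_stack([a, b, a + b])
        out = item_total_analysis(X)
        assert out.loc["item_2", "corrected_item_total_r"] == pytest.approx(1.0)

    def test_deleting_noise_item_raises_alpha(self):
        rng = np.random.default_rng(5)
        core = rng.normal(size=20)
        X = np.column_stack([core, core * 1.1, core * 0.9, rng.normal(size=20)])
        out = item_total_analysis(X)
        assert out.loc["item_3", "alpha_if_deleted"] > cronbach_alpha(X)

    def test_matches_leave_one_out_oracle(self):
        X = np.random.default_rng(6).normal(size=(12, 4))
        out = item_total_analysis(X)
        for i in range(4):
            rest = np.delete(X, i, axis=1)
            assert out.iloc[i]["alpha_if_deleted"] == pytest.approx(alpha_oracle(rest), abs=1e-12)
            r = np.corrcoef(X[:, i], rest.sum(axis=1))[0, 1]
            assert out.iloc[i]["corrected_item_total_r"] == pytest.approx(r, abs=1e-12)

    def test_constant_item_flagged_nan(self):
        rng = np.random.default_rng(7)
        X = np.column_stack([rng.normal(size=10), rng.normal(size=10), np.full(10, 2.0)])
        out = item_total_analysis(X)
        assert np.isnan(out.loc["item_2", "corrected_item_total_r"])


class TestICC:
    def test_identical_raters(self):
        x = np.random.default_rng(8).normal(10, 3, size=(15, 1))
        pair = np.hstack([x, x])
        assert icc(pair, "consistency").estimate == pytest.approx(1.0)
        assert icc(pair, "absolute_agreement").estimate == pytest.approx(1.0)

    def test_constant_shift_breaks_absolute_agreement_only(self):
        x = np.random.default_rng(9).normal(10, 3, size=(15, 1))
        pair = np.hstack([x, x + 2.0])
        assert icc(pair, "consistency").estimate == pytest.approx(1.0)
        assert icc(pair, "absolute_agreement").estimate < 1.0

    def test_matches_anova_oracle_including_negative_estimates(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=8)
        anti = np.column_stack([x, -x + rng.normal(scale=0.1, size=8)])
        for variant in ("consistency", "absolute_agreement"):
            mine = icc(anti, variant)
            assert mine.estimate == pytest.approx(icc_oracle(anti, variant), abs=1e-10)
        assert icc(anti, "consistency").estimate < 0
        assert "negative" in icc(anti, "consistency").flags

    def test_oracle_equivalence_on_random_matrices(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            n = int(rng.integers(4, 20))
            k = int(rng.integers(2, 5))
            X = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
            for variant in ("consistency", "absolute_agreement"):
                assert icc(X, variant).estimate == pytest.approx(
                    icc_oracle(X, variant), abs=1e-10
                )

    def test_matches_pingouin_single_measures(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(13)
        X = rng.normal(size=(12, 2)) + rng.normal(size=(12, 1))
        long = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(12), 2),
                "raters": np.tile(["a", "b"], 12),
                "scores": X.ravel(),
            }
        )
        ref = pg.intraclass_corr(long, targets="targets", raters="raters", ratings="scores")
        ref = ref.set_index("Type")["ICC"]
        assert icc(X, "consistency").estimate == pytest.approx(ref["ICC(C,1)"], abs=1e-10)
        assert icc(X, "absolute_agreement").estimate == pytest.approx(ref["ICC(A,1)"], abs=1e-10)

    def test_all_equal_responses_are_incalculable(self):
        X = np.zeros((10, 2))
        result = icc(X, "consistency")
        assert result.incalculable
        assert np.isnan(result.estimate)

    def test_f_test_significance_flag(self):
        rng = np.random.default_rng(14)
        noise = rng.normal(size=(6, 2))  # no subject signal -> not significant
        assert FLAG_NOT_SIGNIFICANT in icc(noise, "consistency").flags

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=0, max_value=2**31 - 1),
        st.floats(min_value=-5, max_value=5, allow_nan=False),
    )
    def test_consistency_invariant_under_rater_offset(self, seed, shift):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(10, 2)) + rng.normal(size=(10, 1))
        shifted = X.copy()
        shifted[:, 1] += shift
        assert icc(shifted, "consistency").estimate == pytest.approx(
            icc(X, "consistency").estimate, abs=1e-9
        )


class TestSpearman:
    def test_monotone_transform_gives_rho_one(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
        assert spearman(x, np.exp(x)).rho == pytest.approx(1.0)

    def test_reversed_order_gives_rho_minus_one(self):
        x = np.arange(10.0)
        assert spearman(x, x[::-1]).rho == pytest.approx(-1.0)

    def test_ties_match_midrank_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 7.0]
        y = [2.0, 1.0, 4.0, 4.0, 4.0, 6.0, 8.0, 8.0]
        rx, ry = midrank(x), midrank(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y).rho == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_flagged(self):
        out = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert FLAG_INCALCULABLE in out.flags and np.isnan(out.rho)

    def test_high_convergent_validity_between_instruments(self):
        # the same latent abilities scored through both instruments should
        # correlate strongly, mirroring convergent-validity analysis
        from orsim.instruments import rating_totals

        grs = generate_rating_table(RaterModel.from_icc(0.85, 1.5), 20, 6, "grs", seed=21)
        cmc = generate_rating_table(RaterModel.from_icc(0.85, 0.8), 20, 6, "cmc", seed=21)
        g = rating_totals(grs, "grs").groupby("subject_id")["total"].mean()
        c = rating_totals(cmc, "cmc").groupby("subject_id")["total"].mean()
        out = spearman(g.to_numpy(), c.loc[g.index].to_numpy())
        assert out.rho > 0.7 and out.p < 0.05


class TestReliabilityReport:
    def test_identical_raters_give_unit_icc_everywhere(self):
        table = generate_rating_table(RaterModel(1.0, 0.0), 20, 6, "grs", seed=2)
        report = reliability_report(table, "grs")
        assert (report.icc_table["estimate"] == 1.0).all()
        assert (report.icc_table["flags"] == "").all()

    def test_all_zero_item_flagged_incalculable_not_numeric(self):
        table = generate_rating_table(RaterModel(0.6, 0.3), 10, 3, "cmc", seed=3)
        table.loc[table["item"] == "missed_detection", "score"] = 0
        report = reliability_report(table, "cmc")
        rows = report.icc_table.query("scope == 'item' and name == 'missed_detection'")
        assert (rows["flags"].str.contains(FLAG_INCALCULABLE)).all()
        assert rows["estimate"].isna().all()

    def test_per_scenario_grouping_uses_subject_rows(self):
        table = generate_rating_table(RaterModel(1.0, 0.4), 12, 4, "grs", seed=4)
        report = reliability_report(table, "grs", grouping="scenario")
        per_scen = report.icc_table.query("scope == 'total' and scenario != 'all'")
        assert (per_scen["n"] == 12).all()
        aggregate = report.icc_table.query("scope == 'total' and scenario == 'all'")
        assert (aggregate["n"] == 48).all()

    def test_alpha_if_deleted_consistent_with_direct_alpha(self):
        from orsim.psychometrics import rater_average_matrix

        table = generate_rating_table(RaterModel(1.0, 0.4, sigma_item=0.5), 15, 4, "grs", seed=5)
        report = reliability_report(table, "grs")
        avg = rater_average_matrix(table, "grs")
        for item in avg.columns:
            direct = cronbach_alpha(avg.drop(columns=[item]).to_numpy())
            assert report.item_stats.loc[item, "alpha_if_deleted"] == pytest.approx(direct)

    def test_true_icc_recovered_from_synthetic_tables(self):
        estimates = []
        for seed in range(10):
            table = generate_rating_table(RaterModel.from_icc(0.8, 1.5), 20, 6, "grs", seed=seed)
            report = reliability_report(table, "grs")
            row = report.icc_table.query(
                "scope == 'total' and items == 'all' and variant == 'consistency'"
            )
            estimates.append(float(row["estimate"].iloc[0]))
        assert 0.7 <= float(np.median(estimates)) <= 0.9

    def test_shuffling_one_rater_destroys_consistency(self):
        table = generate_rating_table(RaterModel.from_icc(0.8, 1.5), 20, 6, "grs", seed=6)
        report = reliability_report(table, "grs")
        baseline = float(
            report.icc_table.query(
                "scope=='total' and items=='all' and variant=='consistency'"
            )["estimate"].iloc[0]
        )
        rng = np.random.default_rng(0)
        shuffled = table.copy()
        mask = shuffled["rater_id"] == "R2"
        for item in shuffled["item"].unique():
            sel = mask & (shuffled["item"] == item)
            shuffled.loc[sel, "score"] = rng.permutation(shuffled.loc[sel, "score"].to_numpy())
        report2 = reliability_report(shuffled, "grs")
        broken = float(
            report2.icc_table.query(
                "scope=='total' and items=='all' and variant=='consistency'"
            )["estimate"].iloc[0]
        )
        assert broken < baseline and abs(broken) < 0.25

    def test_three_raters_rejected_by_study_design(self):
        table = generate_rating_table(
            RaterModel(1.0, 0.2, biases=(0.0, 0.0, 0.0)), 5, 2, "grs", seed=7
        )
        with pytest.raises(DomainError, match="2 raters"):
            reliability_report(table, "grs")


class TestEffectSizes:
    def test_printed_arithmetic_of_group_means(self):
        # groups engineered to the published split means: the raw difference
        # must reproduce mean2 - mean1 exactly
        g1 = np.array([15.1 - 0.5] * 5 + [15.1 + 0.5] * 5)
        g2 = np.array([20.2 - 0.5] * 5 + [20.2 + 0.5] * 5)
        table = effect_size_table(pd.Series(np.concatenate([g1, g2])))
        row = table.loc["median_split"]
        assert row["mean1"] == pytest.approx(15.1)
        assert row["mean2"] == pytest.approx(20.2)
        assert row["difference"] == pytest.approx(5.1)

    def test_percent_difference_uses_average_of_means(self):
        scores = pd.Series(np.arange(20, dtype=float))
        row = effect_size_table(scores).loc["median_split"]
        expected = row["difference"] / ((row["mean1"] + row["mean2"]) / 2) * 100
        assert row["percent_difference"] == pytest.approx(expected)

    def test_cohens_d_uses_full_sample_pooled_sd(self):
        rng = np.random.default_rng(15)
        scores = pd.Series(np.concatenate([rng.normal(15, 3, 10), rng.normal(20, 3, 10)]))
        row = effect_size_table(scores).loc["median_split"]
        assert row["cohens_d"] == pytest.approx(
            row["difference"] / scores.std(ddof=1), abs=1e-12
        )

    def test_identical_scenario_groups_give_zero_difference_and_d(self):
        scores = pd.Series(np.arange(8, dtype=float), index=[f"S{i}" for i in range(8)])
        scen = pd.DataFrame({"a": scores, "b": scores})
        row = effect_size_table(scores, scen, contrast=("a", "b")).loc["scenario_contrast"]
        assert row["difference"] == 0 and row["cohens_d"] == 0

    def test_quartile_split_takes_middle_quartiles(self):
        scores = pd.Series(np.arange(20, dtype=float))
        row = effect_size_table(scores).loc["quartile_split"]
        assert row["mean1"] == pytest.approx(np.arange(5, 10).mean())
        assert row["mean2"] == pytest.approx(np.arange(10, 15).mean())

    def test_too_few_subjects_rejected(self):
        with pytest.raises(DomainError):
            effect_size_table(pd.Series([1.0, 2.0, 3.0]))

    def test_from_rating_table_includes_scenario_contrast(self):
        table = generate_rating_table(RaterModel.from_icc(0.8, 1.5), 20, 6, "grs", seed=16)
        out = instrument_effect_sizes(table, "grs")
        assert set(out.index) == {"median_split", "quartile_split", "scenario_contrast"}
        assert out.loc["median_split", "difference"] > 0
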