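"""Tests for the comparison pipeline, ANOVA routines, and reference tables."""

import itertools

import numpy as np
import pandas as pd
import pytest

from memdkit import (
    InvalidInputError,
    StudyParams,
    load_mode_alignment_table,
    load_mode_mixing_table,
    lsd_posthoc,
    report,
    rm_anova_oneway,
    run_comparison,
    subject_method_means,
    two_way_anova,
)


def explicit_two_way_ss(df):
    """Independent oracle: textbook balanced two-way sums of squares."""
    grand = df["value"].mean()
    n = len(df)
    a_means = df.groupby("program")["value"].mean()
    b_means = df.groupby("method")["value"].mean()
    cell = df.groupby(["program", "method"])["value"].agg(["mean", "count"])
    n_per_a = n / len(a_means)
    n_per_b = n / len(b_means)
    ss_a = float((n_per_a * (a_means - grand) ** 2).sum())
    ss_b = float((n_per_b * (b_means - grand) ** 2).sum())
    ss_cells = float((cell["count"] * (cell["mean"] - grand) ** 2).sum())
    ss_ab = ss_cells - ss_a - ss_b
    ss_total = float(((df["value"] - grand) ** 2).sum())
    return {"program": ss_a, "method": ss_b, "program x method": ss_ab,
            "error": ss_total - ss_cells}


def explicit_rm_f(X):
    """Independent oracle: repeated-measures F from raw definitional sums."""
    X = np.asarray(X, float)
    n, k = X.shape
    grand = X.mean()
    ss_cond = n * sum((X[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = k * sum((X[i].mean() - grand) ** 2 for i in range(n))
    ss_err = sum(
        (X[i, j] - X[i].mean() - X[:, j].mean() + grand) ** 2
        for i, j in itertools.product(range(n), range(k))
    )
    return (ss_cond / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))


@pytest.fixture(scope="module")
def toy_table():
    rng = np.random.default_rng(0)
    rows = []
    for s in range(1, 7):
        for p in ("sitting", "standing", "walking"):
            for m in ("EEMD", "MEMD", "NA-MEMD"):
                rows.append(dict(subject=s, program=p, method=m,
                                 value=rng.normal(0.7, 0.1)))
    return pd.DataFrame(rows)


class TestReferenceTables:
    def test_shapes_and_balance(self):
        for tab in (load_mode_alignment_table(), load_mode_mixing_table()):
            assert len(tab) == 11 * 3 * 3
            assert tab.groupby(["program", "method"]).size().nunique() == 1

    def test_alignment_column_means_match_printed_summary(self):
        tab = load_mode_alignment_table()
        means = tab.groupby(["program", "method"])["value"].mean().round(2)
        assert means[("sitting", "EEMD")] == 0.67
        assert means[("sitting", "NA-MEMD")] == 0.83
        assert means[("walking", "MEMD")] == 0.73

    def test_subject_one_program_average(self):
        means = subject_method_means(load_mode_alignment_table())
        assert means.loc[1, "NA-MEMD"] == pytest.approx((0.84 + 0.76 + 0.78) / 3)


class TestTwoWayAnova:
    def test_all_equal_values_give_zero_effect_ss(self, toy_table):
        flat = toy_table.assign(value=0.5)
        aov = two_way_anova(flat)
        for src in ("program", "method", "program x method"):
            assert aov.loc[aov["source"] == src, "ss"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_explicit_ss_oracle(self, toy_table):
        aov = two_way_anova(toy_table).set_index("source")
        oracle = explicit_two_way_ss(toy_table)
        for src, ss in oracle.items():
            assert aov.loc[src, "ss"] == pytest.approx(ss, abs=1e-9)
        assert aov["ms"].equals(aov["ss"] / aov["df"]) or np.allclose(
            aov["ms"], aov["ss"] / aov["df"]
        )

    def test_ss_decomposition(self, toy_table):
        aov = two_way_anova(toy_table)
        total = ((toy_table["value"] - toy_table["value"].mean()) ** 2).sum()
        assert aov["ss"].sum() == pytest.approx(total, abs=1e-9)

    def test_unbalanced_rejected(self, toy_table):
        with pytest.raises(InvalidInputError):
            two_way_anova(toy_table.iloc[:-1])


class TestRmAnova:
    def test_identical_columns_give_zero_f(self):
        X = pd.DataFrame({"a": [1.0, 2, 3], "b": [1.0, 2, 3]})
        aov = rm_anova_oneway(X)
        assert aov.iloc[0]["F"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_definitional_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 3))
        aov = rm_anova_oneway(pd.DataFrame(X))
        assert aov.iloc[0]["F"] == pytest.approx(explicit_rm_f(X), abs=1e-9)

    def test_matches_statsmodels_anovarm(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 3))
        long = pd.DataFrame(
            [
                {"subject": i, "cond": j, "value": X[i, j]}
                for i in range(8)
                for j in range(3)
            ]
        )
        ref = AnovaRM(long, "value", "subject", within=["cond"]).fit()
        ours = rm_anova_oneway(pd.DataFrame(X))
        assert ours.iloc[0]["F"] == pytest.approx(
            float(ref.anova_table["F Value"].iloc[0]), abs=1e-9
        )
        assert ours.iloc[0]["p"] == pytest.approx(
            float(ref.anova_table["Pr > F"].iloc[0]), abs=1e-12
        )

    def test_incomplete_matrix_rejected(self):
        X = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 3.0]})
        with pytest.raises(InvalidInputError):
            rm_anova_oneway(X)


class TestLsd:
    def test_identical_columns_give_p_one(self):
        X = pd.DataFrame(np.tile([[1.0], [2.0], [3.0]], (1, 3)), columns=list("abc"))
        lsd = lsd_posthoc(X)
        assert np.allclose(lsd["p"], 1.0)

    def test_shifted_column_has_smallest_p(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 0.05, size=(8, 1))
        X = pd.DataFrame(
            np.hstack([base, base + rng.normal(0, 0.05, (8, 1)), base + 1.0]),
            columns=["a", "b", "c"],
        )
        lsd = lsd_posthoc(X).set_index("pair")
        assert lsd.loc["a vs c", "p"] < lsd.loc["a vs b", "p"]
        assert lsd.loc["b vs c", "p"] < lsd.loc["a vs b", "p"]

    def test_reference_table_largest_contrast_is_namemd_vs_eemd(self):
        means = subject_method_means(load_mode_alignment_table())
        lsd = lsd_posthoc(means).set_index("pair")
        diffs = lsd["difference"].abs()
        assert diffs.idxmax() == "EEMD vs NA-MEMD"


class TestPipeline:
    @pytest.fixture(scope="class")
    def small_study(self):
        from memdkit import SurrogateSpec, gen_surrogate, segment_motion

        recordings = {}
        for s, program in [(1, "sitting"), (1, "standing")]:
            rec = gen_surrogate(SurrogateSpec(seed=s * 10 + hash(program) % 7))
            recordings[(s, program)] = segment_motion(rec)[0]
        params = StudyParams()
        return run_comparison(recordings, params=params)

    def test_structural_row_counts(self, small_study):
        # per recording x method: 4 count rows + alignment + mixing
        assert len(small_study) == 2 * 3 * (4 + 2)
        assert set(small_study["metric"]) == {"imf_count", "alignment", "mixing"}

    def test_multivariate_methods_have_equal_channel_counts(self, small_study):
        counts = small_study[small_study["metric"] == "imf_count"]
        for m in ("MEMD", "NA-MEMD"):
            per_rec = counts[counts["method"] == m].groupby(["subject", "program"])["value"]
            assert (per_rec.nunique() == 1).all()

    def test_unknown_method_rejected(self, small_study):
        with pytest.raises(InvalidInputError):
            run_comparison({}, methods=("EMD-X",))

    def test_report_outputs_are_deterministic(self, small_study, tmp_path):
        paths_a = report(small_study, tmp_path / "a")
        paths_b = report(small_study, tmp_path / "b")
        for key in paths_a:
            a = (tmp_path / "a" / paths_a[key].split("/")[-1]).read_bytes()
            b = (tmp_path / "b" / paths_b[key].split("/")[-1]).read_bytes()
            assert a == b, key

    def test_report_rejects_empty_table(self, tmp_path):
        with pytest.raises(InvalidInputError):
            report(pd.DataFrame(), tmp_path)
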