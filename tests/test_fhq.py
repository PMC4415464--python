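"""Questionnaire-style selection: Fisher cut-offs, balanced accuracy, analysis."""

import itertools

import pytest
from scipy.stats import fisher_exact

from twostagedx import TwoStageDesign, rank_and_select
from twostagedx.fhq import (
    QuestionTable,
    balanced_accuracy,
    balanced_accuracy_rule,
    fhq_analyze,
    fisher_pvalue,
    fisher_threshold,
    load_fhq_fixture,
    stage_concordance_chisq,
)


class TestFisherThreshold:
    @pytest.mark.parametrize(
        "x,n1,fp,tn",
        [(19, 26, 40, 160), (5, 20, 10, 10), (12, 20, 3, 17), (0, 8, 4, 12)],
    )
    def test_pvalue_matches_scipy(self, x, n1, fp, tn):
        ours = fisher_pvalue(x, n1, fp, tn)
        ref = fisher_exact([[x, n1 - x], [fp, tn]]).pvalue
        assert ours == pytest.approx(ref, rel=1e-10)

    @pytest.mark.parametrize(
        "n1,fp,tn", [(20, 0, 20), (26, 40, 160), (15, 10, 30), (30, 30, 170)]
    )
    def test_threshold_minimality_by_exhaustive_scan(self, n1, fp, tn):
        c = fisher_threshold(n1, fp, tn, alpha=0.05)
        assert c is not None
        # every count at or above c is significant...
        assert all(fisher_pvalue(x, n1, fp, tn) < 0.05 for x in range(c, n1 + 1))
        # ...and c is minimal
        assert c == 0 or fisher_pvalue(c - 1, n1, fp, tn) >= 0.05

    def test_alpha_one_keeps_everything(self):
        assert fisher_threshold(20, 10, 10, alpha=1.0) == 0

    def test_unattainable_threshold(self):
        # margins too small for significance even at x = n1
        assert fisher_threshold(3, 5, 5) is None
        assert fisher_pvalue(3, 3, 5, 5) >= 0.05

    def test_degenerate_margins_rejected(self):
        with pytest.raises(ValueError):
            fisher_threshold(0, 5, 5)
        with pytest.raises(ValueError):
            fisher_threshold(10, 0, 0)

    def test_mid_p_is_smaller(self):
        assert fisher_pvalue(12, 20, 3, 17, mid_p=True) < fisher_pvalue(
            12, 20, 3, 17
        )


class TestBalancedAccuracy:
    def test_perfect_question(self):
        q = QuestionTable("q", tp=10, fn=0, fp=0, tn=20)
        assert balanced_accuracy(q) == 1.0

    def test_arithmetic(self):
        q = QuestionTable("q", tp=12, fn=8, fp=4, tn=16)  # sens .6, spec .8
        assert balanced_accuracy(q) == pytest.approx(0.7)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            balanced_accuracy(QuestionTable("q", tp=0, fn=0, fp=1, tn=1))
        with pytest.raises(ValueError):
            balanced_accuracy(QuestionTable("q", tp=1, fn=1, fp=0, tn=0))


class TestBalancedAccuracyRule:
    def test_equal_sizes_and_specificities_reduce_to_sensitivity(self):
        tables = [
            QuestionTable("a", tp=0, fn=10, fp=5, tn=15),
            QuestionTable("b", tp=0, fn=10, fp=5, tn=15),
        ]
        rule = balanced_accuracy_rule(tables)
        design_ba = TwoStageDesign(n1=(10, 10), c=(0, 0), n2=5, ranking=rule)
        design_sens = TwoStageDesign(n1=(10, 10), c=(0, 0), n2=5)
        for x in itertools.product(range(11), range(11)):
            assert (
                rank_and_select(x, design_ba).M == rank_and_select(x, design_sens).M
            )

    def test_rank_order_matches_direct_sort(self):
        tables = [
            QuestionTable("a", tp=0, fn=0, fp=6, tn=14),  # spec .70
            QuestionTable("b", tp=0, fn=0, fp=2, tn=18),  # spec .90
            QuestionTable("c", tp=0, fn=0, fp=4, tn=16),  # spec .80
        ]
        n1 = (8, 10, 9)
        tables = [
            QuestionTable(t.label, tp=0, fn=n, fp=t.fp, tn=t.tn)
            for t, n in zip(tables, n1)
        ]
        rule = balanced_accuracy_rule(tables)
        design = TwoStageDesign(n1=n1, c=(0, 0, 0), n2=5, ranking=rule)
        for x in itertools.product(range(4), range(4), range(4)):
            sel = rank_and_select(x, design)
            qs = [
                QuestionTable(t.label, tp=xi, fn=n - xi, fp=t.fp, tn=t.tn)
                for t, n, xi in zip(tables, n1, x)
            ]
            direct = sorted(
                range(3), key=lambda i: (-balanced_accuracy(qs[i]), i)
            )
            assert list(sel.ranked) == direct

    def test_dominance_bound_matches_exhaustive_search(self):
        tables = [
            QuestionTable("a", tp=0, fn=12, fp=6, tn=14),
            QuestionTable("b", tp=0, fn=10, fp=2, tn=18),
        ]
        rule = balanced_accuracy_rule(tables)
        rule.check_consistency((12, 10))
        for xj in range(11):
            bound = rule.dominance(xj, 0, 1)
            brute = next(
                (
                    xi
                    for xi in range(13)
                    if rule.score(xi, 0) >= rule.score(xj, 1)
                ),
                None,
            )
            from twostagedx.design import count_at_least

            if brute is None:
                assert count_at_least(bound) > 12
            else:
                assert count_at_least(bound) == brute


class TestStageConcordance:
    def test_published_breast_cancer_counts(self):
        assert stage_concordance_chisq((19, 26), (14, 22)) == pytest.approx(
            0.696, abs=5e-4
        )

    def test_identical_proportions_give_p_one(self):
        assert stage_concordance_chisq((10, 20), (10, 20)) == pytest.approx(1.0)

    def test_gross_discordance(self):
        assert stage_concordance_chisq((19, 26), (0, 22)) < 0.001

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError):
            stage_concordance_chisq((0, 5), (0, 5))


@pytest.fixture(scope="module")
def fixture_reports():
    data = load_fhq_fixture()
    return {
        cond: fhq_analyze(tables, condition=cond) for cond, tables in data.items()
    }


class TestFHQAnalyze:

    def test_bias_detected_only_where_support_truncates(self, fixture_reports):
        breast = fixture_reports["breast_cancer"]
        assert breast.selected == "Q8"
        assert breast.estimates["umvcue"] < breast.estimates["mle"]
        assert breast.selection_bias_detected
        for cond in ("diabetes", "ihd", "colorectal_cancer"):
            r = fixture_reports[cond]
            assert r.estimates["umvcue"] == pytest.approx(
                r.estimates["mle"], abs=1e-12
            )
            assert not r.selection_bias_detected

    def test_breast_like_condition_uses_published_counts(self, fixture_reports):
        r = fixture_reports["breast_cancer"]
        assert r.estimates["stage1"] == pytest.approx(19 / 26)
        assert r.estimates["stage2"] == pytest.approx(14 / 22)
        assert r.estimates["mle"] == pytest.approx(33 / 48)
        assert r.chisq_p == pytest.approx(0.696, abs=5e-4)

    def test_report_frame_well_formed(self, fixture_reports):
        frame = fixture_reports["diabetes"].to_frame()
        assert set(frame["estimator"]) == {"stage1", "stage2", "mle", "umvcue"}
        assert (frame["ci_lower"] <= frame["ci_upper"]).all()

    def test_no_significant_question_reports_stopped(self):
        tables = [
            QuestionTable("q1", tp=1, fn=9, fp=10, tn=10),
            QuestionTable("q2", tp=2, fn=8, fp=12, tn=8),
        ]
        report = fhq_analyze(tables, condition="none")
        assert report.stopped

    def test_stage2_on_wrong_question_rejected(self):
        tables = [
            QuestionTable("good", tp=19, fn=7, fp=40, tn=160),
            QuestionTable("bad", tp=11, fn=19, fp=30, tn=170, tp2=5, fn2=5),
        ]
        with pytest.raises(ValueError, match="selection rules"):
            fhq_analyze(tables, condition="mismatch")
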