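"""Dichotomization, diagnostic metrics and the exploratory scheme search."""

import itertools

import pytest
from hypothesis import given, settings

from thyrocascade import (BinaryTable, DichotomizationScheme, compute_metrics,
                          dichotomize, search_schemes, tabulate)
from thyrocascade.diagnostics import CASCADE_PAPER, FNA_PAPER, FS_PAPER
from thyrocascade.errors import ThyroCascadeError

from conftest import cohorts


def brute_force_2x2(cohort, stage_attr, positive):
    """Record-level oracle for the 2x2 collapse."""
    tp = fp = fn = tn = 0
    for rec in cohort:
        pos = getattr(rec, stage_attr) in positive
        event = rec.outcome == "MALIGNANT"
        tp += pos and event
        fp += pos and not event
        fn += (not pos) and event
        tn += (not pos) and not event
    return BinaryTable(tp=tp, fp=fp, fn=fn, tn=tn)


def test_fna_preset_2x2_from_published_margins(paper_cohort):
    """Bethesda {V,VI} positive collapses the FNA table to (3213,39,331,224)."""
    bt = dichotomize(tabulate(paper_cohort, "FNA"), FNA_PAPER)
    assert (bt.tp, bt.fp, bt.fn, bt.tn) == (3213, 39, 331, 224)


def test_fs_preset_2x2_from_published_margins(paper_cohort):
    bt = dichotomize(tabulate(paper_cohort, "FS"), FS_PAPER)
    assert (bt.tp, bt.fp, bt.fn, bt.tn) == (3334, 0, 210, 263)


def test_all_positive_scheme_rejected(paper_cohort):
    table = tabulate(paper_cohort, "FS")
    with pytest.raises(ThyroCascadeError, match="proper subset"):
        dichotomize(table, DichotomizationScheme(
            frozenset(table.row_labels)))


def test_unknown_category_rejected(paper_cohort):
    with pytest.raises(ThyroCascadeError, match="not in table"):
        dichotomize(tabulate(paper_cohort, "FNA"),
                    DichotomizationScheme(frozenset({"MALIGNANCY"})))


@pytest.mark.parametrize("bt,panel", [
    # (accuracy, sensitivity, specificity, ppv, npv), percent one decimal
    (BinaryTable(3213, 39, 331, 224), (90.3, 90.7, 85.2, 98.8, 40.4)),
    (BinaryTable(3334, 0, 210, 263), (94.5, 94.1, 100.0, 100.0, 55.6)),
    (BinaryTable(3448, 21, 96, 242), (96.9, 97.3, 92.0, 99.4, 71.6)),
    (BinaryTable(1, 0, 0, 1), (100.0, 100.0, 100.0, 100.0, 100.0)),
])
def test_metric_panels(bt, panel):
    """The five standard metrics reproduce the published percent panels."""
    mets = compute_metrics(bt)
    got = tuple(getattr(mets, name).percent for name in
                ("accuracy", "sensitivity", "specificity", "ppv", "npv"))
    assert got == panel


def test_zero_denominator_metric_is_undefined_not_zero():
    # no test-negatives at all -> NPV has denominator 0
    mets = compute_metrics(BinaryTable(tp=5, fp=2, fn=0, tn=0))
    assert mets.npv.value is None
    assert mets.sensitivity.value == 1.0  # others still returned


@pytest.mark.parametrize("ci", ["wilson", "clopper-pearson"])
def test_point_estimates_inside_intervals(ci):
    for bt in [BinaryTable(3213, 39, 331, 224), BinaryTable(3334, 0, 210, 263),
               BinaryTable(3, 1, 2, 4)]:
        mets = compute_metrics(bt, ci=ci)
        for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            est = getattr(mets, name)
            assert est.ci_low <= est.value <= est.ci_high


def test_outcome_swap_symmetry():
    """Swapping outcome labels swaps sens<->spec and PPV<->NPV."""
    bt = BinaryTable(tp=30, fp=7, fn=11, tn=21)
    swapped = BinaryTable(tp=bt.tn, fp=bt.fn, fn=bt.fp, tn=bt.tp)
    a, b = compute_metrics(bt), compute_metrics(swapped)
    assert a.sensitivity.value == b.specificity.value
    assert a.specificity.value == b.sensitivity.value
    assert a.ppv.value == b.npv.value
    assert a.npv.value == b.ppv.value
    assert a.accuracy.value == b.accuracy.value


@settings(max_examples=50, deadline=None, derandomize=True)
@given(cohorts(max_size=30))
def test_dichotomize_equals_record_level_oracle(cohort):
    """Table-collapse 2x2 equals a direct record count for random cohorts."""
    table = tabulate(cohort, "FNA")
    bt = dichotomize(table, FNA_PAPER)
    assert bt == brute_force_2x2(cohort, "fna_category",
                                 FNA_PAPER.positive_categories)


def test_positive_set_growth_is_monotone(paper_cohort):
    """Adding a category never decreases TP and never increases TN."""
    table = tabulate(paper_cohort, "FNA")
    order = table.row_labels
    prev = None
    for k in range(1, len(order)):
        bt = dichotomize(table, DichotomizationScheme(frozenset(order[:k])))
        if prev is not None:
            assert bt.tp >= prev.tp and bt.tn <= prev.tn
        prev = bt


class TestSearchSchemes:
    def test_threshold_ranking_matches_brute_force(self, paper_cohort):
        """The ranked thresholds agree with exhaustive recomputation."""
        table = tabulate(paper_cohort, "FNA")
        ranked = search_schemes(table, criterion="accuracy", family="threshold")
        assert len(ranked) == 5  # proper prefixes of the 6 ordinal categories
        # brute force: accuracy of each top-k prefix
        best_acc, best_set = -1.0, None
        for k in range(1, 6):
            pos = set(table.row_labels[:k])
            bt = dichotomize(table, DichotomizationScheme(frozenset(pos)))
            acc = (bt.tp + bt.tn) / bt.total
            if acc > best_acc:
                best_acc, best_set = acc, pos
        assert set(ranked[0].scheme.positive_categories) == best_set
        assert ranked[0].criterion_value == pytest.approx(best_acc)
        # the raw-accuracy winner includes the intermediate categories, i.e.
        # it is {III..VI}, not the clinically conventional {V,VI} preset
        assert best_set == {"VI", "V", "IV", "III"}
        accs = [r.criterion_value for r in ranked]
        assert accs == sorted(accs, reverse=True)

    def test_subset_family_counts_all_proper_subsets(self, paper_cohort):
        table = tabulate(paper_cohort, "FS")
        ranked = search_schemes(table, family="subset")
        assert len(ranked) == 2 ** 4 - 2

    def test_two_row_table_has_single_threshold(self, paper_cohort):
        from thyrocascade.contingency import ContingencyTable
        table = ContingencyTable(("POS", "NEG"), [[3213, 39], [331, 224]])
        ranked = search_schemes(table, family="threshold")
        assert len(ranked) == 1
        direct = compute_metrics(BinaryTable(3213, 39, 331, 224))
        assert ranked[0].metrics.accuracy.value == direct.accuracy.value

    def test_unknown_criterion_rejected(self, paper_cohort):
        with pytest.raises(ThyroCascadeError, match="criterion"):
            search_schemes(tabulate(paper_cohort, "FNA"), criterion="auc")
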