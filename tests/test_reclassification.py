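"""Categorical NRI: marginal and paired estimators."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings

from thyrocascade import (BinaryTable, Cohort, DichotomizationScheme,
                          PatientRecord, apply_cascade, dichotomize,
                          nri_from_marginals, nri_paired, simulate_cohort,
                          tabulate)
from thyrocascade.cascade import PAPER_RULE
from thyrocascade.diagnostics import CASCADE_PAPER, FNA_PAPER, FS_PAPER
from thyrocascade.errors import CohortMismatchError, StratumEmptyError
from thyrocascade.synthetic import SimulationConfig

from conftest import cohorts

FNA_2x2 = BinaryTable(3213, 39, 331, 224)
FS_2x2 = BinaryTable(3334, 0, 210, 263)
CASCADE_2x2 = BinaryTable(3448, 21, 96, 242)


class TestMarginal:
    def test_fna_to_fs_is_published_value(self):
        """NRI = 121/3544 + 39/263 = 0.182 for FNA -> frozen section."""
        res = nri_from_marginals(FNA_2x2, FS_2x2)
        assert res.nri_exact == Fraction(121, 3544) + Fraction(39, 263)
        assert res.rounded == 0.182
        assert res.pairing == "MARGINAL_ONLY"
        assert res.se is None and res.ci95 is None and res.p_value is None

    def test_fna_to_cascade_is_published_value(self):
        res = nri_from_marginals(FNA_2x2, CASCADE_2x2)
        assert res.nri_exact == Fraction(235, 3544) + Fraction(18, 263)
        assert res.rounded == 0.135

    def test_identity_comparison_is_zero(self):
        assert nri_from_marginals(FNA_2x2, FNA_2x2).nri == 0.0

    def test_components_sum_to_nri(self):
        res = nri_from_marginals(FNA_2x2, FS_2x2)
        assert res.nri == pytest.approx(res.nri_events + res.nri_nonevents)
        assert -1 <= res.nri_events <= 1 and -1 <= res.nri_nonevents <= 1

    def test_mismatched_cohorts_rejected(self):
        with pytest.raises(CohortMismatchError):
            nri_from_marginals(FNA_2x2, BinaryTable(10, 2, 3, 4))


class TestPaired:
    def test_point_estimate_matches_marginal_on_reconstruction(self, paper_cohort):
        staged = apply_cascade(paper_cohort, PAPER_RULE)
        res = nri_paired(staged, "FNA", FNA_PAPER, "FS", FS_PAPER)
        assert res.pairing == "PAIRED_RECORDS"
        assert float(res.nri_exact) == pytest.approx(
            nri_from_marginals(FNA_2x2, FS_2x2).nri)
        assert res.ci95[0] < res.nri < res.ci95[1]
        assert res.p_value < 0.001

    def test_identical_schemes_give_zero_and_p_one(self, toy_cohort):
        res = nri_paired(toy_cohort, "FNA", FNA_PAPER, "FNA", FNA_PAPER)
        assert res.nri == 0.0 and res.se == 0.0 and res.p_value == 1.0

    def test_four_record_hand_enumeration(self):
        """One upward event move among 2 events, nothing else: NRI = 0.5."""
        records = [
            # event, old-negative (III not in {V,VI}), new-positive -> up
            PatientRecord("a", "III", "MALIGNANCY", "MALIGNANT"),
            # event, positive under both -> no move
            PatientRecord("b", "VI", "MALIGNANCY", "MALIGNANT"),
            # non-events, negative under both -> no move
            PatientRecord("c", "II", "BENIGN", "BENIGN"),
            PatientRecord("d", "II", "BENIGN", "BENIGN"),
        ]
        res = nri_paired(Cohort(records), "FNA", FNA_PAPER, "FS", FS_PAPER)
        assert res.nri_events == 0.5
        assert res.nri_nonevents == 0.0
        assert res.nri == 0.5

    def test_empty_stratum_rejected(self):
        cohort = Cohort([PatientRecord("a", "VI", "MALIGNANCY", "MALIGNANT")])
        with pytest.raises(StratumEmptyError):
            nri_paired(cohort, "FNA", FNA_PAPER, "FS", FS_PAPER)

    def test_se_formula_on_hand_counts(self):
        """SE from the asymptotic variance, recomputed by hand."""
        records = (
            [PatientRecord(f"e{i}", "III", "MALIGNANCY", "MALIGNANT")
             for i in range(3)]            # 3 ups among events
            + [PatientRecord(f"f{i}", "VI", "BENIGN", "MALIGNANT")
               for i in range(2)]          # 2 downs among events
            + [PatientRecord(f"g{i}", "VI", "MALIGNANCY", "MALIGNANT")
               for i in range(5)]          # 5 static events
            + [PatientRecord(f"h{i}", "V", "BENIGN", "BENIGN")
               for i in range(4)]          # 4 downs among non-events
            + [PatientRecord(f"k{i}", "II", "BENIGN", "BENIGN")
               for i in range(6)]          # 6 static non-events
        )
        res = nri_paired(Cohort(records), "FNA", FNA_PAPER, "FS", FS_PAPER)
        n_e, n_ne = 10, 10
        p_up_e, p_down_e = 0.3, 0.2
        p_up_ne, p_down_ne = 0.0, 0.4
        var = (p_up_e + p_down_e - (p_up_e - p_down_e) ** 2) / n_e \
            + (p_up_ne + p_down_ne - (p_down_ne - p_up_ne) ** 2) / n_ne
        assert res.se == pytest.approx(var ** 0.5)
        assert res.nri == pytest.approx((0.3 - 0.2) + (0.4 - 0.0))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(cohorts(min_size=2, max_size=40, require_both_outcomes=True))
def test_paired_point_estimate_equals_marginal(cohort):
    """The two estimators coincide on the induced 2x2s for any cohort."""
    old = dichotomize(tabulate(cohort, "FNA"), FNA_PAPER)
    new = dichotomize(tabulate(cohort, "FS"), FS_PAPER)
    paired = nri_paired(cohort, "FNA", FNA_PAPER, "FS", FS_PAPER)
    marginal = nri_from_marginals(old, new)
    assert paired.nri_exact == marginal.nri_exact


@settings(max_examples=40, deadline=None, derandomize=True)
@given(cohorts(min_size=2, max_size=40, require_both_outcomes=True))
def test_antisymmetry(cohort):
    fwd = nri_paired(cohort, "FNA", FNA_PAPER, "FS", FS_PAPER)
    rev = nri_paired(cohort, "FS", FS_PAPER, "FNA", FNA_PAPER)
    assert fwd.nri_exact == -rev.nri_exact


def test_simulated_dominance_recovers_generating_delta():
    """With scheme B better in both axes, mean NRI ~ dSens + dSpec.

    The generative model gives the frozen section higher sensitivity and
    specificity than FNA by construction; over seeded replicates the mean
    estimated NRI must sit within Monte-Carlo error of the generating
    difference."""
    base = SimulationConfig.paper_defaults(n=2000, collapse_fs=True)
    # generating sens/spec under the presets (positive = first category
    # block): FNA positive mass = P(VI)+P(V); FS positive mass = P(MAL)
    sens_old = base.fna_given_outcome["MALIGNANT"][:2].sum()
    spec_old = 1 - base.fna_given_outcome["BENIGN"][:2].sum()
    sens_new = base.fs_given_outcome["MALIGNANT"][0]
    spec_new = 1 - base.fs_given_outcome["BENIGN"][0]
    expected = (sens_new - sens_old) + (spec_new - spec_old)
    assert expected > 0

    estimates = []
    for seed in range(12):
        base.seed = seed
        cohort = simulate_cohort(base)
        estimates.append(
            nri_paired(cohort, "FNA", FNA_PAPER, "FS", FS_PAPER).nri)
    mean = np.mean(estimates)
    mc_err = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
    assert mean == pytest.approx(expected, abs=max(4 * mc_err, 0.02))
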