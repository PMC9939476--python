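"""Shared fixtures and hypothesis strategies."""

from __future__ import annotations

import pytest
from hypothesis import strategies as st

from thyrocascade import Cohort, PatientRecord, reconstruct_paper_cohort
from thyrocascade.vocab import FNA_CATEGORIES, FS_CATEGORIES, OUTCOMES


@pytest.fixture(scope="session")
def paper_cohort() -> Cohort:
    """The deterministic 3807-record reconstruction of the published margins."""
    return reconstruct_paper_cohort()


@pytest.fixture(scope="session")
def bare_cohort() -> Cohort:
    """Reconstruction without covariates (classification fields only)."""
    return reconstruct_paper_cohort(include_covariates=False)


@pytest.fixture
def toy_cohort() -> Cohort:
    records = [
        PatientRecord("a", "VI", "MALIGNANCY", "MALIGNANT"),
        PatientRecord("b", "V", "SUSPICIOUS", "MALIGNANT"),
        PatientRecord("c", "II", "BENIGN", "BENIGN"),
        PatientRecord("d", "III", "BENIGN", "BENIGN"),
    ]
    return Cohort(records=records, label="toy")


def record_strategy(index: int):
    return st.builds(
        PatientRecord,
        patient_id=st.just(f"h{index}"),
        fna_category=st.sampled_from(FNA_CATEGORIES),
        fs_category=st.sampled_from(FS_CATEGORIES),
        outcome=st.sampled_from(OUTCOMES),
        age_years=st.one_of(st.none(), st.integers(0, 100)),
        sex=st.one_of(st.none(), st.sampled_from(["F", "M"])),
        diameter_mm=st.one_of(st.none(), st.floats(0.1, 60.0, allow_nan=False)),
        bilateral=st.one_of(st.none(), st.booleans()),
        multifocal=st.one_of(st.none(), st.booleans()),
    )


@st.composite
def cohorts(draw, min_size: int = 1, max_size: int = 40,
            require_both_outcomes: bool = False):
    n = draw(st.integers(min_size, max_size))
    records = [draw(record_strategy(i)) for i in range(n)]
    if require_both_outcomes:
        outcomes = {r.outcome for r in records}
        if "MALIGNANT" not in outcomes:
            records[0] = PatientRecord("h0", "VI", "MALIGNANCY", "MALIGNANT")
        if "BENIGN" not in {r.outcome for r in records} and len(records) > 1:
            records[-1] = PatientRecord(records[-1].patient_id, "II",
                                        "BENIGN", "BENIGN")
        elif "BENIGN" not in {r.outcome for r in records}:
            records.append(PatientRecord("hb", "II", "BENIGN", "BENIGN"))
    return Cohort(records=records, label="hypothesis")
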