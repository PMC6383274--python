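import numpy as np
import pytest

from addinter.contingency import ExposureTable2x4
from addinter.records import StudyDataset, SubjectRecord

#: printed 2x4 cell counts (cases, controls) by (FH, BMI-abnormal)
TABLE5_COUNTS = {
    (0, 0): (20, 75),
    (0, 1): (32, 36),
    (1, 0): (117, 88),
    (1, 1): (246, 70),
}

#: reported crude odds-ratio triple (both, FH-only, BMI-only)
REPORTED_OR_TRIPLE = (12.993, 4.986, 3.333)


@pytest.fixture
def table5():
    return ExposureTable2x4(counts=dict(TABLE5_COUNTS))


def _record(subject_id, pair_id, status, fh, abnormal_bmi, sex="female", age=60.0):
    """Subject with weight chosen to land in the requested BMI state."""
    weight = 80.0 if abnormal_bmi else 55.0  # at 160 cm: BMI 31.2 vs 21.5
    return SubjectRecord(
        subject_id=subject_id,
        pair_id=pair_id,
        status=status,
        sex=sex,
        age=age,
        height=160.0,
        weight=weight,
        waist=75.0,
        hip=95.0,
        family_history=bool(fh),
    )


def dataset_from_cell_counts(counts, seed=0) -> StudyDataset:
    """Expand 2x4 cell counts into individual records.

    Cell totals reproduce ``counts`` exactly. Cases and controls are
    cross-paired after a deterministic shuffle so complete pairs span
    exposure cells (pairing does not affect the unconditional table;
    leftover unmatched subjects get singleton, incomplete pair ids).
    Pairs alternate sex so sex-adjusted models are estimable.
    """
    shuffle = np.random.default_rng(seed)
    case_cells, control_cells = [], []
    for cell, (n_case, n_control) in counts.items():
        case_cells += [cell] * n_case
        control_cells += [cell] * n_control
    case_cells = [case_cells[i] for i in shuffle.permutation(len(case_cells))]
    control_cells = [control_cells[i] for i in shuffle.permutation(len(control_cells))]
    records = []
    for i in range(max(len(case_cells), len(control_cells))):
        pid = f"p{i}"
        sex = "male" if i % 2 else "female"
        if i < len(case_cells):
            fh, ab = case_cells[i]
            records.append(_record(f"c{i}", pid, "case", fh, ab, sex=sex))
        if i < len(control_cells):
            fh, ab = control_cells[i]
            records.append(_record(f"k{i}", pid, "control", fh, ab, sex=sex))
    return StudyDataset(records=records)


@pytest.fixture
def table5_dataset():
    return dataset_from_cell_counts(TABLE5_COUNTS)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
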