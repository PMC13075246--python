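import matplotlib

matplotlib.use("Agg")

from datetime import datetime, timedelta

import pytest

from respagree import CohortParams, EpochRecord, PairedDataset, SubjectInfo, generate_cohort

T0 = datetime(2024, 6, 1, 13, 0)


def make_dataset(rows, subjects=None):
    """rows: (subject_id, minute, bpm_ref, bpm_test[, ref_artifact, usable])."""
    records = []
    for row in rows:
        sid, minute, ref, test = row[:4]
        art = row[4] if len(row) > 4 else False
        usable = row[5] if len(row) > 5 else 60
        records.append(
            EpochRecord(sid, T0 + timedelta(minutes=minute), ref, test, art, usable)
        )
    infos = None
    if subjects is not None:
        infos = [SubjectInfo(sid, age, nap) for sid, age, nap in subjects]
    return PairedDataset.from_records(records, infos)


@pytest.fixture
def small_cohort():
    params = CohortParams(n_subjects=5, nap_mean_min=30.0, nap_sd_min=6.0, seed=11)
    return generate_cohort(params)
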