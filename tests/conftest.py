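import numpy as np
import pandas as pd
import pytest

from varmeta.data import GroupSummary, StudyRecord


@pytest.fixture
def toy_effects():
    """The six-study toy set: estimates with equal variances 0.04."""
    y = np.array([0.1, 0.3, -0.2, 0.5, 0.0, 0.25])
    v = np.full(6, 0.04)
    return y, v


@pytest.fixture
def small_table(tmp_path):
    """A well-formed three-row study table on disk."""
    df = pd.DataFrame({
        "study_id": ["a2001", "b2005", "c2010"],
        "region": ["anterior cingulate cortex", "thalamus", "caudate"],
        "metabolite": ["glutamate", "glutamine", "Glx"],
        "medication_status": ["medicated", "antipsychotic_naive", "mixed"],
        "n_patients": [20, 15, 30],
        "mean_patients": [10.2, 5.1, 7.7],
        "sd_patients": [1.9, 0.8, 1.2],
        "n_controls": [22, 14, 28],
        "mean_controls": [10.0, 5.0, 7.5],
        "sd_controls": [1.5, 0.7, 1.1],
        "mean_age": [31.5, 27.0, 40.2],
        "prop_male": [0.6, 0.7, 0.5],
    })
    path = tmp_path / "table.csv"
    df.to_csv(path, index=False)
    return path, df


def make_record(region="MFC", metabolite="glutamate", study="s1",
                mp=10.0, sp=2.0, np_=20, mc=10.0, sc=1.5, nc=20,
                status="medicated", moderators=None):
    return StudyRecord(
        study_id=study, cohort_id=study, region=region, metabolite=metabolite,
        patient=GroupSummary(mp, sp, np_), control=GroupSummary(mc, sc, nc),
        medication_status=status, moderators=moderators or {})
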