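import numpy as np
import pandas as pd
import pytest

from mesopanel.data import RfuMatrix


def make_annotation(records):
    """Build a validated-shape annotation frame from compact records.

    Each record: (sample_id, class_label, site, draw_type, subject_id,
    plate_id, stage, histology, assay_version) with trailing fields optional.
    """
    defaults = ("NA", "NA", "V1")
    rows = []
    for rec in records:
        rec = tuple(rec) + defaults[len(rec) - 6 :] if len(rec) < 9 else tuple(rec)
        rows.append(rec)
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "class_label", "site", "draw_type", "subject_id",
            "plate_id", "stage", "histology", "assay_version",
        ],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_matrix(rng):
    """20 samples x 50 analytes of log-normal RFU."""
    values = np.exp2(rng.normal(10, 1, size=(20, 50)))
    return RfuMatrix(
        pd.DataFrame(
            values,
            index=[f"S{i:02d}" for i in range(20)],
            columns=[f"A{j:02d}" for j in range(50)],
        )
    )
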