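import numpy as np
import pandas as pd
import pytest

from trfdr.synthetic import TissueLibrary, default_lut
from trfdr.types import FEATURE_COLUMNS


@pytest.fixture(scope="session")
def lut():
    return default_lut()


@pytest.fixture(scope="session")
def library():
    return TissueLibrary.default()


def make_feature_frame(rng, n_patients=4, per_patient=30, shift=1.0):
    """Synthetic 13-feature table with a class shift, for classifier tests.

    Features are lognormal (positive, as the log10 transform requires);
    tumor rows are shifted by ``shift`` in log-space on a subset of
    features.
    """
    rows = []
    for p in range(n_patients):
        for i in range(per_patient):
            label = "tumor" if rng.random() < 0.4 else "no_tumor"
            base = rng.normal(0.0, 0.35, size=len(FEATURE_COLUMNS))
            if label == "tumor":
                base[:5] += shift
            rec = {
                "patient_id": f"P{p:03d}",
                "sample": "tumor_core" if i % 2 else "margin_normal",
                "row": i // 13,
                "col": i % 13,
                "p_tumor": 50 if label == "tumor" else 0,
                "p_fibro": 25 if label == "tumor" else 50,
                "p_adipose": 25 if label == "tumor" else 50,
                "label": label,
                "single_observer": True,
            }
            rec.update({c: 10.0**v for c, v in zip(FEATURE_COLUMNS, base)})
            rows.append(rec)
    return pd.DataFrame(rows)


def make_table1_frame():
    """Record set encoding the published composition accounting:
    652/93/838 homogeneous tumor/fibroglandular/adipose regions and
    1160/2075 heterogeneous tumor/no-tumor regions (4818 total, 73
    patients)."""
    rows = []
    groups = [
        (652, dict(p_tumor=100, p_fibro=0, p_adipose=0)),
        (93, dict(p_tumor=0, p_fibro=100, p_adipose=0)),
        (838, dict(p_tumor=0, p_fibro=0, p_adipose=100)),
        (1160, dict(p_tumor=50, p_fibro=25, p_adipose=25)),
        (2075, dict(p_tumor=0, p_fibro=50, p_adipose=50)),
    ]
    i = 0
    for count, comp in groups:
        for _ in range(count):
            label = "tumor" if comp["p_tumor"] > 0 else "no_tumor"
            rows.append({"patient_id": f"P{i % 73:03d}", "label": label, **comp})
            i += 1
    return pd.DataFrame(rows)


@pytest.fixture
def table1_frame():
    return make_table1_frame()
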