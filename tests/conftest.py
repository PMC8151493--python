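import numpy as np
import pandas as pd
import pytest

from lactocurve import ObservationTable, label_cows, simulate_herd
from lactocurve.synthetic_data import SimulationConfig


def make_table(rows):
    """Build a validated table from (cow_id, day, bhb[, extras]) tuples.

    Unspecified biomarkers get benign positive defaults.
    """
    records = []
    for r in rows:
        cow_id, day, bhb = r[0], r[1], r[2]
        extra = r[3] if len(r) > 3 else {}
        records.append({
            "cow_id": cow_id,
            "parity": extra.get("parity", "multiparous"),
            "day": day,
            "bhb": bhb,
            "nefa": extra.get("nefa", 0.3),
            "tbil": extra.get("tbil", 3.0),
            "ast": extra.get("ast", 80.0),
            "post_treatment": extra.get("post_treatment", False),
        })
    return ObservationTable(pd.DataFrame(records))


@pytest.fixture(scope="session")
def herd():
    """Default synthetic herd (99 cows, 14 weekly visits)."""
    return simulate_herd(seed=11)


@pytest.fixture(scope="session")
def herd_labels(herd):
    return label_cows(herd.table, 0.8)


@pytest.fixture
def toy_table():
    return make_table([
        ("A", -7, 0.40), ("A", 0, 0.55), ("A", 7, 0.62),
        ("B", -6, 0.45), ("B", 1, 0.50), ("B", 6, 0.95),
        ("C", -3, 0.35), ("C", 2, 0.42), ("C", 9, 0.48),
    ])
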