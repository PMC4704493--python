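import numpy as np
import pandas as pd
import pytest

from mimictox import screen as mscreen
from mimictox import simulate as msim
from mimictox.datatypes import ScreenPlate


@pytest.fixture
def grid_plate():
    """A deterministic 8x12 plate with known per-row gain factors."""
    rows = [chr(ord("A") + r) for r in range(8)]
    gains = {row: 0.5 + 0.25 * i for i, row in enumerate(rows)}
    recs = []
    for row in rows:
        for col in range(1, 13):
            recs.append({"row": row, "column": col,
                         "mimic_id": f"m-{row}{col:02d}",
                         "value": gains[row] * (90 + col)})
    return ScreenPlate("P1", "lineA", 1, pd.DataFrame(recs)), gains


@pytest.fixture(scope="session")
def screen_run():
    """Default synthetic screen pushed through the full processing chain."""
    plates, truth, ann = msim.simulate_screen(seed=1)
    normed = [mscreen.normalize_row_median(p) for p in plates]
    mean, sd, n = mscreen.aggregate_replicates(normed, exclude=("miR-NC",))
    zm = mscreen.compute_zscores(mean)
    hits = mscreen.call_hits(zm)
    return {"plates": plates, "truth": truth, "ann": ann, "normed": normed,
            "mean": mean, "sd": sd, "n": n, "zm": zm, "hits": hits}


@pytest.fixture
def survival_cohort():
    cohort, truth = msim.simulate_survival_cohort(seed=42)
    return cohort, truth


def make_cohort(times, events, expression=None, prefix="s"):
    n = len(times)
    return pd.DataFrame({
        "sample_id": [f"{prefix}{i}" for i in range(n)],
        "time": np.asarray(times, dtype=float),
        "event": np.asarray(events, dtype=int),
        "expression": np.zeros(n) if expression is None
        else np.asarray(expression, dtype=float)})
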