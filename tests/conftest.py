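import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def make_colony_table(values: np.ndarray, red: np.ndarray | None = None,
                      present: np.ndarray | None = None) -> pd.DataFrame:
    """Build a ColonyTable DataFrame from a 2-D growth grid (test helper)."""
    values = np.asarray(values, dtype=float)
    red = values.copy() if red is None else np.asarray(red, dtype=float)
    n_rows, n_cols = values.shape
    if present is None:
        present = np.ones_like(values, dtype=bool)
    rows = []
    for i in range(n_rows):
        for j in range(n_cols):
            rows.append({
                "plate_id": "p0", "condition": "test", "replicate": "rep1",
                "row": i, "col": j, "strain": f"s{i * n_cols + j:05d}",
                "growth": values[i, j] if present[i, j] else 0.0,
                "red_intensity": red[i, j] if present[i, j] else 0.0,
                "present": bool(present[i, j]),
            })
    return pd.DataFrame(rows)


def iqm_bruteforce(values) -> float:
    """Independent fractional-weight IQM oracle.

    Weights each sorted observation by the overlap of its unit interval
    ``[i, i+1)`` with the central half ``[n/4, 3n/4)`` — a different
    formulation from the implementation's trim-count bookkeeping.
    """
    s = sorted(float(v) for v in values)
    n = len(s)
    lo, hi = n / 4.0, 3.0 * n / 4.0
    total = 0.0
    weight = 0.0
    for i, v in enumerate(s):
        w = max(0.0, min(i + 1.0, hi) - max(float(i), lo))
        total += w * v
        weight += w
    return total / weight
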