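import numpy as np
import pandas as pd
import pytest

from pptkit.core import GlucoseTrace, MealEvent


@pytest.fixture
def t0():
    return pd.Timestamp("2020-01-01 08:00")


@pytest.fixture
def quarter_hour_grid():
    def make(n, start="2020-01-01 08:00"):
        s = pd.Timestamp(start)
        return [s + pd.Timedelta(minutes=15 * i) for i in range(n)]

    return make


@pytest.fixture
def triangular_trace(quarter_hour_grid):
    """100 mg/dl baseline rising linearly to 160 at 60 min, back to 100 at
    120 min, 15-min sampling: true 2-h iAUC above 100 is 60 mg/dl x h."""
    return GlucoseTrace(
        "p00", quarter_hour_grid(9), [100, 115, 130, 145, 160, 145, 130, 115, 100]
    )


@pytest.fixture
def random_day_trace():
    """Factory for randomized <= 1-day traces used by the oracle suite."""

    def make(rng: np.random.Generator, n_readings: int | None = None):
        n = n_readings or int(rng.integers(60, 97))
        start = pd.Timestamp("2020-01-01") + pd.Timedelta(minutes=int(rng.integers(0, 120)))
        ts = [start + pd.Timedelta(minutes=15 * i) for i in range(n)]
        glu = np.clip(
            140 + 30 * rng.standard_normal(n).cumsum() / np.sqrt(np.arange(1, n + 1)),
            45, 350,
        )
        # one connection unless the trace is long enough to split
        conns = [(0, n)] if n < 80 else [(0, n // 2), (n // 2, n)]
        return GlucoseTrace("p00", ts, glu, conns)

    return make


def make_meal(pid="p00", when="2020-01-01 08:00", kcal=400.0, score=None, **kw):
    return MealEvent(pid, pd.Timestamp(when), kcal=kcal, meal_score=score, **kw)
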