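import numpy as np
import pandas as pd
import pytest

from graintrap.core import LOCATIONS
from graintrap.simulate import SimConfig, simulate_experiment


def make_records(
    counts_by_day: dict[int, dict[tuple[str, str], int]],
    bin_id: str = "bin1",
    density: float = 1.0,
    mc: float = 10.7,
    days: int = 10,
    temperature: float = 26.0,
    humidity: float = 45.0,
) -> pd.DataFrame:
    """Build a complete single-bin record table from sparse count overrides.

    ``counts_by_day[day][(layer, position)]`` sets a count; everything else
    is zero.  All 15 locations are present every day.
    """
    rows = []
    for day in range(1, days + 1):
        overrides = counts_by_day.get(day, {})
        for loc in LOCATIONS:
            rows.append(
                {
                    "bin_id": bin_id,
                    "replicate_id": "R1",
                    "density": density,
                    "mc": mc,
                    "day": day,
                    "layer": loc.layer.value,
                    "position": loc.position.value,
                    "count": overrides.get(loc.key, 0),
                    "temperature": temperature,
                    "humidity": humidity,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def default_sim():
    """One full synthetic experiment under the default study design."""
    return simulate_experiment(SimConfig(seed=20240917))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
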