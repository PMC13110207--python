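import numpy as np
import pandas as pd
import pytest

from rbmscore.io import LabTable, SiteAggregateTable, TimeTable


@pytest.fixture
def toy_agg() -> SiteAggregateTable:
    return SiteAggregateTable(
        pd.DataFrame(
            {
                "site": ["S01", "S02", "S03"],
                "n_screen": [20, 30, 25],
                "n_enrolled": [15, 22, 18],
                "y_fail": [5, 8, 7],
                "y_window": [2, 1, 0],
                "y_bii": [3, 2, 4],
                "n_bii": [15, 22, 18],
                "m_shift": [0, 1, 0],
            }
        )
    )


@pytest.fixture
def toy_labs(toy_agg) -> LabTable:
    rng = np.random.default_rng(42)
    rows = []
    for _, r in toy_agg.frame.iterrows():
        vals = rng.normal(80, 15, int(r["n_enrolled"]))
        rows.append(pd.DataFrame({"site": r["site"], "lab_value": vals}))
    return LabTable(pd.concat(rows, ignore_index=True))


@pytest.fixture
def toy_times(toy_agg) -> TimeTable:
    rng = np.random.default_rng(43)
    rows = []
    for _, r in toy_agg.frame.iterrows():
        vals = np.exp(rng.normal(np.log(7), 0.4, int(r["n_screen"])))
        rows.append(pd.DataFrame({"site": r["site"], "screening_time": vals}))
    return TimeTable(pd.concat(rows, ignore_index=True))


@pytest.fixture(scope="session")
def small_trial():
    """A small simulated trial shared across tests (12 sites)."""
    from rbmscore.simulate import TrialConfig, simulate_trial

    cfg = TrialConfig(n_sites=12, atypical_fraction=0.25)
    return simulate_trial(cfg, seed=123)
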