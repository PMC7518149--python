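import numpy as np
import pandas as pd
import pytest

import milkorder as mo


@pytest.fixture(scope="session")
def small_config():
    return mo.SimConfig(
        n_cows=60,
        n_days=40,
        pen_days=15,
        seed=3,
        missing_rate=0.05,
        outlier_days=(20, 22),
    )


@pytest.fixture(scope="session")
def small_herd(small_config):
    return mo.draw_herd(small_config)


@pytest.fixture(scope="session")
def small_qm(small_config, small_herd):
    log = mo.simulate_milkings(small_herd, small_config)
    return mo.filter_cows(mo.filter_days(mo.to_quantiles(log), warmup=0, drop_windows=[]))


@pytest.fixture(scope="session")
def mu_by_cow(small_herd):
    return pd.Series({p.cow_id: p.mu for p in small_herd})


def toy_milklog(positions_by_day, subperiods=None):
    """Build a MilkLog from {day: {cow_id: position}}."""
    rows = []
    for day, posmap in positions_by_day.items():
        sp = (subperiods or {}).get(day, "pen")
        for cow, pos in posmap.items():
            rows.append((day, sp, cow, pos))
    return mo.MilkLog(
        pd.DataFrame(rows, columns=["day", "subperiod", "cow_id", "position"])
    )


@pytest.fixture
def make_milklog():
    return toy_milklog


def qm_from_values(values, subperiods=None, enrolled=None):
    """QuantileMatrix straight from a cows x days array (NaN = missing)."""
    df = pd.DataFrame(np.asarray(values, float))
    df.index.name = "cow_id"
    sub = pd.Series(
        subperiods if subperiods is not None else ["pen"] * df.shape[1],
        index=df.columns,
    )
    return mo.QuantileMatrix(df, sub, enrolled)


@pytest.fixture
def make_qm():
    return qm_from_values
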