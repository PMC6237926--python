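import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from yieldtrends.panel import YieldPanel
from yieldtrends.synthetic import reference_fixture


def make_panel(rows):
    """Build a YieldPanel from (dept, crop, season, year, area, prod, yld)."""
    df = pd.DataFrame(
        rows,
        columns=["department_id", "crop", "season_type", "year",
                 "area_ha", "production_t", "yield_t_ha"],
    )
    return YieldPanel(df)


@pytest.fixture(scope="session")
def fixture_panel_truth():
    return reference_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
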