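import numpy as np
import pandas as pd
import pytest

import myoscore as ms


@pytest.fixture(scope="session")
def tool():
    return ms.default_tool()


@pytest.fixture(scope="session")
def fixtures():
    return ms.load_fixtures()


@pytest.fixture(scope="session")
def study():
    """One simulated study at the default (published-layout) conditions."""
    return ms.simulate_study(ms.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def quad_item_scores(study):
    """Main-exercise quadriceps ratings of one item (complete 11x11 table)."""
    s1 = study.scores[study.scores["session"] == 1]
    sub = s1[s1["case_id"].isin(study.main_cases["quadriceps"])]
    return sub[sub["item_id"] == "cd3_endomysial"]


@pytest.fixture()
def balanced_table():
    rng = np.random.default_rng(202)
    theta = rng.normal(0, 1.0, 12)[:, None]
    b = rng.normal(0, 0.4, 6)[None, :]
    e = rng.normal(0, 0.5, (12, 6))
    return pd.DataFrame(theta + b + e)
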