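import numpy as np
import pytest

import deltacpue as dc

#: Reduced categorical design used for simulation experiments: 4 year and 4
#: month levels keep the fixed-effect count small while exercising every
#: term type (year, month, fleet, observer).
REDUCED_YEARS = (2000, 2001, 2002, 2003)
REDUCED_MONTHS = (1, 4, 7, 10)


def reduced_truth(seed, n_sets, n_vessels=30, **overrides):
    """Study-condition truth restricted to the reduced design."""
    per_fleet = {"local": n_vessels // 2, "foreign": n_vessels - n_vessels // 2}
    truth = dc.default_truth(seed=seed, n_sets=n_sets, years=REDUCED_YEARS,
                             months=REDUCED_MONTHS,
                             n_vessels_by_fleet=per_fleet)
    for key, val in overrides.items():
        setattr(truth, key, val)
    return truth


@pytest.fixture(scope="session")
def small_logbook():
    """2,000-set logbook under the full 16-year design."""
    truth = dc.default_truth(seed=42, n_sets=2000)
    records, _ = dc.generate_logbook(truth)
    return records


@pytest.fixture(scope="session")
def reduced_logbook():
    """4,000-set logbook under the reduced design, with its truth."""
    truth = reduced_truth(seed=17, n_sets=4000, n_vessels=20)
    records, truth = dc.generate_logbook(truth)
    return records, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
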