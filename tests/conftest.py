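import numpy as np
import pytest
from hypothesis import settings

import tcalkit as tk
from tcalkit import mortality_io as mio
from tcalkit import synthetic_data as synth

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def time_invariant_surface(m, n_years, sex="female", terminal_year=2020):
    """Surface whose every year column equals the rate vector m.

    Years cover ``terminal_year - n_years .. terminal_year - 1`` — the
    cells a TCAL with window ``[terminal_year - n_years, terminal_year]``
    reads.
    """
    m = np.asarray(m, dtype=float)
    return tk.MortalitySurface(
        sex=sex,
        ages=np.arange(m.size),
        years=np.arange(terminal_year - n_years, terminal_year),
        rates=np.tile(m[:, None], (1, n_years)),
    )


@pytest.fixture(scope="session")
def paper_params():
    return synth.paper_like_params()


@pytest.fixture(scope="session")
def paper_expected(paper_params):
    """Deterministic (expected-count) full paper-like dataset with cause rates."""
    data = synth.generate_dataset(paper_params, mode="expected")
    for sex in data:
        data[sex]["cause_rates"] = mio.cause_specific_rates(
            data[sex]["rates"], data[sex]["counts"]
        )
    return data


@pytest.fixture(scope="session")
def small_params():
    """Reduced grid for pipeline smoke tests."""
    return synth.paper_like_params(age_max=40, year_start=2005, year_end=2020)
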