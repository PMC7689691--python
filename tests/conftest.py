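import numpy as np
import pytest

import banditaqm as baq


@pytest.fixture
def desk_mcmc():
    """Reduced sampler effort used throughout the suite (R-hat checked)."""
    return baq.McmcSettings.desk()


@pytest.fixture
def prior():
    return baq.PriorSpec()


@pytest.fixture
def default_generator():
    return baq.default_generator_config(seed=123)


@pytest.fixture
def stationary_pools(default_generator):
    return baq.generate_stationary(default_generator)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_records(rows):
    """rows: (installation_id, treatment_id, iso_date, concentration)."""
    import io

    header = "installation_id,treatment_id,record_date,n_effluent_mg_l\n"
    body = "\n".join(",".join(map(str, r)) for r in rows)
    return io.StringIO(header + body + ("\n" if body else ""))
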