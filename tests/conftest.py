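import pytest

import ctenofa as cf
from ctenofa import io as cio
from ctenofa.metrics import metrics_table


@pytest.fixture(scope="session")
def default_study():
    """One full synthetic survey at the default study conditions."""
    config = cf.SimulationConfig(seed=42)
    tree, records, truth, profiles, standards, peaks, spectra = cf.simulate_study(
        config, rel_noise=0.0
    )
    return {
        "config": config,
        "tree": tree,
        "records": records,
        "truth": truth,
        "profiles": profiles,
        "standards": standards,
        "peaks": peaks,
        "spectra": spectra,
    }


@pytest.fixture(scope="session")
def default_metrics(default_study):
    return metrics_table(default_study["profiles"])


@pytest.fixture(scope="session")
def default_compositions(default_study):
    return cio.composition_wide(default_study["profiles"])
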