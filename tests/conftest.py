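import numpy as np
import pytest

from dnadistort import io_formats


@pytest.fixture(scope="session")
def panel():
    return io_formats.load_fixture_panel()


@pytest.fixture(scope="session")
def panel_counts(panel):
    """Per-site G:C>T:A counts under the published panel totals."""
    from dnadistort.hotspot_stats import SiteMutationCount

    return [
        SiteMutationCount(f"codon{fx.codon}", fx.observed_gt, 421, 353)
        for fx in panel
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
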