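import numpy as np
import pandas as pd
import pytest

from misl.signal_model import MISLModelParams, SaturationScheme


@pytest.fixture
def params():
    """Group-mean quantification constants of the 3 T protocol."""
    return MISLModelParams(alpha=0.42, r1rho_tissue_s1=1.72, r1_csf_s1=0.23)


@pytest.fixture
def scheme():
    """The labeling train: 50 sincgauss pulses, 3 uT, 50/25 ms, -10 ppm."""
    return SaturationScheme()


@pytest.fixture
def paired_table():
    """Builder for a two-session long-format region table."""

    def _build(data, region="whole_brain_csf", metric="mean_tcf"):
        rows = []
        for i, (a, b) in enumerate(np.atleast_2d(data)):
            rows.append(
                {"subject": f"s{i}", "session": 1, "region": region, metric: a}
            )
            rows.append(
                {"subject": f"s{i}", "session": 2, "region": region, metric: b}
            )
        return pd.DataFrame(rows)

    return _build
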