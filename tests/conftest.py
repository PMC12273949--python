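import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_variant_row(position, ref="A", alt="G", freq=0.95, reads_plus=10, reads_minus=10, **kw):
    row = {
        "strain": "S", "block": "B1", "line": "L1",
        "position": position, "ref": ref, "alt": alt, "class": "BPS",
        "freq": freq, "reads_plus": reads_plus, "reads_minus": reads_minus,
        "region": "noncoding", "coding_effect": "not_applicable", "gene": "",
    }
    row.update(kw)
    return row


@pytest.fixture
def toy_variants():
    """Seven-row variant table: 5 pass the default filters, 2 fail."""
    rows = [
        make_variant_row(100),
        make_variant_row(200, ref="C", alt="T"),
        make_variant_row(300, ref="G", alt="T"),
        make_variant_row(400, ref="T", alt="A"),
        make_variant_row(500, ref="A", alt="C"),
        make_variant_row(600, freq=0.50),            # fails frequency filter
        make_variant_row(700, reads_plus=3),          # fails strand support
    ]
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
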