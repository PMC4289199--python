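import numpy as np
import pytest

import recspot as rs


@pytest.fixture(scope="session")
def table():
    return rs.PhysicoChemTable.default()


@pytest.fixture(scope="session")
def planted_small():
    """Small planted-signal dataset: CG-enriched hot class vs uniform cold.

    Short sequences keep every downstream fit fast while the enrichment is
    strong enough to be linearly separable.
    """
    cfg = rs.SyntheticConfig(
        n_hot=15, n_cold=18, length_range=(800, 1200), planted_kmers=(("CG", 3.0),), seed=7
    )
    seqs, y = rs.generate_dataset(cfg)
    X, layout = rs.encode_dataset(seqs, k_max=2, params=rs.PseDncParams(omega=5))
    return rs.LabeledMatrix(X, y, layout.names), cfg

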