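"""Shared fixtures: hand-built and synthetic datasets, panel statistics."""

import numpy as np
import pytest

from svrsar.data_io import CompoundRecord, DataSet, FingerprintScheme
from svrsar.sari import panel_stats, score_dataset
from svrsar.synthetic_data import PanelConfig, SyntheticConfig, generate_dataset, generate_reference_panel


def make_dataset(fingerprints, pkis, universe=32, t=0.56, target_id="toy"):
    """Build a DataSet from raw on-bit sets and potencies."""
    scheme = FingerprintScheme("synthetic", universe, t)
    records = [
        CompoundRecord(f"C{i}", frozenset(fp), float(p))
        for i, (fp, p) in enumerate(zip(fingerprints, pkis))
    ]
    return DataSet(target_id=target_id, scheme=scheme, records=records)


@pytest.fixture(scope="session")
def cliff_dataset():
    """Standard cliff fixture: 80 compounds, 10% planted activity cliffs."""
    return generate_dataset(
        SyntheticConfig(n_compounds=80, n_clusters=8, cliff_fraction=0.1, seed=7)
    )


@pytest.fixture(scope="session")
def smooth_dataset():
    """Cliff-free counterpart of the standard fixture (same seed)."""
    return generate_dataset(
        SyntheticConfig(n_compounds=80, n_clusters=8, cliff_fraction=0.0, seed=7)
    )


@pytest.fixture(scope="session")
def small_panel_stats():
    """Panel statistics from a small (fast) mixed synthetic panel."""
    panel = generate_reference_panel(
        PanelConfig(n_sets=20, size_range=(40, 60), seed=3)
    )
    scores = [score_dataset(ds) for ds in panel]
    return panel_stats(
        [s.cont_raw for s in scores], [s.disc_raw for s in scores]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
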