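import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mave_scorer import constants as C
from mave_scorer.integrate import assemble_matrix, call_dominant_negative
from mave_scorer.scoring import score_assay
from mave_scorer.simulate import (
    SimConfig,
    simulate_barcode_library,
    simulate_counts,
    simulate_truth,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    """The default stated-world simulation: 2,000 variants, 3 replicates."""
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def default_truth(default_config) -> pd.DataFrame:
    return simulate_truth(default_config)


@pytest.fixture(scope="session")
def default_barcodes(default_config, default_truth) -> pd.DataFrame:
    return simulate_barcode_library(default_truth, default_config)


@pytest.fixture(scope="session")
def default_scoresets(default_config, default_truth, default_barcodes) -> dict:
    """Scored output of all four assays on the default simulation."""
    bc_map = default_barcodes.rename(columns={"weight": "support"})
    out = {}
    for assay in C.ASSAYS:
        counts = simulate_counts(
            default_truth, default_config, assay, barcodes=default_barcodes
        )
        out[assay] = score_assay(counts, assay, barcode_map=bc_map)
    return out


@pytest.fixture(scope="session")
def default_matrix(default_scoresets) -> pd.DataFrame:
    return assemble_matrix({a: r.scores for a, r in default_scoresets.items()})


@pytest.fixture(scope="session")
def default_dn_calls(default_matrix) -> pd.DataFrame:
    return call_dominant_negative(default_matrix)


@pytest.fixture(scope="session")
def tiny_read_config() -> SimConfig:
    """Small library for read-level subassembly tests."""
    return SimConfig(
        n_variants=40,
        protein_length=60,
        barcodes_per_variant_mean=4.0,
        reads_per_barcode_mean=15.0,
        seq_error_rate=0.005,
        seed=3,
    )


def make_variant_counts(
    table: dict[str, dict[str, float]], replicate: int = 1
) -> pd.DataFrame:
    """Long count table from {variant: {sample: rpm}} (test helper)."""
    rows = [
        {"entity_id": v, "sample": s, "replicate": replicate, "rpm": rpm}
        for v, samples in table.items()
        for s, rpm in samples.items()
    ]
    return pd.DataFrame(rows)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
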