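"""Shared fixtures: small synthetic datasets generated at test time."""

import warnings

import numpy as np
import pytest

from crevar.syndata import (
    DETERMINISTIC_CRITERIA,
    MultiomeConfig,
    SimConfig,
    StarrConfig,
    VariantConfig,
    simulate_multiome,
    simulate_starr_counts,
    simulate_variant_sets,
)


@pytest.fixture(autouse=True)
def _quiet_warnings():
    """Tests assert on warnings explicitly where they matter."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def multiome():
    return simulate_multiome(SimConfig(seed=101))


@pytest.fixture(scope="session")
def multiome_no_markers():
    """Markerless multiome: clean null pairs for link-recovery checks."""
    cfg = SimConfig(seed=11, multiome=MultiomeConfig(n_marker_peaks=0,
                                                     n_marker_genes=0))
    return simulate_multiome(cfg)


@pytest.fixture(scope="session")
def starr_null():
    """No planted effects; used for calibration checks."""
    cfg = SimConfig(seed=301, starr=StarrConfig(n_snps=500, n_control_snps=100))
    return simulate_starr_counts(cfg)


@pytest.fixture(scope="session")
def variant_sets_deterministic():
    cfg = SimConfig(
        seed=7,
        variants=VariantConfig(channel_pool=DETERMINISTIC_CRITERIA),
    )
    return simulate_variant_sets(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
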