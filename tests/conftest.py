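"""Shared fixtures: the bundled catalog and a small planted cohort."""

from __future__ import annotations

import pytest

from mlidscan.io import bundled_idmr_catalog
from mlidscan.simulate import (
    PlantedEvent,
    SyntheticCohortConfig,
    generate_cohort,
    generate_manifest,
)


@pytest.fixture(scope="session")
def catalog():
    return bundled_idmr_catalog()


@pytest.fixture(scope="session")
def planted_cohort(catalog):
    """4 controls + 6 patients; P1/P3 are MLID-positive by construction."""
    config = SyntheticCohortConfig(
        n_patients=6,
        planted_events=[
            PlantedEvent("P1", "KCNQ1OT1:TSS-DMR", "LoM", 0.3),
            PlantedEvent("P1", "PPIEL:Ex1-DMR", "LoM", 0.3),
            PlantedEvent("P2", "KCNQ1OT1:TSS-DMR", "LoM", 0.3),
            PlantedEvent("P3", "H19/IGF2:IG-DMR", "GoM", 0.3),
            PlantedEvent("P3", "FAM50B:TSS-DMR", "LoM", 0.3),
        ],
        seed=42,
    )
    manifest = generate_manifest(config, catalog)
    beta, truth = generate_cohort(config, manifest, catalog)
    return config, manifest, beta, truth
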