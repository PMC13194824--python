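"""Shared fixtures: a desk-scale genome model and small simulated samples.

All fixtures are generated programmatically with fixed seeds; nothing is
read from disk.
"""

import numpy as np
import pandas as pd
import pytest

from fragdecipher.pfe import PFEConfig
from fragdecipher.synthetic import (
    SampleProfile,
    SimulationConfig,
    build_genome_model,
    simulate_sample,
)


@pytest.fixture(scope="session")
def small_model():
    """12 arms x 6 genes: large enough for every feature family, small
    enough that a full PFE pass takes well under a second."""
    return build_genome_model(
        SimulationConfig(n_arms=12, genes_per_arm=6, n_active=10,
                         background_size=40, seed=7)
    )


@pytest.fixture(scope="session")
def fast_pfe_config():
    """Reduced Dirichlet draw count for unit tests whose assertions do not
    depend on draw-level precision."""
    return PFEConfig(n_dirichlet=400, seed=3)


@pytest.fixture(scope="session")
def healthy_sample(small_model):
    return simulate_sample(
        small_model,
        SampleProfile(label="healthy", target_fragment_count=30_000, seed=11),
    )


@pytest.fixture(scope="session")
def cancer_sample(small_model):
    return simulate_sample(
        small_model,
        SampleProfile(
            label="cancer",
            tumor_fraction=0.2,
            entropy_boost_genes=tuple(small_model.active_genes),
            arm_copy_factors={"1q": 1.5, "4p": 0.6},
            target_fragment_count=30_000,
            seed=13,
        ),
    )


def make_fragments(records, sample_id="t"):
    """Helper: FragmentSet from a list of (chrom, start, end)."""
    from fragdecipher.fragments import FragmentSet

    return FragmentSet(
        sample_id=sample_id,
        records=pd.DataFrame(records, columns=["chrom", "start", "end"]),
    )
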