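from __future__ import annotations

import numpy as np
import pytest

from exocomm.synthetic import SyntheticConfig, TissueSpec, generate_bundle
from exocomm.workflow import BundleInputs, PipelineParams, run_pipeline


def tiny_synthetic_config(**overrides) -> SyntheticConfig:
    """A small, fast bundle in the fully recoverable regime."""
    defaults = dict(
        seed=11,
        n_genes=400,
        n_mito_genes=5,
        tissues=(
            TissueSpec("neonatal", {"EC": 60, "FB": 50, "MAC": 40}, max_mito_fraction=0.25),
            TissueSpec("adult", {"EC": 40, "FB": 60, "MAC": 50}, max_mito_fraction=0.15),
        ),
        markers_per_type=20,
        marker_fold=8.0,
        planted_ligands=12,
        planted_receptors=12,
        planted_pairs=15,
        decoy_ligands=5,
        decoy_receptors=5,
        decoy_pairs=5,
        background_proteins=30,
        n_go_terms=15,
        genes_per_term=(8, 18),
        shared_terms=3,
        ligands_per_shared_term=6,
        receptors_per_shared_term=5,
        nb_mean=2.0,
        mito_mean_factor=3.0,
        qc_low_gene_fraction=0.02,
        qc_high_gene_fraction=0.0,
        qc_high_mito_fraction=0.02,
        n_rare_genes=2,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_config() -> SyntheticConfig:
    return tiny_synthetic_config()


@pytest.fixture(scope="session")
def tiny_bundle(tiny_config):
    return generate_bundle(tiny_config)


@pytest.fixture(scope="session")
def tiny_result(tiny_bundle):
    return run_pipeline(BundleInputs.from_bundle(tiny_bundle), PipelineParams(seed=1))


@pytest.fixture(scope="session")
def default_bundle():
    """The full-size study-condition bundle (seed 7)."""
    return generate_bundle(SyntheticConfig())


@pytest.fixture(scope="session")
def default_result(default_bundle):
    return run_pipeline(BundleInputs.from_bundle(default_bundle), PipelineParams(seed=0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
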