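import numpy as np
import pytest

import bbpls
from bbpls.preprocess import residualize_dataset


@pytest.fixture(scope="session")
def small_cfg():
    return bbpls.SyntheticConfig(
        n_subjects=150,
        n_sites=3,
        n_parcels_cortical=20,
        n_parcels_subcortical=4,
        n_items=15,
        n_latent=3,
        latent_strength=(5.0, 3.0, 2.0),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return bbpls.generate_dataset(small_cfg)


@pytest.fixture(scope="session")
def small_assets(small_cfg):
    return bbpls.generate_parcellation_assets(small_cfg)


@pytest.fixture(scope="session")
def strong_fit():
    """Residualized + reduced + decomposed strong-signal cohort, reused across tests."""
    cfg = bbpls.SyntheticConfig(
        n_subjects=800,
        n_sites=4,
        n_parcels_cortical=40,
        n_parcels_subcortical=6,
        n_items=30,
        n_latent=3,
        latent_strength=(5.0, 3.0, 2.0),
        confound_strength=0.5,
        seed=7,
    )
    dataset, truth = bbpls.generate_dataset(cfg)
    blocks, behavior = residualize_dataset(dataset)
    model, X = bbpls.fit_reduction(blocks, 0.5)
    result = bbpls.pls_decompose(X, behavior)
    return dict(cfg=cfg, dataset=dataset, truth=truth, blocks=blocks,
                behavior=behavior, model=model, X=X, result=result)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
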