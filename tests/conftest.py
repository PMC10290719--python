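import numpy as np
import pytest

from kinoprof.features import featurize_records
from kinoprof.models import PredictorConfig, VariantSpec
from kinoprof.pharm3d import build_signature_space
from kinoprof.simulate import SimConfig, sample_compounds, simulate_bioactivity, simulate_catalog


@pytest.fixture(scope="session")
def space():
    return build_signature_space()


@pytest.fixture(scope="session")
def small_sim():
    """Desk-scale synthetic dataset: 8 kinases x 12 compounds, width 40."""
    cfg = SimConfig(
        n_kinases=8, alignment_width=40, n_groups=2, n_compounds=12, seed=11
    )
    catalog, site_map = simulate_catalog(cfg)
    compounds = sample_compounds(cfg.n_compounds, seed=cfg.seed + 2)
    data = simulate_bioactivity(catalog, compounds, cfg)
    return catalog, site_map, compounds, data


@pytest.fixture(scope="session")
def small_bundle(small_sim):
    """Featurized (variant 3-2) bundle of the small synthetic dataset."""
    catalog, site_map, _, data = small_sim
    return featurize_records(data.records, catalog, "3-2", site_map=site_map, seed=5)


def tiny_config(variant="3-2", kinase_length=40, kinase_channels=21, **over):
    """A predictor configuration small enough for second-scale training."""
    base = dict(
        variant=VariantSpec(variant),
        kinase_length=kinase_length,
        kinase_channels=kinase_channels,
        conv_channels=8,
        kernel_sizes=(3,),
        attention_heads=2,
        embed_dim=16,
        head_dims=(32, 16),
        seed=0,
    )
    base.update(over)
    return PredictorConfig(**base)


@pytest.fixture
def tiny_config_factory():
    return tiny_config
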