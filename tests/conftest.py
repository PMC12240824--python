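import numpy as np
import pytest

from conncodec.flavors import EdgeVectorSet, FlavorSpec
from conncodec.synth import SyntheticSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def tiny_flavors():
    """Three flavors on two small atlases (2 FC + 1 SC)."""
    return [
        FlavorSpec("X8_FC", "FC", "X8", 8, fc_variant="pearson"),
        FlavorSpec("X8_SCpr", "SC", "X8", 8, sc_variant="prob"),
        FlavorSpec("Y10_FC", "FC", "Y10", 10, fc_variant="pearson"),
    ]


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small, fast synthetic cohort shared by unit tests (read-only)."""
    spec = SyntheticSpec(
        n_subj=60, flavors=tiny_flavors(), latent_dim=6, overlap=0.7,
        noise_sd=0.2, n_mz=6, n_dz=4, n_sib=6, n_retest=5,
        n_train=40, n_val=8, n_test=12, seed=77,
    )
    edge_sets, cohort, truth = generate_cohort(spec)
    return spec, edge_sets, cohort, truth


def random_edge_set(flavor: FlavorSpec, n_subj: int,
                    rng: np.random.Generator) -> EdgeVectorSet:
    ids = [f"s{i:03d}" for i in range(n_subj)]
    return EdgeVectorSet(flavor, ids, rng.standard_normal((n_subj, flavor.n_edges)))
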