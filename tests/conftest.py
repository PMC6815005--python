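import numpy as np
import pytest

from katzmda import (
    AssociationDataset,
    DiseaseDAG,
    SyntheticConfig,
    generate,
)
from katzmda.semantic import semantic_similarity_matrix


@pytest.fixture(scope="session")
def tiny_dataset() -> AssociationDataset:
    """3 diseases x 4 metabolites, 5 known pairs — small enough to hand-check."""
    return AssociationDataset.from_pairs(
        [("d1", "m1"), ("d1", "m2"), ("d2", "m2"), ("d2", "m3"), ("d3", "m4")]
    )


@pytest.fixture(scope="session")
def chain_dags() -> dict[str, DiseaseDAG]:
    """d1 and d2 share ancestor A; d3 is isolated."""
    return {
        "d1": DiseaseDAG("d1", {"A", "d1"}, {("A", "d1")}),
        "d2": DiseaseDAG("d2", {"A", "d2"}, {("A", "d2")}),
        "d3": DiseaseDAG("d3", {"d3"}, set()),
    }


@pytest.fixture(scope="session")
def preset_world():
    """The default planted-cluster synthetic world (seed 7) plus its DSS."""
    dataset, dags, truth = generate(SyntheticConfig())
    dss = semantic_similarity_matrix(dags, dataset.disease_ids)
    return dataset, dags, truth, dss


def random_hetero_blocks(rng: np.random.Generator, n_m: int, n_d: int):
    """Random symmetric similarity blocks + 0/1 adjacency for oracle tests."""
    SM = rng.random((n_m, n_m))
    SM = (SM + SM.T) / 2
    SD = rng.random((n_d, n_d))
    SD = (SD + SD.T) / 2
    M = (rng.random((n_d, n_m)) < 0.4).astype(float)
    return SM, SD, M
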