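import numpy as np
import pytest

from vdireg.containers import ImagingMatrix, Phenotype


def make_matrix(n=20, m=8, seed=0, modality="SIM"):
    rng = np.random.default_rng(seed)
    return ImagingMatrix(
        values=rng.normal(size=(n, m)),
        subject_ids=np.array([f"s{i}" for i in range(n)], dtype=object),
        voxel_ids=np.array([f"{modality}:v{j}" for j in range(m)], dtype=object),
        modality=modality,
    )


def make_phenotype(X, seed=1, label="trait"):
    rng = np.random.default_rng(seed)
    return Phenotype(
        y=rng.normal(size=X.n_subjects),
        subject_ids=X.subject_ids.copy(),
        trait_label=label,
    )


@pytest.fixture
def small_matrix():
    return make_matrix()


@pytest.fixture
def small_phenotype(small_matrix):
    return make_phenotype(small_matrix)
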