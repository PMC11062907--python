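import numpy as np
import pandas as pd
import pytest

from trainstates.core import GROUPS, SEXES, FeatureMatrix, StudyDesign
from trainstates.synthgen import SynthConfig, generate_study


def build_design(
    n_per_group: int = 6,
    sexes=SEXES,
    groups=GROUPS,
    tissue: str = "muscle",
    ome: str = "metabolomics",
) -> StudyDesign:
    rows = [
        {
            "sample_id": f"{sex}_{group}_r{i + 1}",
            "sex": sex,
            "group": group,
            "tissue": tissue,
            "ome": ome,
        }
        for sex in sexes
        for group in groups
        for i in range(n_per_group)
    ]
    return StudyDesign(pd.DataFrame(rows))


def build_matrix(
    design: StudyDesign,
    n_features: int = 50,
    noise_sd: float = 1.0,
    seed: int = 0,
    tissue: str = "muscle",
    ome: str = "metabolomics",
) -> FeatureMatrix:
    """Pure-noise continuous matrix aligned to a design (for toy tests)."""
    rng = np.random.default_rng(seed)
    samples = design.for_matrix(tissue, ome).index
    data = pd.DataFrame(
        rng.normal(0.0, noise_sd, size=(n_features, len(samples))),
        index=[f"feat{i:04d}" for i in range(n_features)],
        columns=samples,
    )
    return FeatureMatrix(data, tissue, ome, kind="continuous", log_scale=True)


@pytest.fixture(scope="session")
def small_study():
    """One-tissue, one-ome synthetic study with 20% signal."""
    cfg = SynthConfig(
        n_features=500,
        frac_null=0.8,
        omes=(("metabolomics", "continuous"),),
        tissues=("liver",),
        seed=11,
    )
    return generate_study(cfg)


@pytest.fixture(scope="session")
def toy_design():
    return build_design(n_per_group=4)
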