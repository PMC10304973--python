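import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from coremicro.synthetic_data import CommunityModel, StudyDesign, generate_study
from coremicro.tables_io import FeatureTable, SampleMetadata, TaxonomyMap


@pytest.fixture
def toy_tree() -> TreeNode:
    """Balanced 4-tip tree with unit branch lengths and a zero-length root."""
    return TreeNode.read(io.StringIO("((A:1,B:1):1,(C:1,D:1):1):0;"))


@pytest.fixture
def toy_table() -> FeatureTable:
    return FeatureTable(
        pd.DataFrame(
            [[5, 0, 2, 1], [1, 3, 0, 0], [4, 4, 4, 4]],
            index=["s1", "s2", "s3"],
            columns=["A", "B", "C", "D"],
        )
    )


def make_metadata(rows) -> SampleMetadata:
    """rows: (sample_id, country, household, sample_type) tuples."""
    frame = pd.DataFrame(
        rows, columns=["sample_id", "country", "household", "sample_type"]
    ).set_index("sample_id")
    return SampleMetadata(frame)


def make_taxonomy(mapping) -> TaxonomyMap:
    return TaxonomyMap.from_strings(mapping)


def random_table(rng, n_samples=6, n_features=10, depth=200) -> FeatureTable:
    counts = rng.multinomial(depth, rng.dirichlet(np.ones(n_features)), size=n_samples)
    return FeatureTable(
        pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"f{j}" for j in range(n_features)],
        )
    )


@pytest.fixture(scope="session")
def small_study():
    """Compact synthetic study reused across tests (deterministic)."""
    design = StudyDesign(households_per_country=4, n_taxa=40)
    model = CommunityModel(n_core=6, n_bloom=3, n_rare=2)
    return generate_study(design, model, seed=11)


@pytest.fixture(scope="session")
def default_study():
    """Default stated-world study (5 countries x 15 households, 60 taxa)."""
    return generate_study(seed=5)
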