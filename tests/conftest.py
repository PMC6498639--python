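import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from ssdfate.io import ExpressionMatrix
from ssdfate.tree import SpeciesTree

TISSUES = ["leaf", "anther", "pistil", "embryo"]


@pytest.fixture
def tissues():
    return list(TISSUES)


@pytest.fixture
def raw_matrix():
    data = pd.DataFrame(
        [[0.0, 5.0, 1.0, 0.0], [3.0, 3.0, 3.0, 3.0], [0.2, 0.4, 0.1, 0.0]],
        index=["g1", "g2", "g3"],
        columns=TISSUES,
    )
    return ExpressionMatrix(data, species="test")


@pytest.fixture
def simple_tree():
    return SpeciesTree.from_newick("((A,B),C);", is_path=False)
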