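import numpy as np
import pytest
from skbio import TreeNode

from regiondiv.types import OTUTable


@pytest.fixture
def small_table():
    return OTUTable(
        sample_ids=["s1", "s2", "s3"],
        otu_ids=["A", "B", "C", "D"],
        counts=np.array([[3, 0, 1, 7],
                         [5, 5, 0, 0],
                         [1, 1, 1, 1]]),
    )


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); — total branch length 5."""
    return TreeNode.read(["((A:1,B:1):1,C:2);"])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
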