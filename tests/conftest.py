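import numpy as np
import pandas as pd
import pytest

from splenopt import default_preset, generate_cohort
from splenopt.tree import Node, PolicyTree


@pytest.fixture(scope="session")
def spec20k():
    return default_preset(n_patients=20_000, seed=7)


@pytest.fixture(scope="session")
def cohort20k(spec20k):
    return generate_cohort(spec20k)


@pytest.fixture()
def toy_cohort():
    """Six patients with hand-countable arms and outcomes."""
    return pd.DataFrame({
        "age": [30, 40, 50, 60, 25, 35],
        "sbp": [120, 110, 80, 70, 130, 100],
        "hr": [80, 90, 120, 130, 70, 85],
        "treatment": ["OBS", "OBS", "AE", "SPLENECTOMY", "OBS", "AE"],
        "death": [0, 1, 0, 1, 0, 0],
    })


@pytest.fixture()
def figure_style_tree():
    """Hand-built depth-2 tree: shock index at 1.551; the shocked branch
    splits on early pRBC transfusion (no -> AE, yes -> splenectomy)."""
    root = Node(
        feature="shock_index", threshold=1.551,
        left=Node(treatment="AE"),
        right=Node(
            feature="prbc_1h", threshold=0.5,
            left=Node(treatment="AE"),
            right=Node(treatment="SPLENECTOMY"),
        ),
    )
    return PolicyTree(root=root, max_depth=2)
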