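import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from guteco.data import OtuTable
from guteco.simulate import SimulationConfig, simulate_study


@pytest.fixture
def four_tip_tree() -> TreeNode:
    """Balanced 4-tip tree: ((A:1,B:1):1,(C:1,D:1):1);"""
    return TreeNode.read(["((A:1,B:1):1,(C:1,D:1):1);"])


@pytest.fixture
def small_table() -> OtuTable:
    counts = np.array([[1, 2], [0, 3], [4, 0]])
    return OtuTable(counts, ["O1", "O2", "O3"], ["s1", "s2"])


def reduced_config(seed: int, **overrides) -> SimulationConfig:
    """Desk-scale study: 800-OTU universe, 54 gut + 45 water samples."""
    params = dict(
        n_otus=800,
        dph_schedule=(12, 20, 27, 42, 56, 98),
        replicates=1,
        depth=500,
        seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


def tiny_config(seed: int, **overrides) -> SimulationConfig:
    """Very small study for structural/conservation checks."""
    params = dict(
        n_otus=40,
        dph_schedule=(12, 42, 98),
        replicates=1,
        depth=200,
        seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def reduced_study():
    """One reduced simulated study shared across read-only tests."""
    return simulate_study(reduced_config(5))


def random_metadata(sample_ids, rng) -> pd.DataFrame:
    rows = []
    for s in sample_ids:
        dph = int(rng.choice([12, 20, 27, 42, 56, 70, 98]))
        stage = {12: "S1", 20: "S1", 27: "S2", 42: "S2", 56: "S3", 70: "S3", 98: "S3"}[dph]
        hatch, rear = rng.choice(list("ABC")), rng.choice(list("ABC"))
        rows.append(
            dict(sample_id=s, habitat="gut", tank=rear, cage="1", hatch_env=hatch,
                 rear_env=rear, dph=dph, stage=stage, transition=hatch != rear,
                 food="live" if dph < 20 else "dry")
        )
    return pd.DataFrame(rows)
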