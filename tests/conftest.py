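import numpy as np
import pandas as pd
import pytest

from camap.constraints import ConstraintSet, CrossConstraint
from camap.network import CountTable, Dataset, Network, ParameterSet
from camap.prior import PriorSpec

# Brain-tumor example: coma (C) caused by brain tumour (BT) and increased
# serum calcium (IS).  Parent configurations of C are (BT, IS) in mixed
# radix: j=0 -> (0,0), j=1 -> (0,1), j=2 -> (1,0), j=3 -> (1,1).


@pytest.fixture
def brain_net() -> Network:
    return Network(
        nodes=["BT", "IS", "C"],
        parents={"BT": [], "IS": [], "C": ["BT", "IS"]},
        cardinalities={"BT": 2, "IS": 2, "C": 2},
    )


@pytest.fixture
def bt_counts() -> CountTable:
    # 20 patients; columns are C=0, C=1
    return CountTable(
        {
            "C": np.array([[0, 3], [1, 0], [3, 4], [9, 0]]),
            "BT": np.array([[4, 16]]),
            "IS": np.array([[10, 10]]),
        }
    )


@pytest.fixture
def bt_records() -> pd.DataFrame:
    rows = []
    combos = {(0, 0, 1): 3, (0, 1, 0): 1, (1, 0, 0): 3, (1, 0, 1): 4, (1, 1, 0): 9}
    for (bt, is_, c), n in combos.items():
        rows.extend([{"BT": bt, "IS": is_, "C": c}] * n)
    return pd.DataFrame(rows)


@pytest.fixture
def bt_dataset(bt_records) -> Dataset:
    return Dataset(bt_records)


@pytest.fixture
def bt_prior(brain_net) -> PriorSpec:
    # elicited prior shape printed at two decimals
    tab = np.array([[0.99, 0.01], [0.56, 0.44], [0.60, 0.40], [0.05, 0.95]])
    return PriorSpec(
        ParameterSet(
            {
                "C": tab,
                "BT": np.array([[0.5, 0.5]]),
                "IS": np.array([[0.5, 0.5]]),
            }
        ),
        sample_count=0,
        diversity_tau=0.0,
    )


@pytest.fixture
def bt_constraints() -> ConstraintSet:
    # five monotonic-influence statements on P(C=1 | BT, IS)
    pairs = [(0, 1), (0, 2), (0, 3), (1, 3), (2, 3)]
    return ConstraintSet.from_list(
        [CrossConstraint("C", lesser_j=a, greater_j=b, k=1) for a, b in pairs]
    )


@pytest.fixture
def two_node_net() -> Network:
    """Binary chain A -> B with hand-set CPTs for exact-KL oracles."""
    params = ParameterSet(
        {
            "A": np.array([[0.3, 0.7]]),
            "B": np.array([[0.9, 0.1], [0.2, 0.8]]),
        }
    )
    return Network(
        nodes=["A", "B"],
        parents={"A": [], "B": ["A"]},
        cardinalities={"A": 2, "B": 2},
        true_params=params,
    )
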