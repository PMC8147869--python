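import pytest

from promsets.activity_data import CompoundGroup, PromiscuityDataset
from promsets.promiscuity_grouping import build_activity_matrix
from promsets.synthetic_data import generate_world, tiny_config


@pytest.fixture(scope="session")
def tiny_world():
    return generate_world(tiny_config(seed=0))


@pytest.fixture(scope="session")
def tiny_matrix(tiny_world):
    return build_activity_matrix(tiny_world.records)


@pytest.fixture()
def small_dataset():
    """Hand-built two-group dataset with SMILES for every member."""
    groups = [
        CompoundGroup(
            group_id=0,
            mt_compound="M0",
            target_set=("T0", "T1", "T2"),
            st_members={"T0": "S0", "T1": "S1"},
            n_tested_per_member={"M0": 3, "S0": 5, "S1": 4},
        ),
        CompoundGroup(
            group_id=1,
            mt_compound="M1",
            target_set=("T1", "T2", "T3"),
            st_members={"T1": "S2", "T2": "S3", "T3": "S4"},
            n_tested_per_member={"M1": 4, "S2": 6, "S3": 5, "S4": 4},
        ),
    ]
    smiles = {
        "M0": "Cc1ccccc1",
        "S0": "CCc1ccccc1",
        "S1": "CCCc1ccccc1",
        "M1": "Cc1ccncc1",
        "S2": "CCc1ccncc1",
        "S3": "CCCc1ccncc1",
        "S4": "OCc1ccncc1",
    }
    return PromiscuityDataset(
        name="small",
        assay_set="mixed",
        pd_threshold=3,
        groups=groups,
        removal_marks={"M0": {"random_removal_set"}},
        smiles=smiles,
    )
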