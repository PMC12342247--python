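import numpy as np
import pandas as pd
import pytest

from scnvuln.data import Atlas, default_atlas, region_table_from_frame


@pytest.fixture
def tiny_atlas():
    return Atlas(
        pd.DataFrame(
            {
                "region_id": ["a_left", "a_right", "b_left", "b_right"],
                "name": ["A (l)", "A (r)", "B (l)", "B (r)"],
                "hemisphere": ["left", "right", "left", "right"],
            }
        )
    )


@pytest.fixture
def tiny_volume(tiny_atlas):
    frame = pd.DataFrame(
        [[2.0, 3.0, 5.0, 10.0], [1.0, 1.0, 1.0, 1.0], [4.0, 4.0, 8.0, 4.0]],
        index=pd.Index(["s1", "s2", "s3"], name="subject_id"),
        columns=tiny_atlas.region_ids,
    )
    return region_table_from_frame(frame, tiny_atlas, "volume")


@pytest.fixture
def tiny_covariates():
    return pd.DataFrame(
        {
            "subject_id": ["s1", "s2", "s3"],
            "genotype": ["APOE2", "APOE3", "APOE4"],
            "sex": ["F", "F", "M"],
            "age_months": [14.0, 15.0, 16.0],
            "diet": ["CTRL", "CTRL", "HFD"],
            "immunity": ["HN", "mNos2", "HN"],
        }
    )


@pytest.fixture(scope="session")
def atlas40():
    return default_atlas(40)
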