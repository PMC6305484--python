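import numpy as np
import pandas as pd
import pytest

from spoilcom.community_data import (
    REPLICATE_LEVEL,
    STATION_LEVEL,
    CommunityMatrix,
    StationTable,
)


def make_matrix(counts, units=None, species=None, level=STATION_LEVEL) -> CommunityMatrix:
    counts = np.asarray(counts)
    units = units or [f"u{i}" for i in range(counts.shape[0])]
    species = species or [f"sp{j}" for j in range(counts.shape[1])]
    return CommunityMatrix(pd.DataFrame(counts, index=units, columns=species), level=level)


def make_stations(substrates, covers, ids=None) -> StationTable:
    ids = ids or [f"u{i}" for i in range(len(substrates))]
    return StationTable(
        pd.DataFrame({"substrate": substrates, "cover": covers},
                     index=pd.Index(ids, name="station_id"))
    )


@pytest.fixture
def toy_matrix() -> CommunityMatrix:
    """Six stations, four species, mixed abundances."""
    return make_matrix(
        [[5, 0, 1, 0],
         [3, 0, 2, 0],
         [4, 1, 0, 0],
         [0, 6, 0, 2],
         [0, 4, 1, 3],
         [1, 5, 0, 4]],
    )


@pytest.fixture
def toy_groups(toy_matrix) -> pd.Series:
    return pd.Series(["A", "A", "A", "B", "B", "B"], index=toy_matrix.unit_ids)
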