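"""Species-by-station abundance tables: IO, replicate pooling and filtering.

The central object is :class:`CommunityMatrix`, an integer abundance table
with sampling units (replicate soil cores or stations) as rows and species
as columns.  Field protocols in this kind of survey take several soil cores
per station and pool them before any community statistic is computed, so
the matrix carries a ``level`` flag distinguishing replicate-level from
station-level data.

Filtering follows two audit-trailed rules used before segregation analysis:
species whose total catch is too small to classify (fewer than 10
individuals over the whole survey by default) are dropped, and stations that
are nearly empty (fewer than 2 individuals by default) are removed before
ordination, since a station represented by a single animal is pure noise in
a dissimilarity matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SUBSTRATES = ("ST", "PE")
COVERS = ("B", "M", "S", "T")

REPLICATE_LEVEL = "replicate"
STATION_LEVEL = "station"


class CommunityDataError(ValueError):
    """Raised for malformed community matrices or metadata tables."""


@dataclass
class CommunityMatrix:
    """Units x species integer abundance table.

    Parameters
    ----------
    data:
        DataFrame with unit ids as index and species ids as columns; cells
        are non-negative integers.
    level:
        Either ``"replicate"`` or ``"station"``.
    """

    data: pd.DataFrame
    level: str = STATION_LEVEL

    def __post_init__(self) -> None:
        if self.level not in (REPLICATE_LEVEL, STATION_LEVEL):
            raise CommunityDataError(f"unknown level {self.level!r}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise CommunityDataError(f"duplicate unit id: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise CommunityDataError(f"duplicate species id: {dupes}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise CommunityDataError("non-numeric cell in community matrix")
        if values.size:
            if not np.all(np.isfinite(values)):
                raise CommunityDataError("non-finite cell in community matrix")
            if np.any(values < 0):
                raise CommunityDataError("negative cell in community matrix")
            if not np.allclose(values, np.round(values)):
                raise CommunityDataError("non-integer cell in community matrix")
        self.data = self.data.astype(np.int64)

    # -- convenience views ------------------------------------------------
    @property
    def unit_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def grand_total(self) -> int:
        return int(self.data.to_numpy().sum())

    def species_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def unit_totals(self) -> pd.Series:
        return self.data.sum(axis=1)


@dataclass
class StationTable:
    """Per-station grouping factors: substrate, vegetation cover, site."""

    data: pd.DataFrame  # index station_id; columns substrate, cover, [site]

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise CommunityDataError("duplicate station_id in station table")
        for col, allowed in (("substrate", SUBSTRATES), ("cover", COVERS)):
            if col not in self.data.columns:
                raise CommunityDataError(f"station table missing column {col!r}")
            bad = set(self.data[col]) - set(allowed)
            if bad:
                raise CommunityDataError(f"invalid {col} codes: {sorted(bad)}")

    @property
    def station_ids(self) -> list[str]:
        return list(self.data.index)

    def substrate_of(self, units: Sequence[str]) -> pd.Series:
        return self.data.loc[list(units), "substrate"]

    def cover_of(self, units: Sequence[str]) -> pd.Series:
        return self.data.loc[list(units), "cover"]


SOIL_VARIABLES = (
    "clay",
    "fine_silt",
    "coarse_silt",
    "fine_sand",
    "coarse_sand",
    "nitrogen",
    "organic_matter",
    "pH",
    "CN",
)

GRANULOMETRIC = SOIL_VARIABLES[:5]


@dataclass
class SoilTable:
    """Per-sample soil chemistry: five granulometric fractions (g/kg),
    nitrogen (gN/kg), organic matter (g/kg), water pH and C/N ratio."""

    data: pd.DataFrame  # index sample_id; columns station_id + SOIL_VARIABLES

    def __post_init__(self) -> None:
        missing = [v for v in ("station_id", *SOIL_VARIABLES) if v not in self.data.columns]
        if missing:
            raise CommunityDataError(f"soil table missing columns {missing}")
        for frac in GRANULOMETRIC:
            if (self.data[frac] < 0).any():
                raise CommunityDataError(f"negative granulometric fraction {frac}")
        ph = self.data["pH"]
        if ((ph < 0) | (ph > 14)).any():
            raise CommunityDataError("pH outside [0, 14]")


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def load_community_matrix(
    path: str | Path,
    *,
    orientation: str = "units_by_species",
    level: str = STATION_LEVEL,
    sep: str | None = None,
) -> CommunityMatrix:
    """Read a delimited abundance table.

    ``orientation`` is ``"units_by_species"`` (rows are stations/replicates)
    or ``"species_by_units"`` (the file is transposed on disk).  Empty
    species columns are retained.
    """
    path = Path(path)
    if orientation not in ("units_by_species", "species_by_units"):
        raise CommunityDataError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=sep or _sniff_sep(path), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.isna().any().any():
        raise CommunityDataError(f"ragged or missing cells in {path}")
    if orientation == "species_by_units":
        df = df.T
    return CommunityMatrix(df, level=level)


def write_community_matrix(m: CommunityMatrix, path: str | Path) -> None:
    path = Path(path)
    m.data.rename_axis("unit_id").to_csv(path, sep=_sniff_sep(path))


def load_station_table(path: str | Path, sep: str | None = None) -> StationTable:
    path = Path(path)
    df = pd.read_csv(path, sep=sep or _sniff_sep(path))
    if "station_id" not in df.columns:
        raise CommunityDataError("station table needs a station_id column")
    df = df.set_index("station_id")
    df.index = df.index.astype(str)
    return StationTable(df)


def write_station_table(t: StationTable, path: str | Path) -> None:
    path = Path(path)
    t.data.rename_axis("station_id").to_csv(path, sep=_sniff_sep(path))


def load_soil_table(path: str | Path, sep: str | None = None) -> SoilTable:
    path = Path(path)
    df = pd.read_csv(path, sep=sep or _sniff_sep(path))
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    return SoilTable(df)


def write_soil_table(t: SoilTable, path: str | Path) -> None:
    path = Path(path)
    t.data.rename_axis("sample_id").to_csv(path, sep=_sniff_sep(path))


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def pool_replicates(
    m: CommunityMatrix,
    mapping: Mapping[str, str],
    *,
    allow_incomplete: bool = False,
    expected_replicates: int | None = None,
) -> CommunityMatrix:
    """Sum replicate rows into station rows.

    ``mapping`` sends each replicate id to its station id.  Species and
    grand totals are conserved exactly.  When ``expected_replicates`` is
    given and a station has fewer, the pooling either fails or (with
    ``allow_incomplete``) proceeds with a logged warning.
    """
    if m.level != REPLICATE_LEVEL:
        raise CommunityDataError("pool_replicates expects a replicate-level matrix")
    missing = [u for u in m.unit_ids if u not in mapping]
    if missing:
        raise CommunityDataError(f"replicates with no station in mapping: {missing}")
    stations = pd.Series({u: mapping[u] for u in m.unit_ids}, name="station")
    sizes = stations.value_counts()
    if (sizes == 0).any():
        raise CommunityDataError("station with zero replicates")
    if expected_replicates is not None:
        short = sizes[sizes < expected_replicates]
        if len(short):
            if not allow_incomplete:
                raise CommunityDataError(
                    f"stations with fewer than {expected_replicates} replicates: "
                    f"{sorted(short.index)}"
                )
            logger.warning(
                "pooling incomplete stations %s with %s of %d replicates",
                sorted(short.index), short.tolist(), expected_replicates,
            )
    pooled = m.data.groupby(stations).sum()
    # keep first-appearance station order rather than groupby's sorted order
    order = list(dict.fromkeys(stations[u] for u in m.unit_ids))
    pooled = pooled.loc[order]
    pooled.index.name = m.data.index.name
    return CommunityMatrix(pooled, level=STATION_LEVEL)


def filter_rare_species(
    m: CommunityMatrix, min_total: int = 10
) -> tuple[CommunityMatrix, list[str]]:
    """Drop species with grand total strictly below ``min_total``.

    The default of 10 reflects the rule that fewer than 10 individuals over
    the whole survey is too small a sample for habitat-segregation analysis.
    Returns the filtered matrix and the removed species, preserving column
    order of survivors.
    """
    if min_total < 0:
        raise CommunityDataError("min_total must be >= 0")
    totals = m.species_totals()
    removed = [s for s in m.species_ids if totals[s] < min_total]
    if removed:
        logger.info("removed %d species with total < %d: %s", len(removed), min_total, removed)
    kept = [s for s in m.species_ids if s not in set(removed)]
    return CommunityMatrix(m.data[kept], level=m.level), removed


def filter_sparse_stations(
    m: CommunityMatrix, min_station_total: int = 2
) -> tuple[CommunityMatrix, list[str]]:
    """Drop stations whose total abundance is below ``min_station_total``.

    Generalizes the removal of near-empty stations (a station holding a
    single animal dominates an abundance ordination as an outlier) into a
    reproducible rule with an audit trail.
    """
    if m.level != STATION_LEVEL:
        raise CommunityDataError("filter_sparse_stations expects a station-level matrix")
    totals = m.unit_totals()
    removed = [u for u in m.unit_ids if totals[u] < min_station_total]
    if removed:
        logger.warning(
            "removed %d stations with total < %d: %s", len(removed), min_station_total, removed
        )
    kept = [u for u in m.unit_ids if u not in set(removed)]
    if not kept:
        logger.warning("all stations removed by sparsity filter")
    return CommunityMatrix(m.data.loc[kept], level=m.level), removed


def to_presence_absence(m: CommunityMatrix) -> CommunityMatrix:
    """Map counts to 0/1 occurrence. Idempotent."""
    return CommunityMatrix((m.data > 0).astype(np.int64), level=m.level)
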