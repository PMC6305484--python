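"""End-to-end analysis: load or simulate, filter, ordinate, test, classify.

``run_full_analysis`` chains every stage of the community analysis in the
order a field survey of this design calls for:

1. load a replicate-level matrix (or simulate one) and pool the soil-core
   replicates per station;
2. drop species too rare to classify and near-empty stations;
3. NMDS on Bray-Curtis distances; PERMANOVA (on Sorensen distances) of
   substrate overall, of substrate within each vegetation-cover stage, and
   of cover within each substrate;
4. IndVal + binomial classification of every species' substrate and cover
   preference;
5. pooled diversity profiles per substrate and per cover;
6. Mann-Whitney comparisons of the soil variables, when a soil table is
   present.

Everything is a pure function of (inputs, config, seed); all tables are
written as TSV plus a JSON metadata record.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import community_data as cd
from . import community_tests as ct
from . import diversity as dv
from . import indicator as ind
from . import ordination as ordn
from . import synthetic as syn

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """All knobs of the pipeline, serializable to YAML/JSON."""

    # input: file paths ...
    community_path: str | None = None
    community_level: str = cd.REPLICATE_LEVEL
    station_path: str | None = None
    soil_path: str | None = None
    replicate_mapping_path: str | None = None  # TSV replicate_id -> station_id
    # ... or a simulation block
    simulate: bool = False
    pool_name: str = "default"  # default | strong | null
    # filters
    min_species_total: int = 10
    min_station_total: int = 2
    # NMDS
    nmds_k: int = 2
    nmds_starts: int = 100
    stress_threshold: float = 0.3
    # PERMANOVA
    permanova_distance: str = "sorensen"  # sorensen | bray_curtis
    permanova_permutations: int = 200
    # IndVal
    indval_permutations: int = 999
    alpha: float = 0.05
    # diversity
    q_grid: list[float] = field(default_factory=lambda: list(dv.DEFAULT_Q_GRID))
    # randomness
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "AnalysisConfig":
        text = Path(path).read_text()
        d = yaml.safe_load(text)
        return cls.from_dict(d or {})

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass
class ReportBundle:
    config: AnalysisConfig
    matrix: cd.CommunityMatrix  # filtered, station-level
    stations: cd.StationTable
    removed_species: list[str]
    removed_stations: list[str]
    nmds: ordn.NMDSResult
    permanova_table: pd.DataFrame
    species_table: pd.DataFrame
    diversity_table: pd.DataFrame
    profile_comparisons: pd.DataFrame
    soil_table: pd.DataFrame | None
    metadata: dict[str, Any]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cd.write_community_matrix(self.matrix, out / "community_filtered.tsv")
        cd.write_station_table(self.stations, out / "stations.tsv")
        coords = self.nmds.coordinates.copy()
        coords.to_csv(out / "nmds_coordinates.tsv", sep="\t")
        self.permanova_table.to_csv(out / "permanova.tsv", sep="\t", index=False)
        self.species_table.to_csv(out / "species_classification.tsv", sep="\t")
        self.diversity_table.to_csv(out / "diversity_profiles.tsv", sep="\t", index=False)
        self.profile_comparisons.to_csv(out / "profile_comparisons.tsv", sep="\t", index=False)
        if self.soil_table is not None:
            self.soil_table.to_csv(out / "soil_comparisons.tsv", sep="\t", index=False)
        (out / "metadata.json").write_text(json.dumps(self.metadata, indent=2, sort_keys=True))


def fixture_config() -> AnalysisConfig:
    """The shipped demonstration run: the simulated survey with a spoil-tip
    contrast that fades under tree cover and a richer native-soil fauna.
    Fixed seed; 25 NMDS starts keep the demo quick while the structure is
    strong enough that far fewer starts already find the same solution."""
    return AnalysisConfig(simulate=True, pool_name="fixture", seed=42, nmds_starts=25)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _load_inputs(config: AnalysisConfig):
    if config.simulate:
        design = syn.generate_design()
        pools = {
            "default": syn.default_pool,
            "strong": syn.strong_effect_pool,
            "null": syn.null_pool,
            "fixture": syn.fixture_pool,
        }
        if config.pool_name not in pools:
            raise ValueError(f"unknown pool {config.pool_name!r}")
        pool = pools[config.pool_name]()
        m, truth = syn.simulate_community(pool, design, seed=config.seed)
        soil = syn.simulate_soil_table(design, seed=config.seed + 1)
        mapping = syn.replicate_mapping(design)
        return m, design.stations, soil, mapping, truth
    if not config.community_path or not config.station_path:
        raise ValueError("config needs either simulate=true or community/station paths")
    m = cd.load_community_matrix(config.community_path, level=config.community_level)
    stations = cd.load_station_table(config.station_path)
    soil = cd.load_soil_table(config.soil_path) if config.soil_path else None
    mapping = None
    if config.replicate_mapping_path:
        mdf = pd.read_csv(config.replicate_mapping_path, sep="\t")
        mapping = dict(zip(mdf.iloc[:, 0].astype(str), mdf.iloc[:, 1].astype(str)))
    return m, stations, soil, mapping, None


def _distance(m: cd.CommunityMatrix, which: str) -> ordn.DistanceMatrix:
    if which == "sorensen":
        return ordn.sorensen(m)
    if which == "bray_curtis":
        return ordn.bray_curtis(m)
    raise ValueError(f"unknown distance {which!r}")


def _subset_permanovas(
    m: cd.CommunityMatrix,
    stations: cd.StationTable,
    config: AnalysisConfig,
    rng_seeds: dict[str, int],
) -> pd.DataFrame:
    """Overall substrate test, substrate tests per cover stage, and cover
    tests per substrate; subsets re-run PERMANOVA on the sliced matrix
    without re-applying species filters."""
    sub = stations.substrate_of(m.unit_ids)
    cov = stations.cover_of(m.unit_ids)
    rows = []

    def run(name: str, units: list[str], labels: pd.Series) -> None:
        counts = labels.loc[units].value_counts()
        if len(counts) < 2 or (counts < 2).any():
            logger.warning("PERMANOVA %s skipped: group sizes %s", name, counts.to_dict())
            rows.append({"comparison": name, "skipped": True})
            return
        msub = cd.CommunityMatrix(m.data.loc[units], level=m.level)
        msub, dropped = cd.filter_sparse_stations(msub, 1)  # guard all-zero rows only
        d = _distance(msub, config.permanova_distance)
        res = ct.permanova(
            d, labels, n_perm=config.permanova_permutations, seed=rng_seeds[name]
        )
        rows.append({"comparison": name, "skipped": False, **res.to_dict()})

    run("substrate_overall", m.unit_ids, sub)
    for c in cd.COVERS:
        units = [u for u in m.unit_ids if cov[u] == c]
        run(f"substrate_within_{c}", units, sub)
    for s in cd.SUBSTRATES:
        units = [u for u in m.unit_ids if sub[u] == s]
        run(f"cover_within_{s}", units, cov)
    return pd.DataFrame(rows)


def run_full_analysis(config: AnalysisConfig, out_dir: str | Path | None = None) -> ReportBundle:
    meta: dict[str, Any] = {"config": config.to_dict(), "stages": []}

    def stage(name: str):
        meta["stages"].append(name)
        logger.info("stage %s", name)

    try:
        stage("load")
        m, stations, soil, mapping, truth = _load_inputs(config)
    except Exception as e:  # noqa: BLE001
        raise StageError("load", e) from e

    try:
        stage("pool")
        if m.level == cd.REPLICATE_LEVEL:
            if mapping is None:
                raise ValueError("replicate-level input requires a replicate mapping")
            m = cd.pool_replicates(m, mapping)
    except Exception as e:  # noqa: BLE001
        raise StageError("pool", e) from e

    try:
        stage("filter")
        m, removed_species = cd.filter_rare_species(m, config.min_species_total)
        m, removed_stations = cd.filter_sparse_stations(m, config.min_station_total)
        stations_used = cd.StationTable(stations.data.loc[m.unit_ids])
    except Exception as e:  # noqa: BLE001
        raise StageError("filter", e) from e

    seed = config.seed
    seeds = {"nmds": seed + 11, "indval": seed + 13}
    names = ["substrate_overall"] + [f"substrate_within_{c}" for c in cd.COVERS] + [
        f"cover_within_{s}" for s in cd.SUBSTRATES
    ]
    perm_seeds = {n: seed + 100 + i for i, n in enumerate(names)}

    try:
        stage("ordination")
        d_bc = ordn.bray_curtis(m)
        nmds_res = ordn.nmds(
            d_bc, k=config.nmds_k, n_starts=config.nmds_starts, seed=seeds["nmds"]
        )
        if nmds_res.stress >= config.stress_threshold:
            logger.warning(
                "NMDS stress %.3f above threshold %.3f",
                nmds_res.stress, config.stress_threshold,
            )
    except Exception as e:  # noqa: BLE001
        raise StageError("ordination", e) from e

    try:
        stage("permanova")
        perm_table = _subset_permanovas(m, stations_used, config, perm_seeds)
    except Exception as e:  # noqa: BLE001
        raise StageError("permanova", e) from e

    try:
        stage("classification")
        classifications = ind.classify_species(
            m, stations_used,
            n_perm=config.indval_permutations, alpha=config.alpha, seed=seeds["indval"],
        )
        species_table = ind.build_species_table(classifications)
        if truth is not None:
            species_table = species_table.join(truth, how="left")
    except Exception as e:  # noqa: BLE001
        raise StageError("classification", e) from e

    try:
        stage("diversity")
        q = np.asarray(config.q_grid)
        prof_sub = dv.group_profiles(m, stations_used.substrate_of(m.unit_ids), q)
        prof_cov = dv.group_profiles(m, stations_used.cover_of(m.unit_ids), q)
        frames = [p.to_frame(g) for g, p in {**prof_sub, **prof_cov}.items()]
        diversity_table = pd.concat(frames, ignore_index=True)
        comp_rows = []
        both = {**prof_sub, **prof_cov}
        keys = list(both)
        for i, ga in enumerate(keys):
            for gb in keys[i + 1:]:
                verdict, crossings = dv.compare_profiles(both[ga], both[gb])
                comp_rows.append(
                    {"group_a": ga, "group_b": gb, "verdict": verdict,
                     "crossings": ";".join(f"{a:g}-{b:g}" for a, b in crossings)}
                )
        profile_comparisons = pd.DataFrame(comp_rows)
    except Exception as e:  # noqa: BLE001
        raise StageError("diversity", e) from e

    soil_table = None
    if soil is not None:
        try:
            stage("soil")
            soil_table = ct.soil_comparison_table(soil, stations)
        except Exception as e:  # noqa: BLE001
            raise StageError("soil", e) from e

    meta.update(
        {
            "seed": seed,
            "n_stations": len(m.unit_ids),
            "n_species": len(m.species_ids),
            "removed_species": removed_species,
            "removed_stations": removed_stations,
            "nmds_stress": nmds_res.stress,
            "nmds_converged": nmds_res.converged,
        }
    )
    bundle = ReportBundle(
        config=config, matrix=m, stations=stations_used,
        removed_species=removed_species, removed_stations=removed_stations,
        nmds=nmds_res, permanova_table=perm_table, species_table=species_table,
        diversity_table=diversity_table, profile_comparisons=profile_comparisons,
        soil_table=soil_table, metadata=meta,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
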