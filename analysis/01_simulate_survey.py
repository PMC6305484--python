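#!/usr/bin/env python
"""Step 1 — generate the demonstration survey.

Simulates the 81-station two-substrate (spoil tip ST vs. peripheral PE),
four-cover (bare, meadow, shrub, tree) sampling design with five soil-core
replicates per station, pools replicates to station level, applies the
standard filters (species with fewer than 10 individuals overall; stations
with fewer than 2 individuals) and writes the working tables that the later
numbered scripts consume.
"""

from pathlib import Path

from spoilcom import community_data as cd
from spoilcom import synthetic as syn

SEED = 42
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    design = syn.generate_design()
    pool = syn.fixture_pool()
    replicates, truth = syn.simulate_community(pool, design, seed=SEED)
    soil = syn.simulate_soil_table(design, seed=SEED + 1)

    stations = cd.pool_replicates(replicates, syn.replicate_mapping(design))
    stations, dropped_species = cd.filter_rare_species(stations, min_total=10)
    stations, dropped_stations = cd.filter_sparse_stations(stations, min_station_total=2)

    cd.write_community_matrix(replicates, OUT / "community_replicates.tsv")
    cd.write_community_matrix(stations, OUT / "community_stations.tsv")
    cd.write_station_table(design.stations, OUT / "stations.tsv")
    cd.write_soil_table(soil, OUT / "soil.tsv")
    truth.to_csv(OUT / "truth.tsv", sep="\t")

    n = int(stations.data.to_numpy().sum())
    print(f"stations: {len(stations.unit_ids)}  species kept: {len(stations.species_ids)}")
    print(f"individuals after filtering: {n}")
    print(f"species dropped (<10 individuals): {len(dropped_species)}")
    print(f"stations dropped (<2 individuals): {len(dropped_stations)}")


if __name__ == "__main__":
    main()
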