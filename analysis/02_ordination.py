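#!/usr/bin/env python
"""Step 2 — non-metric multidimensional scaling of the station assemblages.

Ordinates the filtered station-by-species matrix on the Bray-Curtis
distance with a 100-start two-dimensional NMDS, then writes the station
coordinates and the substrate/cover group centroids.
"""

from pathlib import Path

from spoilcom import community_data as cd
from spoilcom.ordination import bray_curtis, group_centroids, nmds

SEED = 42
RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA = RESULTS / "data"


def main() -> None:
    m = cd.load_community_matrix(DATA / "community_stations.tsv")
    stations = cd.load_station_table(DATA / "stations.tsv")

    res = nmds(bray_curtis(m), k=2, n_starts=100, seed=SEED + 11)
    res.coordinates.to_csv(RESULTS / "nmds_coordinates.tsv", sep="\t")
    for factor in ("substrate", "cover"):
        cent = group_centroids(res.coordinates, stations.data[factor])
        cent.to_csv(RESULTS / f"nmds_centroids_{factor}.tsv", sep="\t")

    print(f"NMDS stress (Kruskal stress-1): {res.stress:.4f}")
    print(f"converged: {res.converged}  best of {res.n_starts} starts")


if __name__ == "__main__":
    main()
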