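#!/usr/bin/env python
"""Step 4 — indicator species analysis and ecological classification.

Computes the Dufrene-Legendre indicator value (IndVal) of every species for
the substrate groups with a 999-permutation significance test, then assigns
each species a substrate qualification (pioneer / stenoecious / colonizing /
opportunist / euryecious) and a vegetation-cover qualification (exclusive /
elective / preferring / indifferent) from the IndVal and exact binomial
preference tests.
"""

from pathlib import Path

from spoilcom import community_data as cd
from spoilcom.indicator import build_species_table, classify_species

SEED = 42
RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA = RESULTS / "data"


def main() -> None:
    m = cd.load_community_matrix(DATA / "community_stations.tsv")
    stations = cd.load_station_table(DATA / "stations.tsv")

    classifications = classify_species(m, stations, n_perm=999, seed=SEED + 13)
    table = build_species_table(classifications)
    table.to_csv(RESULTS / "species_classification.tsv", sep="\t")

    print(table.to_string())
    print()
    print("substrate qualifications:",
          table["substrate_qualif"].value_counts().to_dict())
    print("cover qualifications:   ",
          table["cover_qualif"].value_counts().to_dict())


if __name__ == "__main__":
    main()
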