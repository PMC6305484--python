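#!/usr/bin/env python
"""Step 6 — soil physico-chemistry comparisons.

Compares each measured soil variable (granulometric fractions, nitrogen,
organic matter, pH, C/N) between the two substrates with Mann-Whitney U
tests, overall and within each vegetation cover.
"""

from pathlib import Path

from spoilcom import community_data as cd
from spoilcom.community_tests import soil_comparison_table

RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA = RESULTS / "data"


def main() -> None:
    soil = cd.load_soil_table(DATA / "soil.tsv")
    stations = cd.load_station_table(DATA / "stations.tsv")

    table = soil_comparison_table(soil, stations)
    table.to_csv(RESULTS / "soil_comparisons.tsv", sep="\t", index=False)

    overall = table[table["comparison"] == "overall"]
    print(overall.to_string(index=False))


if __name__ == "__main__":
    main()
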