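#!/usr/bin/env python
"""Step 3 — permutational MANOVA of assemblage composition.

Tests the substrate effect (spoil tip vs. peripheral) overall and within
each vegetation cover, and the cover effect within each substrate, on the
Sorensen distance with 200 free label permutations per test.
"""

from pathlib import Path

import pandas as pd

from spoilcom import community_data as cd
from spoilcom.community_tests import permanova, significance_stars
from spoilcom.ordination import sorensen

SEED = 42
N_PERM = 200
RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA = RESULTS / "data"


def main() -> None:
    m = cd.load_community_matrix(DATA / "community_stations.tsv")
    stations = cd.load_station_table(DATA / "stations.tsv")
    dist = sorensen(m)

    comparisons = [("substrate_overall", None, None, "substrate")]
    for cover in sorted(stations.data["cover"].unique()):
        comparisons.append((f"substrate_within_{cover}", "cover", cover, "substrate"))
    for sub in sorted(stations.data["substrate"].unique()):
        comparisons.append((f"cover_within_{sub}", "substrate", sub, "cover"))

    rows = []
    for i, (name, strat_col, strat_val, factor) in enumerate(comparisons):
        labels = stations.data[factor]
        if strat_col is not None:
            units = stations.data.index[stations.data[strat_col] == strat_val]
            sub_dist, labels = dist.subset(list(units)), labels.loc[units]
        else:
            sub_dist = dist
        if labels.value_counts().min() < 2 or labels.nunique() < 2:
            rows.append({"comparison": name, "skipped": True})
            continue
        res = permanova(sub_dist, labels, n_perm=N_PERM, seed=SEED + 100 + i)
        rows.append({"comparison": name, "skipped": False, **res.to_dict(),
                     "stars": significance_stars(res.p_value)})
        print(f"{name:24s} F = {res.pseudo_f:7.2f}  R2 = {res.r_squared:.3f}  "
              f"p = {res.p_value:.4f} {significance_stars(res.p_value)}")

    pd.DataFrame(rows).to_csv(RESULTS / "permanova.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
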