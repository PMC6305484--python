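"""Permutation MANOVA on distance matrices and rank tests for soil variables.

PERMANOVA partitions the total sum of squared inter-point distances into a
between-group and a within-group component without ever computing
coordinates:

    SS_total = (1/n) * sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
    SS_between = SS_total - SS_within
    pseudo-F = (SS_between / (a - 1)) / (SS_within / (n - a))

The p-value comes from free permutation of the group labels, with the
add-one convention p = (1 + #{F_perm >= F_obs}) / (n_perm + 1).  R^2 =
SS_between / SS_total measures the fraction of community variation the
grouping explains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .community_data import SOIL_VARIABLES, SoilTable, StationTable
from .ordination import DistanceMatrix


class StatsTestError(ValueError):
    pass


@dataclass
class PermanovaResult:
    ss_total: float
    ss_between: float
    ss_within: float
    df_between: int
    df_within: int
    pseudo_f: float  # +inf when SS_within == 0
    r_squared: float
    p_value: float
    n_perm: int

    def to_dict(self) -> dict:
        return {
            "SS_total": self.ss_total, "SS_between": self.ss_between,
            "SS_within": self.ss_within, "df_between": self.df_between,
            "df_within": self.df_within, "pseudo_F": self.pseudo_f,
            "R2": self.r_squared, "p": self.p_value, "n_perm": self.n_perm,
        }


@dataclass
class RankTestResult:
    u_statistic: float
    p_value: float
    method: str  # "exact" | "asymptotic"


def _ss_within(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    ssw = 0.0
    for g in range(n_groups):
        mask = codes == g
        ng = int(mask.sum())
        block = d2[np.ix_(mask, mask)]
        ssw += block.sum() / (2.0 * ng)  # full matrix counts each pair twice
    return ssw


def permanova(
    d: DistanceMatrix,
    groups: pd.Series | dict,
    n_perm: int = 200,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA of ``groups`` on distance matrix ``d``.

    ``groups`` maps every unit id of ``d`` to a group label; at least two
    groups of at least two units each are required.  Deterministic for a
    given seed.
    """
    if n_perm < 1:
        raise StatsTestError("n_perm must be >= 1")
    groups = pd.Series(groups)
    missing = [u for u in d.unit_ids if u not in groups.index]
    if missing:
        raise StatsTestError(f"units without group label: {missing}")
    labels = groups.loc[d.unit_ids]
    codes, uniques = pd.factorize(labels)
    a = len(uniques)
    n = d.n
    sizes = np.bincount(codes, minlength=a)
    if a < 2:
        raise StatsTestError("need at least two groups")
    if (sizes < 2).any():
        small = [u for u, s in zip(uniques, sizes) if s < 2]
        raise StatsTestError(f"groups with fewer than two units: {small}")
    d2 = d.values ** 2
    ss_total = d2.sum() / (2.0 * n)
    ssw = _ss_within(d2, codes, a)
    ssa = ss_total - ssw
    df_b, df_w = a - 1, n - a

    def f_stat(ssa_: float, ssw_: float) -> float:
        if ssw_ <= 0:
            return np.inf
        return (ssa_ / df_b) / (ssw_ / df_w)

    f_obs = f_stat(ssa, ssw)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ssw_p = _ss_within(d2, codes[perm], a)
        if f_stat(ss_total - ssw_p, ssw_p) >= f_obs:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return PermanovaResult(
        ss_total=float(ss_total), ss_between=float(ssa), ss_within=float(ssw),
        df_between=df_b, df_within=df_w, pseudo_f=float(f_obs),
        r_squared=float(ssa / ss_total) if ss_total > 0 else 0.0,
        p_value=p, n_perm=n_perm,
    )


def mann_whitney_u(
    x, y, *, method: str = "auto"
) -> RankTestResult:
    """Two-sided Mann-Whitney U test; U is reported for the first sample.

    Exact enumeration when the pooled sample is small (n1 + n2 <= 20) and
    tie-free, otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StatsTestError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if np.unique(pooled).size == 1:
        import warnings

        warnings.warn("all values identical in both samples; p = 1")
        return RankTestResult(
            u_statistic=float(x.size * y.size / 2), p_value=1.0, method="degenerate"
        )
    if method == "auto":
        method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return RankTestResult(
        u_statistic=float(res.statistic), p_value=float(min(1.0, res.pvalue)),
        method=method,
    )


def soil_comparison_table(
    soil: SoilTable,
    stations: StationTable,
    *,
    by_cover: bool = True,
) -> pd.DataFrame:
    """Per-variable ST-vs-PE Mann-Whitney comparisons.

    One row per soil variable per comparison (overall plus, optionally, one
    per vegetation-cover stage), with group means +/- sd, the U statistic,
    the two-sided p and a significance tier.
    """
    import logging

    logger = logging.getLogger(__name__)
    df = soil.data.copy()
    meta = stations.data
    known = df["station_id"].isin(meta.index)
    if (~known).any():
        logger.warning("soil samples with unknown station skipped: %s",
                       df.index[~known].tolist())
        df = df[known]
    df = df.join(meta[["substrate", "cover"]], on="station_id")
    comparisons = [("overall", df)]
    if by_cover:
        for cov, sub in df.groupby("cover"):
            comparisons.append((f"cover_{cov}", sub))
    rows = []
    for name, sub in comparisons:
        st = sub[sub["substrate"] == "ST"]
        pe = sub[sub["substrate"] == "PE"]
        for var in SOIL_VARIABLES:
            if st.empty or pe.empty:
                logger.warning("comparison %s lacks one group; skipped", name)
                continue
            res = mann_whitney_u(pe[var], st[var])
            rows.append(
                {
                    "comparison": name, "variable": var,
                    "PE_n": len(pe), "PE_mean": pe[var].mean(), "PE_sd": pe[var].std(),
                    "ST_n": len(st), "ST_mean": st[var].mean(), "ST_sd": st[var].std(),
                    "U": res.u_statistic, "p": res.p_value,
                    "signif": significance_stars(res.p_value),
                }
            )
    return pd.DataFrame(rows)


def significance_stars(p: float) -> str:
    """Conventional tiers: *** p<0.001, ** p<0.01, * p<0.05, NS otherwise."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"
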