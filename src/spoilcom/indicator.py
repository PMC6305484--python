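"""IndVal indicator-species analysis and habitat-preference classification.

For species *i* and site group *j* the indicator value combines
specificity and fidelity:

    A_ij = (individuals of i in the sites of j) / (individuals of i in all sites)
    B_ij = (sites of j where i occurs) / (sites of j)
    IndVal_ij = A_ij * B_ij * 100

IndVal reaches its maximum of 100 when the species occurs in every site of
group j and nowhere else.  Note the specificity term uses the species'
total abundance over all sites as denominator (so the A_ij sum to 1 across
groups); the classical variant based on group mean abundances is available
behind ``a_denominator="group_mean"``.

Significance of a species' peak IndVal is assessed by permuting station
group labels.  Species whose IndVal is not significant may still show a
*simple preference*: an exact binomial test asks whether the share of the
species' individuals found in its best group exceeds that group's share of
stations.

Two decision trees turn these tests into habitat-preference categories.

Substrate (spoil tip ST vs. peripheral environment PE):
  * significant IndVal peaking on ST  -> ``pioneer``
  * significant IndVal peaking on PE  -> ``stenoecious``
  * otherwise, binomial preference ST -> ``colonizing``
  * otherwise, binomial preference PE -> ``opportunist``
  * no signal at all                  -> ``euryecious``

Vegetation cover (bare B, meadow M, shrub S, tree T):
  * significant IndVal                          -> ``exclusive`` of its peak cover
  * 2 covers occupied and binomial preference   -> ``elective``
  * >2 covers occupied and binomial preference  -> ``preferring``
  * otherwise                                   -> ``indifferent``
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import logging

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .community_data import CommunityMatrix
from .community_tests import significance_stars

logger = logging.getLogger(__name__)

SUBSTRATE_CATEGORIES = ("pioneer", "stenoecious", "colonizing", "opportunist", "euryecious")
COVER_CATEGORIES = ("exclusive", "elective", "preferring", "indifferent")


class IndicatorError(ValueError):
    pass


@dataclass
class IndValEntry:
    species_id: str
    group_id: str
    a: float
    b: float
    indval: float
    assigned: bool
    p_perm: float | None = None


@dataclass
class BinomialPreference:
    favored_group: str
    successes: int
    n: int
    p0: float
    p_value: float


@dataclass
class SubstratePreference:
    category: str  # one of SUBSTRATE_CATEGORIES
    favored: str | None  # ST or PE, None for euryecious
    indval_p: float
    binomial_p: float


@dataclass
class CoverPreference:
    category: str  # one of COVER_CATEGORIES
    favored: tuple[str, ...]  # empty for indifferent
    n_covers_present: int
    indval_p: float
    binomial_p: float


# ---------------------------------------------------------------------------
# Core computation (vectorized over species)
# ---------------------------------------------------------------------------

def _group_setup(m: CommunityMatrix, groups: pd.Series | Mapping) -> tuple[np.ndarray, list]:
    groups = pd.Series(groups)
    missing = [u for u in m.unit_ids if u not in groups.index]
    if missing:
        raise IndicatorError(f"stations without group label: {missing}")
    labels = groups.loc[m.unit_ids]
    uniques = sorted(labels.unique())
    codes = np.array([uniques.index(v) for v in labels])
    sizes = np.bincount(codes, minlength=len(uniques))
    if (sizes == 0).any():
        raise IndicatorError("group with zero stations")
    return codes, uniques


def _indval_arrays(
    x: np.ndarray, codes: np.ndarray, n_groups: int,
    a_denominator: Literal["total", "group_mean"] = "total",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """A, B and IndVal as (n_groups x n_species) arrays."""
    onehot = np.zeros((n_groups, x.shape[0]))
    onehot[codes, np.arange(x.shape[0])] = 1.0
    sizes = onehot.sum(axis=1)  # stations per group
    abund = onehot @ x  # individuals of each species per group
    occ = onehot @ (x > 0)  # occupied stations per group
    with np.errstate(invalid="ignore", divide="ignore"):
        if a_denominator == "total":
            tot = x.sum(axis=0)
            a = np.where(tot > 0, abund / np.where(tot > 0, tot, 1), 0.0)
        elif a_denominator == "group_mean":
            means = abund / sizes[:, None]
            mean_sum = means.sum(axis=0)
            a = np.where(mean_sum > 0, means / np.where(mean_sum > 0, mean_sum, 1), 0.0)
        else:
            raise IndicatorError(f"unknown a_denominator {a_denominator!r}")
    b = occ / sizes[:, None]
    return a, b, a * b * 100.0


def indval(
    m: CommunityMatrix,
    groups: pd.Series | Mapping,
    *,
    a_denominator: Literal["total", "group_mean"] = "total",
) -> list[IndValEntry]:
    """IndVal of every species for every group; ``assigned`` marks each
    species' argmax group (ties go to the alphabetically first group, with
    a logged warning)."""
    codes, uniques = _group_setup(m, groups)
    x = m.counts.astype(float)
    a, b, iv = _indval_arrays(x, codes, len(uniques), a_denominator)
    best = iv.argmax(axis=0)  # first max wins; uniques is sorted
    ties = (iv == iv.max(axis=0, keepdims=True)).sum(axis=0) > 1
    present = x.sum(axis=0) > 0
    if (ties & present).any():
        tied = [s for s, t, pr in zip(m.species_ids, ties, present) if t and pr]
        logger.warning("IndVal argmax ties broken alphabetically for %s", tied)
    entries = []
    for si, sp in enumerate(m.species_ids):
        for gi, g in enumerate(uniques):
            entries.append(
                IndValEntry(
                    species_id=sp, group_id=g,
                    a=float(a[gi, si]), b=float(b[gi, si]), indval=float(iv[gi, si]),
                    assigned=(gi == best[si]),
                )
            )
    return entries


def indval_significance(
    m: CommunityMatrix,
    groups: pd.Series | Mapping,
    n_perm: int = 999,
    seed: int = 0,
    *,
    a_denominator: Literal["total", "group_mean"] = "total",
) -> pd.Series:
    """Permutation p-value per species for its maximum IndVal over groups.

    The null shuffles station group labels; p uses the add-one convention
    (1 + #{max IndVal_perm >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise IndicatorError("n_perm must be >= 1")
    codes, uniques = _group_setup(m, groups)
    x = m.counts.astype(float)
    ng = len(uniques)
    _, _, iv = _indval_arrays(x, codes, ng)
    stat_obs = iv.max(axis=0)
    rng = np.random.default_rng(seed)
    hits = np.zeros(x.shape[1])
    for _ in range(n_perm):
        perm_codes = codes[rng.permutation(codes.size)]
        _, _, iv_p = _indval_arrays(x, perm_codes, ng)
        hits += iv_p.max(axis=0) >= stat_obs
    p = (1 + hits) / (n_perm + 1)
    return pd.Series(p, index=m.species_ids, name="indval_p")


def binomial_preference(
    species_counts_by_group: Mapping[str, int],
    stations_by_group: Mapping[str, int],
) -> BinomialPreference:
    """Simple-preference test for one species.

    The favored group maximizes the ratio of observed individuals to the
    expectation under proportional allocation (the group's share of
    stations).  The exact two-sided binomial test then compares the count
    in the favored group against that station share, correcting for
    unbalanced designs.
    """
    groups = sorted(stations_by_group)
    n = int(sum(species_counts_by_group.get(g, 0) for g in groups))
    if n == 0:
        raise IndicatorError("species with zero individuals")
    total_stations = sum(stations_by_group.values())
    if len(groups) < 2:
        raise IndicatorError("need at least two groups")
    ratios = {
        g: species_counts_by_group.get(g, 0)
        / (n * stations_by_group[g] / total_stations)
        for g in groups
    }
    favored = max(groups, key=lambda g: ratios[g])  # ties -> alphabetical via sorted groups
    p0 = stations_by_group[favored] / total_stations
    successes = int(species_counts_by_group.get(favored, 0))
    p = binomtest(successes, n, p0, alternative="two-sided").pvalue
    return BinomialPreference(
        favored_group=favored, successes=successes, n=n, p0=p0, p_value=float(p)
    )


# ---------------------------------------------------------------------------
# Decision trees
# ---------------------------------------------------------------------------

def classify_substrate(
    entries: Sequence[IndValEntry],
    binom: BinomialPreference,
    indval_p: float,
    alpha: float = 0.05,
) -> SubstratePreference:
    """Five-way substrate classification for one species (see module docs)."""
    by_group = {e.group_id: e for e in entries}
    for g in ("ST", "PE"):
        if g not in by_group:
            raise IndicatorError(f"missing IndVal entry for group {g}")
    argmax = next(e.group_id for e in entries if e.assigned)
    if indval_p < alpha:
        category = "pioneer" if argmax == "ST" else "stenoecious"
        return SubstratePreference(category, argmax, indval_p, binom.p_value)
    if binom.p_value < alpha:
        category = "colonizing" if binom.favored_group == "ST" else "opportunist"
        return SubstratePreference(category, binom.favored_group, indval_p, binom.p_value)
    return SubstratePreference("euryecious", None, indval_p, binom.p_value)


def classify_cover(
    entries: Sequence[IndValEntry],
    binom: BinomialPreference,
    indval_p: float,
    n_covers_present: int,
    alpha: float = 0.05,
) -> CoverPreference:
    """Four-way vegetation-cover classification for one species."""
    if n_covers_present == 0:
        raise IndicatorError("species with zero total cannot be classified")
    argmax = next(e.group_id for e in entries if e.assigned)
    if indval_p < alpha:
        return CoverPreference("exclusive", (argmax,), n_covers_present, indval_p, binom.p_value)
    if binom.p_value < alpha:
        if n_covers_present == 2:
            return CoverPreference(
                "elective", (binom.favored_group,), n_covers_present, indval_p, binom.p_value
            )
        if n_covers_present > 2:
            return CoverPreference(
                "preferring", (binom.favored_group,), n_covers_present, indval_p, binom.p_value
            )
    return CoverPreference("indifferent", (), n_covers_present, indval_p, binom.p_value)


# ---------------------------------------------------------------------------
# End-to-end classification and the species summary table
# ---------------------------------------------------------------------------

@dataclass
class SpeciesClassification:
    species_id: str
    n_individuals: int
    substrate: SubstratePreference
    cover: CoverPreference


def classify_species(
    m: CommunityMatrix,
    stations,
    *,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> list[SpeciesClassification]:
    """Run both decision trees for every species of a station-level matrix.

    ``stations`` is a StationTable covering all units of ``m``.  Species
    with zero total are skipped with a warning (filter first).
    """
    sub_groups = stations.substrate_of(m.unit_ids)
    cov_groups = stations.cover_of(m.unit_ids)
    totals = m.species_totals()
    zero = [s for s in m.species_ids if totals[s] == 0]
    if zero:
        logger.warning("skipping zero-total species: %s", zero)
    sub_entries = indval(m, sub_groups)
    cov_entries = indval(m, cov_groups)
    sub_p = indval_significance(m, sub_groups, n_perm=n_perm, seed=seed)
    cov_p = indval_significance(m, cov_groups, n_perm=n_perm, seed=seed + 1)
    sub_by_sp: dict[str, list[IndValEntry]] = {}
    for e in sub_entries:
        sub_by_sp.setdefault(e.species_id, []).append(e)
    cov_by_sp: dict[str, list[IndValEntry]] = {}
    for e in cov_entries:
        cov_by_sp.setdefault(e.species_id, []).append(e)
    sub_sizes = sub_groups.value_counts().to_dict()
    cov_sizes = cov_groups.value_counts().to_dict()
    out = []
    for sp in m.species_ids:
        if totals[sp] == 0:
            continue
        col = m.data[sp]
        sub_counts = col.groupby(sub_groups).sum().to_dict()
        cov_counts = col.groupby(cov_groups).sum().to_dict()
        sub_binom = binomial_preference(sub_counts, sub_sizes)
        cov_binom = binomial_preference(cov_counts, cov_sizes)
        n_present = int(sum(1 for c, v in cov_counts.items() if v > 0))
        out.append(
            SpeciesClassification(
                species_id=sp,
                n_individuals=int(totals[sp]),
                substrate=classify_substrate(sub_by_sp[sp], sub_binom, sub_p[sp], alpha),
                cover=classify_cover(cov_by_sp[sp], cov_binom, cov_p[sp], n_present, alpha),
            )
        )
    return out


def build_species_table(classifications: Sequence[SpeciesClassification]) -> pd.DataFrame:
    """Species summary table: N, substrate preference with significance
    stars, cover code(s) and qualifier; rows sorted alphabetically."""
    rows = []
    for c in sorted(classifications, key=lambda c: c.species_id):
        sub_stars = (
            significance_stars(c.substrate.indval_p)
            if c.substrate.category in ("pioneer", "stenoecious") else ""
        )
        cov_stars = (
            significance_stars(c.cover.indval_p)
            if c.cover.category == "exclusive" else ""
        )
        rows.append(
            {
                "species": c.species_id,
                "N": c.n_individuals,
                "substrate_pref": c.substrate.favored or "",
                "substrate_stars": sub_stars,
                "substrate_qualif": c.substrate.category,
                "cover_code": "".join(c.cover.favored),
                "cover_stars": cov_stars,
                "cover_qualif": c.cover.category,
            }
        )
    cols = ["species", "N", "substrate_pref", "substrate_stars", "substrate_qualif",
            "cover_code", "cover_stars", "cover_qualif"]
    return pd.DataFrame(rows, columns=cols).set_index("species") if rows else (
        pd.DataFrame(columns=cols).set_index("species")
    )
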