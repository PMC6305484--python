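"""Dissimilarities and non-metric multidimensional scaling (NMDS).

Community structure is visualized with NMDS on Bray-Curtis dissimilarities,
which uses only the rank order of the dissimilarities and is therefore
robust to the wild density variation that parthenogenesis and aggregation
produce in soil-arthropod counts.  The scaling is run from many random
starting configurations; the run is accepted as converged once two starts
reach the same minimum-stress solution (equal stress up to tolerance and
matching under Procrustes superimposition).

Stress is Kruskal's stress-1,
``sqrt(sum((dhat - f(d))^2) / sum(dhat^2))``, where ``dhat`` are the
configuration distances and ``f`` is the monotone (isotonic) regression of
``dhat`` on the input dissimilarities, with primary treatment of ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import procrustes as _scipy_procrustes
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from .community_data import CommunityMatrix, to_presence_absence


class OrdinationError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix with zero diagonal."""

    unit_ids: list[str]
    values: np.ndarray  # (n, n)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.unit_ids):
            raise OrdinationError("distance matrix shape does not match unit ids")
        if not np.all(np.isfinite(v)):
            raise OrdinationError("non-finite distances")
        if not np.allclose(v, v.T):
            raise OrdinationError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise OrdinationError("distance matrix diagonal not zero")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.unit_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.unit_ids, columns=self.unit_ids)

    def subset(self, units: list[str]) -> "DistanceMatrix":
        idx = [self.unit_ids.index(u) for u in units]
        return DistanceMatrix(list(units), self.values[np.ix_(idx, idx)])


@dataclass
class NMDSResult:
    coordinates: pd.DataFrame  # units x k, column-centered
    stress: float
    n_starts: int
    converged: bool
    best_run_seed: int


@dataclass
class ProcrustesResult:
    m12_squared: float
    correlation: float  # sqrt(1 - m12_squared), the Protest statistic
    p_value: float | None = None
    n_perm: int = 0


# ---------------------------------------------------------------------------
# Dissimilarity indices
# ---------------------------------------------------------------------------

def bray_curtis(m: CommunityMatrix) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(x, y) = sum|x-y| / sum(x+y) on abundances."""
    x = m.counts.astype(float)
    row_tot = x.sum(axis=1)
    if np.any(row_tot == 0):
        empty = [u for u, t in zip(m.unit_ids, row_tot) if t == 0]
        raise OrdinationError(
            f"stations with zero total {empty}: remove them first "
            "(filter_sparse_stations)"
        )
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(m.unit_ids, d)


def sorensen(m: CommunityMatrix) -> DistanceMatrix:
    """Sorensen dissimilarity: Bray-Curtis on presence/absence."""
    return bray_curtis(to_presence_absence(m))


# ---------------------------------------------------------------------------
# Stress
# ---------------------------------------------------------------------------

def kruskal_stress(diss: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against condensed dissimilarities.

    Primary tie treatment: within blocks of tied dissimilarities the
    configuration distances are free to order themselves, implemented by
    breaking ties in the sort by the configuration distance before the
    monotone regression.
    """
    dhat = pdist(coords)
    order = np.lexsort((dhat, diss))
    iso = IsotonicRegression(increasing=True)
    fitted_sorted = iso.fit_transform(np.arange(order.size), dhat[order])
    resid = dhat[order] - fitted_sorted
    denom = float(np.sum(dhat ** 2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum(resid ** 2) / denom))


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

def _center(coords: np.ndarray) -> np.ndarray:
    return coords - coords.mean(axis=0, keepdims=True)


def _single_run(
    d: np.ndarray, k: int, rng: np.random.Generator, max_iter: int, eps: float
) -> np.ndarray:
    n = d.shape[0]
    init = rng.uniform(-1.0, 1.0, size=(n, k))
    coords, _ = smacof(
        d, n_components=k, metric=False, init=init, n_init=1,
        max_iter=max_iter, eps=eps, normalized_stress=True,
    )
    return _center(coords)


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    n_starts: int = 100,
    seed: int = 0,
    *,
    stress_tol: float = 1e-6,
    procrustes_tol: float = 1e-3,
    max_iter: int = 500,
    eps: float = 1e-12,
    stop_on_convergence: bool = True,
) -> NMDSResult:
    """Multi-start NMDS, returning the lowest-stress configuration.

    Runs up to ``n_starts`` optimizations from random configurations
    (seeds derived deterministically from ``seed``); ``converged`` is True
    once two runs agree on the minimum stress within ``stress_tol`` and
    superimpose under Procrustes with residual below ``procrustes_tol``.
    With ``stop_on_convergence`` the search stops at that point.
    """
    if d.n <= k:
        raise OrdinationError(f"need more than k={k} units, got {d.n}")
    if n_starts < 1:
        raise OrdinationError("n_starts must be >= 1")
    diss = d.condensed()
    best_coords: np.ndarray | None = None
    best_stress = np.inf
    best_seed = -1
    converged = False
    runs_used = 0
    for run in range(n_starts):
        run_seed = seed * 100_003 + run
        rng = np.random.default_rng(run_seed)
        coords = _single_run(d.values, k, rng, max_iter, eps)
        stress = kruskal_stress(diss, coords)
        runs_used = run + 1
        if stress < best_stress - stress_tol:
            best_coords, best_stress, best_seed = coords, stress, run_seed
            converged = False
        elif best_coords is not None and stress <= best_stress + stress_tol:
            pr = procrustes_test(
                pd.DataFrame(best_coords, index=d.unit_ids),
                pd.DataFrame(coords, index=d.unit_ids),
                n_perm=0,
            )
            if pr.m12_squared < procrustes_tol:
                converged = True
                if stress < best_stress:
                    best_coords, best_stress, best_seed = coords, stress, run_seed
                if stop_on_convergence:
                    break
    assert best_coords is not None
    frame = pd.DataFrame(
        best_coords, index=pd.Index(d.unit_ids, name="unit_id"),
        columns=[f"axis{i + 1}" for i in range(k)],
    )
    return NMDSResult(
        coordinates=frame, stress=best_stress, n_starts=runs_used,
        converged=converged, best_run_seed=best_seed,
    )


# ---------------------------------------------------------------------------
# Procrustes / Protest
# ---------------------------------------------------------------------------

def procrustes_test(
    conf_a: pd.DataFrame,
    conf_b: pd.DataFrame,
    *,
    n_perm: int = 999,
    seed: int = 0,
) -> ProcrustesResult:
    """Procrustes superimposition of two configurations, optionally with the
    Protest permutation test.

    ``m12_squared`` is the sum of squared residuals after optimal
    translation, rotation and uniform scaling of unit-norm configurations
    (0 means identical up to those transforms).  The permutation null
    shuffles the rows of the second configuration; p is the add-one
    fraction of permutations with a residual at most the observed one.
    """
    if list(conf_a.index) != list(conf_b.index):
        if set(conf_a.index) != set(conf_b.index):
            raise OrdinationError("configurations cover different unit sets")
        conf_b = conf_b.loc[conf_a.index]
    if conf_a.shape != conf_b.shape:
        raise OrdinationError("configurations have different dimensions")
    a = conf_a.to_numpy(dtype=float)
    b = conf_b.to_numpy(dtype=float)
    _, _, m12 = _scipy_procrustes(a, b)
    corr = float(np.sqrt(max(0.0, 1.0 - m12)))
    if n_perm <= 0:
        return ProcrustesResult(m12_squared=float(m12), correlation=corr)
    rng = np.random.default_rng(seed)
    n = a.shape[0]
    hits = 0
    for _ in range(n_perm):
        _, _, m12_p = _scipy_procrustes(a, b[rng.permutation(n)])
        if m12_p <= m12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return ProcrustesResult(
        m12_squared=float(m12), correlation=corr, p_value=p, n_perm=n_perm
    )


def group_centroids(coords: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-group centroid and covariance of ordination coordinates, for
    external confidence-ellipse plotting."""
    rows = []
    for g, sub in coords.groupby(groups.loc[coords.index]):
        rec = {"group": g, "n": len(sub)}
        for c in coords.columns:
            rec[f"centroid_{c}"] = sub[c].mean()
        cov = np.cov(sub.to_numpy().T) if len(sub) > 1 else np.zeros(
            (coords.shape[1], coords.shape[1])
        )
        for i, ci in enumerate(coords.columns):
            for j, cj in enumerate(coords.columns):
                if i <= j:
                    rec[f"cov_{ci}_{cj}"] = np.atleast_2d(cov)[i, j]
        rows.append(rec)
    return pd.DataFrame(rows).set_index("group")
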