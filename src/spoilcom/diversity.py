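"""Hill numbers and diversity profiles.

The Hill number of order q is the effective number of species

    qD = (sum_s p_s^q) ** (1 / (1 - q))

computed on the relative abundances p_s of the species actually present.
The order q weights dominance: q = 0 ignores abundance entirely and gives
species richness S; the q -> 1 limit is exp(H), the exponential of Shannon
entropy; q = 2 is the inverse Simpson concentration 1/(1-E) with E the
Gini-Simpson index.  Plotting qD against q gives a diversity profile: when
one community's profile sits above another's at every order, it is
unambiguously more diverse; crossing profiles mean the ordering depends on
how much weight rare species get.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

Q_ONE_TOL = 1e-9
DEFAULT_Q_GRID = tuple(float(q) for q in np.arange(0.0, 4.0 + 1e-12, 0.25))


class DiversityError(ValueError):
    pass


@dataclass
class DiversityProfile:
    q_grid: np.ndarray
    values: np.ndarray  # qD at each q
    p: np.ndarray  # relative abundances used (positive entries only)

    @property
    def richness(self) -> float:
        return float(self.p.size)

    @property
    def shannon(self) -> float:
        """Shannon entropy H (nats)."""
        return float(-np.sum(self.p * np.log(self.p)))

    @property
    def gini_simpson(self) -> float:
        """Gini-Simpson concentration E = 1 - sum p^2."""
        return float(1.0 - np.sum(self.p ** 2))

    def to_frame(self, group: str = "") -> pd.DataFrame:
        df = pd.DataFrame({"q": self.q_grid, "qD": self.values})
        if group:
            df.insert(0, "group", group)
        return df


def _relative_abundances(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        c = c.ravel()
    if np.any(c < 0):
        raise DiversityError("negative counts")
    c = c[c > 0]
    if c.size == 0:
        raise DiversityError("all counts are zero")
    return c / c.sum()


def hill_number(counts, q: float) -> float:
    """Effective species number of order q for one count vector."""
    if q < 0:
        raise DiversityError("q must be >= 0")
    p = _relative_abundances(counts)
    if abs(q - 1.0) <= Q_ONE_TOL:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p ** q) ** (1.0 / (1.0 - q)))


def renyi_profile(counts, q_grid=DEFAULT_Q_GRID) -> DiversityProfile:
    """Diversity profile over a grid of orders q."""
    q = np.asarray(q_grid, dtype=float)
    if q.size == 0:
        raise DiversityError("empty q grid")
    if np.any(np.diff(q) < 0):
        raise DiversityError("q grid must be sorted ascending")
    p = _relative_abundances(counts)
    values = np.array([hill_number(counts, qi) for qi in q])
    return DiversityProfile(q_grid=q, values=values, p=p)


def compare_profiles(pa: DiversityProfile, pb: DiversityProfile, *, tol: float = 1e-12):
    """Dominance relation between two profiles on the same q grid.

    Returns ``(verdict, crossings)`` where verdict is one of
    ``"A_dominates"``, ``"B_dominates"``, ``"equal"``, ``"crossing"`` and
    crossings lists the (q_lo, q_hi) grid intervals in which the sign of
    the difference flips.
    """
    if pa.q_grid.shape != pb.q_grid.shape or not np.allclose(pa.q_grid, pb.q_grid):
        raise DiversityError("profiles are on different q grids")
    diff = pa.values - pb.values
    sign = np.where(diff > tol, 1, np.where(diff < -tol, -1, 0))
    crossings = [
        (float(pa.q_grid[i]), float(pa.q_grid[i + 1]))
        for i in range(sign.size - 1)
        if sign[i] * sign[i + 1] == -1
    ]
    if crossings or (1 in sign and -1 in sign):
        return "crossing", crossings
    if 1 in sign:
        return "A_dominates", []
    if -1 in sign:
        return "B_dominates", []
    return "equal", []


def group_profiles(m, groups, q_grid=DEFAULT_Q_GRID, *, pooled: bool = True) -> dict:
    """Diversity profile per group of stations.

    With ``pooled`` (default) all stations of a group are summed into one
    community before profiling, treating the group as a single assemblage;
    otherwise returns per-station profiles keyed ``group/station``.
    """
    groups = pd.Series(groups).loc[m.unit_ids]
    out: dict[str, DiversityProfile] = {}
    for g, sub in m.data.groupby(groups):
        if pooled:
            out[str(g)] = renyi_profile(sub.sum(axis=0).to_numpy(), q_grid)
        else:
            for u in sub.index:
                out[f"{g}/{u}"] = renyi_profile(sub.loc[u].to_numpy(), q_grid)
    return out
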