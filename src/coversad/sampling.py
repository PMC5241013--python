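"""Sampling-sufficiency diagnostics for point-intercept surveys.

Two complementary views of whether 1010 points are enough:

* rarefied species accumulation — points are shuffled uniformly many times
  and richness recorded after each addition, showing how fast species are
  found with increasing effort;
* cumulative cover trajectories — points are added in the order they were
  collected in the field (zigzag across transects), and each species' FPC
  recomputed after every addition, showing how quickly cover estimates
  stabilise.  Field order, not random order, because additional intercepts
  in the field are not taken at random locations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cover import _check_records
from .survey import PointRecord, transect_number

__all__ = [
    "AccumulationCurve",
    "CoverTrajectory",
    "field_order",
    "species_accumulation",
    "cumulative_cover",
]


@dataclass
class AccumulationCurve:
    """Rarefied richness against number of intercept points.

    ``mean_richness[k-1]`` / ``sd_richness[k-1]`` are the mean and standard
    deviation of observed richness after k points, over ``n_replicates``
    uniform shuffles of the point set.
    """

    n_points: np.ndarray
    mean_richness: np.ndarray
    sd_richness: np.ndarray
    n_replicates: int


@dataclass
class CoverTrajectory:
    """Cumulative FPC of one species as field sampling proceeds.

    ``values[k-1]`` is 100 x hits-so-far / k after the first k points in
    field order; the final value equals the whole-plot FPC exactly.
    """

    species_code: str
    values: np.ndarray

    @property
    def final_fpc(self) -> float:
        return float(self.values[-1])


def field_order(records: Sequence[PointRecord]) -> list[PointRecord]:
    """Records in field collection order: zigzag transects, positions ascending.

    Transects sort by their ordinal (E1-W1, W2-E2, E3-W3, ...), positions
    ascend within each transect.  Idempotent; raises ``ValueError`` naming
    any unrecognisable transect label.
    """
    return sorted(records, key=lambda r: (transect_number(r.transect), r.position_m))


def _presence_matrix(records: Sequence[PointRecord]) -> tuple[np.ndarray, list[str]]:
    """Boolean points x species matrix of direct (non-sky) hits."""
    species = sorted(
        {h.species_code for r in records for h in r.hits if not h.is_sky}
    )
    index = {s: j for j, s in enumerate(species)}
    mat = np.zeros((len(records), len(species)), dtype=bool)
    for i, rec in enumerate(records):
        for h in rec.hits:
            if not h.is_sky:
                mat[i, index[h.species_code]] = True
    return mat, species


def species_accumulation(
    records: Sequence[PointRecord],
    n_replicates: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> AccumulationCurve:
    """Rarefied species accumulation curve over uniform point shuffles.

    Points are resampled without replacement (pure permutations of the
    observed point set), so the mean curve at the full point count equals
    observed richness exactly with zero spread.  A point may contribute
    zero (substrate only), one, or multiple species.
    """
    _check_records(records)
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    presence, species = _presence_matrix(records)
    n = len(records)
    curves = np.empty((n_replicates, n), dtype=np.int32)
    if not species:
        curves[:] = 0
    else:
        point_lists = [np.flatnonzero(presence[:, j]) for j in range(len(species))]
        for rep in range(n_replicates):
            order = rng.permutation(n)
            rank = np.empty(n, dtype=np.int64)
            rank[order] = np.arange(n)
            firsts = np.array([rank[pts].min() for pts in point_lists])
            new_at = np.bincount(firsts, minlength=n)
            curves[rep] = np.cumsum(new_at)
    return AccumulationCurve(
        n_points=np.arange(1, n + 1),
        mean_richness=curves.mean(axis=0),
        sd_richness=curves.std(axis=0),
        n_replicates=n_replicates,
    )


def cumulative_cover(records: Sequence[PointRecord]) -> list[CoverTrajectory]:
    """Cumulative FPC per species with points added in field order.

    After k points the trajectory value is 100 x hits-so-far / k, so early
    values swing widely and settle as the denominator grows.  Trajectories
    are returned for every intercepted species, most abundant (final FPC)
    first.
    """
    _check_records(records)
    ordered = field_order(records)
    presence, species = _presence_matrix(ordered)
    k = np.arange(1, len(ordered) + 1, dtype=float)
    out = [
        CoverTrajectory(sp, 100.0 * np.cumsum(presence[:, j]) / k)
        for j, sp in enumerate(species)
    ]
    out.sort(key=lambda t: (-t.final_fpc, t.species_code))
    return out
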