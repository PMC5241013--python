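"""Percent cover metrics from point-intercept records.

Foliage Projective Cover (FPC) for a species is the percentage of intercept
points at which its foliage is directly hit, within-canopy sky gaps
excluded.  Opaque Canopy Cover (OCC) additionally counts sky gaps
attributed to the species' canopy, treating each canopy as a solid
polygon, so OCC >= FPC always.

A species intercepted by several layers at the same point counts once at
that point (point-frequency convention): this is what bounds the metric at
100%.  The denominator is always the full set of layout points — points
that recorded only substrate still count — so summed single-species covers
may exceed 100% where strata overlap.
"""

from __future__ import annotations

import logging
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .survey import PlotVisit, PointRecord

__all__ = [
    "foliage_projective_cover",
    "opaque_canopy_cover",
    "fractional_cover",
    "species_cover_vector",
    "build_cover_matrix",
    "FractionalCover",
]

logger = logging.getLogger(__name__)

Metric = Literal["FPC", "OCC"]


def _check_records(records: Sequence[PointRecord]) -> None:
    if not records:
        raise ValueError("record list is empty: cover is undefined without points")
    ids = {(r.plot_id, r.visit_id) for r in records}
    if len(ids) > 1:
        raise ValueError(f"records span several plot-visits: {sorted(ids)}")


def species_cover_vector(
    records: Sequence[PointRecord], metric: Metric = "FPC"
) -> pd.Series:
    """Percent cover for every species seen in one plot-visit, in one pass.

    Returns a Series indexed by species code (lexicographic).  Under "OCC",
    sky hits are credited to ``canopy_species``; a sky hit with no
    attribution contributes to no species (logged once).
    """
    _check_records(records)
    if metric not in ("FPC", "OCC"):
        raise ValueError(f"metric must be 'FPC' or 'OCC', got {metric!r}")
    n_points = len(records)
    counts: dict[str, int] = {}
    unattributed = 0
    for rec in records:
        present: set[str] = set()
        for h in rec.hits:
            if h.is_sky:
                if metric == "OCC":
                    if h.canopy_species:
                        present.add(h.canopy_species)
                    else:
                        unattributed += 1
            else:
                present.add(h.species_code)
        for sp in present:
            counts[sp] = counts.get(sp, 0) + 1
    if unattributed:
        logger.warning(
            "%d in-canopy-sky hits had no canopy species attribution and were "
            "counted toward no species",
            unattributed,
        )
    series = pd.Series(counts, dtype=float).sort_index() * (100.0 / n_points)
    series.index.name = "species_code"
    series.name = metric
    return series


def foliage_projective_cover(
    records: Sequence[PointRecord], species: str
) -> float:
    """FPC of one species: 100 x points with a direct hit / total points."""
    _check_records(records)
    n_hit = sum(1 for r in records if r.species_hit(species))
    return 100.0 * n_hit / len(records)


def opaque_canopy_cover(records: Sequence[PointRecord], species: str) -> float:
    """OCC of one species: direct hits plus attributed in-canopy sky gaps."""
    _check_records(records)
    n_hit = 0
    for r in records:
        direct = r.species_hit(species)
        sky = any(h.is_sky and h.canopy_species == species for h in r.hits)
        if direct or sky:
            n_hit += 1
    return 100.0 * n_hit / len(records)


class FractionalCover(NamedTuple):
    """Partition of points into green vegetation, dead vegetation and bare.

    ``non_photosynthetic`` is NaN when the data dialect carries no
    green/brown flags; ``photosynthetic`` then counts every
    vegetation-topped point and the partition degrades to a
    vegetation/bare split.
    """

    photosynthetic: float
    non_photosynthetic: float
    bare: float


def fractional_cover(records: Sequence[PointRecord]) -> FractionalCover:
    """Classify each point by its uppermost vegetation hit.

    Green-topped points are photosynthetic cover, brown/dead-topped points
    non-photosynthetic; points with no vegetation hit are bare substrate
    unless the substrate itself is litter (dead plant material).  Sky hits
    are gaps, not vegetation, and are ignored.  The three percentages sum
    to 100.
    """
    _check_records(records)
    n = len(records)
    pv = npv = bare = unknown = 0
    for rec in records:
        veg = [h for h in rec.hits if not h.is_sky]
        if veg:
            top = max(veg, key=lambda h: (h.height_m if h.height_m is not None else -1.0))
            if top.green is True:
                pv += 1
            elif top.green is False:
                npv += 1
            else:
                unknown += 1
        elif rec.substrate == "litter":
            npv += 1
        else:
            bare += 1
    if unknown:
        logger.warning(
            "%d vegetation-topped points carried no green/brown flag; "
            "non-photosynthetic fraction is indeterminate",
            unknown,
        )
        return FractionalCover(100.0 * (pv + npv + unknown) / n, float("nan"), 100.0 * bare / n)
    return FractionalCover(100.0 * pv / n, 100.0 * npv / n, 100.0 * bare / n)


def build_cover_matrix(
    dataset: Iterable[PlotVisit], metric: Metric = "FPC"
) -> pd.DataFrame:
    """Plot-visits x species percent-cover matrix (the site-by-species table).

    Rows follow input order (MultiIndex plot_id/visit_id), columns are the
    union of species across all visits in lexicographic order, and a
    species absent from a visit's records is an explicit 0, never missing.
    """
    visits = list(dataset)
    if not visits:
        raise ValueError("dataset contains no plot-visits")
    ids = [v.id for v in visits]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate (plot, visit) ids: {dupes}")
    rows = [species_cover_vector(v.records, metric) for v in visits]
    index = pd.MultiIndex.from_tuples(ids, names=["plot_id", "visit_id"])
    matrix = pd.DataFrame(rows, index=index).fillna(0.0)
    matrix = matrix.reindex(sorted(matrix.columns), axis=1)
    matrix.columns.name = "species_code"
    matrix.attrs["metric"] = metric
    return matrix
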