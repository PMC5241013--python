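"""Per-plot diversity metrics from FPC cover vectors.

Shannon diversity H' = -sum p_i ln p_i (natural log) and the Gini–Simpson
index 1 - sum p_i^2, with p_i the species' share of summed cover.  The
Gini–Simpson complement is used for the "Simpson" index so that a
monoculture scores 0 and the upper bound is (S-1)/S; the raw dominance
sum(p^2) and the inverse form 1/sum(p^2) are exposed under their own names
for users who want the other conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .survey import PlotVisit

__all__ = [
    "shannon_diversity",
    "simpson_index",
    "simpson_dominance",
    "inverse_simpson",
    "richness",
    "DiversityRecord",
    "diversity_table",
]

logger = logging.getLogger(__name__)


def _proportions(covers: Sequence[float] | np.ndarray) -> np.ndarray:
    x = np.asarray(covers, dtype=float)
    if x.ndim != 1:
        raise ValueError("covers must be a 1-D vector")
    if np.any(x < 0):
        raise ValueError("covers must be non-negative")
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("all covers are zero: diversity is undefined")
    return x / x.sum()


def shannon_diversity(covers: Sequence[float] | np.ndarray) -> float:
    """H' in nats; 0 for a monoculture, at most ln(S) for S equal covers.

    Zeros are dropped before normalisation, and the result is invariant to
    rescaling all covers by a constant.
    """
    return float(stats.entropy(_proportions(covers)))


def simpson_dominance(covers: Sequence[float] | np.ndarray) -> float:
    """Raw Simpson concentration sum(p^2); 1 for a monoculture."""
    p = _proportions(covers)
    return float(np.sum(p**2))


def simpson_index(covers: Sequence[float] | np.ndarray) -> float:
    """Gini–Simpson index 1 - sum(p^2), in [0, (S-1)/S]."""
    return 1.0 - simpson_dominance(covers)


def inverse_simpson(covers: Sequence[float] | np.ndarray) -> float:
    """Hill number of order 2, 1/sum(p^2): effective number of species."""
    return 1.0 / simpson_dominance(covers)


def richness(plot_visit: PlotVisit) -> tuple[int, int]:
    """(point-intercept richness, voucher richness) for one visit.

    Point-intercept richness counts species with at least one direct
    (non-sky) hit; voucher richness counts distinct vouchered taxa.
    Visual-search vouchering normally finds more species than the
    intercept lines touch, so a voucher count below the intercept count is
    suspicious and logged, but not an error — real data can violate it.
    """
    r_pi = len(plot_visit.intercepted_species())
    r_voucher = len(set(plot_visit.vouchers))
    if plot_visit.vouchers and r_voucher < r_pi:
        logger.warning(
            "plot %s visit %s: voucher richness (%d) below point-intercept "
            "richness (%d)",
            plot_visit.plot_id,
            plot_visit.visit_id,
            r_voucher,
            r_pi,
        )
    return r_pi, r_voucher


@dataclass
class DiversityRecord:
    plot_id: str
    visit_id: str
    richness_pi: int
    richness_voucher: int
    shannon: float
    simpson: float


def diversity_table(
    visits: Iterable[PlotVisit], cover_matrix: pd.DataFrame
) -> pd.DataFrame:
    """Per-visit richness, Shannon and Simpson joined to site covariates.

    Diversity indices are computed from the visit's FPC row of
    ``cover_matrix``; visits with no intercepted species get NaN indices.
    """
    rows = []
    for v in visits:
        r_pi, r_voucher = richness(v)
        covers = (
            cover_matrix.loc[v.id].to_numpy()
            if v.id in cover_matrix.index
            else np.array([])
        )
        has_cover = covers.size > 0 and covers.sum() > 0
        rows.append(
            {
                "plot_id": v.plot_id,
                "visit_id": v.visit_id,
                "richness_pi": r_pi,
                "richness_voucher": r_voucher,
                "shannon": shannon_diversity(covers) if has_cover else np.nan,
                "simpson": simpson_index(covers) if has_cover else np.nan,
                "vegetation_group": v.vegetation_group,
                **v.covariates,
            }
        )
    return pd.DataFrame(rows)
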