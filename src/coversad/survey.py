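"""Core containers for point-intercept vegetation surveys.

A survey plot is a 1 ha square sampled by parallel transects walked in a
zigzag: the observer goes out along transect 1 (east to west), back along
transect 2 (west to east), and so on.  At every metre mark a vertical line
(laser/densitometer staff) is read off: every plant part it intercepts is a
*hit* (species, growth form, height), and the ground surface it lands on is
the *substrate*.  A line may pass through a canopy without touching foliage;
that is recorded as an 'in canopy sky' hit attributed to the canopy species.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "IN_CANOPY_SKY",
    "Hit",
    "PointRecord",
    "PlotLayout",
    "PlotVisit",
    "generate_plot_layout",
    "transect_number",
    "zigzag_transect_labels",
]

#: Sentinel species code for a point inside a canopy outline that hit sky.
IN_CANOPY_SKY = "IN_CANOPY_SKY"

_TRANSECT_RE = re.compile(r"^[EW](\d+)-[EW](\d+)$")


def zigzag_transect_labels(n_transects: int) -> tuple[str, ...]:
    """Transect ids in the order they are walked: E1-W1, W2-E2, E3-W3, ...

    Odd-numbered transects run east to west, even ones back west to east,
    continuing the zigzag across the plot.
    """
    labels = []
    for i in range(1, n_transects + 1):
        labels.append(f"E{i}-W{i}" if i % 2 == 1 else f"W{i}-E{i}")
    return tuple(labels)


def transect_number(label: str) -> int:
    """Ordinal of a transect id within the zigzag walking sequence.

    Raises ``ValueError`` naming the label if it does not look like a
    direction-labelled transect id (e.g. ``"E1-W1"`` or ``"W2-E2"``).
    """
    m = _TRANSECT_RE.match(label)
    if m is None or m.group(1) != m.group(2):
        raise ValueError(f"unrecognised transect label: {label!r}")
    return int(m.group(1))


@dataclass(frozen=True, slots=True)
class Hit:
    """One interception on the vertical line at a point.

    ``species_code == IN_CANOPY_SKY`` marks a within-canopy sky gap; such a
    hit should carry the enclosing canopy's species in ``canopy_species``.
    ``green`` flags photosynthetic (live) versus non-photosynthetic (dead)
    material; ``None`` when the data dialect does not record it.
    """

    species_code: str
    growth_form: str | None = None
    height_m: float | None = None
    green: bool | None = None
    canopy_species: str | None = None

    @property
    def is_sky(self) -> bool:
        return self.species_code == IN_CANOPY_SKY


@dataclass(slots=True)
class PointRecord:
    """All observations at one intercept location.

    ``hits`` may be empty (a substrate-only point); a point always carries
    exactly one substrate category.
    """

    plot_id: str
    visit_id: str
    transect: str
    position_m: int
    hits: tuple[Hit, ...] = ()
    substrate: str = "bare"

    def species_hit(self, species_code: str) -> bool:
        """True if the species is directly intercepted here (sky excluded)."""
        return any(h.species_code == species_code and not h.is_sky for h in self.hits)


@dataclass(frozen=True)
class PlotLayout:
    """Geometry of the point-intercept grid within one plot.

    The default survey design is ten 100 m transects read every metre,
    positions 0..100 inclusive, i.e. 10 x 101 = 1010 points.
    """

    transects: tuple[str, ...]
    positions: tuple[int, ...]
    spacing_m: int = 1

    @property
    def n_transects(self) -> int:
        return len(self.transects)

    @property
    def points_per_transect(self) -> int:
        return len(self.positions)

    @property
    def total_points(self) -> int:
        return self.n_transects * self.points_per_transect

    def iter_points(self) -> Iterator[tuple[str, int]]:
        """Yield (transect, position) pairs in field (zigzag) order."""
        for t in self.transects:
            for p in self.positions:
                yield t, p


def generate_plot_layout(
    n_transects: int = 10, transect_length_m: int = 100, spacing_m: int = 1
) -> PlotLayout:
    """Build the intercept grid for a plot.

    Positions run 0..transect_length_m inclusive at ``spacing_m`` intervals,
    so each transect carries length/spacing + 1 points and the default
    10 x 100 m @ 1 m design yields 1010 points.

    Raises
    ------
    ValueError
        If any argument is not a positive integer or the transect length is
        not divisible by the spacing.
    """
    for name, val in (
        ("n_transects", n_transects),
        ("transect_length_m", transect_length_m),
        ("spacing_m", spacing_m),
    ):
        if not isinstance(val, (int,)) or isinstance(val, bool) or val <= 0:
            raise ValueError(f"{name} must be a positive integer, got {val!r}")
    if transect_length_m % spacing_m != 0:
        raise ValueError(
            f"transect_length_m ({transect_length_m}) must be divisible by "
            f"spacing_m ({spacing_m})"
        )
    positions = tuple(range(0, transect_length_m + 1, spacing_m))
    return PlotLayout(
        transects=zigzag_transect_labels(n_transects),
        positions=positions,
        spacing_m=spacing_m,
    )


@dataclass
class PlotVisit:
    """One sampling event of one plot.

    Bundles the intercept records with the voucher species list (plants
    collected during exhaustive visual search, a superset of what the
    intercept lines touch), the vegetation-group label and environmental
    covariates such as mean annual precipitation (``map_mm``).

    ``truth`` holds generator-side ground truth for synthetic visits
    (e.g. the Pareto shape the community was drawn from); it is ``None``
    for visits read from files.
    """

    plot_id: str
    visit_id: str
    layout: PlotLayout
    records: list[PointRecord] = field(default_factory=list)
    vouchers: tuple[str, ...] = ()
    vegetation_group: str | None = None
    covariates: dict[str, float] = field(default_factory=dict)
    truth: dict | None = None

    @property
    def id(self) -> tuple[str, str]:
        return (self.plot_id, self.visit_id)

    def intercepted_species(self) -> set[str]:
        """Species codes with at least one direct (non-sky) hit."""
        out: set[str] = set()
        for rec in self.records:
            for h in rec.hits:
                if not h.is_sky:
                    out.add(h.species_code)
        return out
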