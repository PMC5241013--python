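"""Delimited-text readers/writers and configuration for the survey pipeline.

Formats (all UTF-8 CSV with a header row; every writer drops a
``<name>.schema.json`` sidecar describing its columns):

* point-intercept table — one row per hit with columns ``plot_id,
  visit_id, transect, position_m, species_code, canopy_species,
  growth_form, height_m, green_flag, substrate``.  A substrate-only point
  carries a single row with an empty ``species_code``;
  within-canopy sky gaps use the ``IN_CANOPY_SKY`` species code and name
  the enclosing canopy species.
* site table — one row per plot-visit with coordinates, vegetation-group
  label and environmental covariates (``map_mm`` etc.).
* voucher table — one row per (plot_id, visit_id, species_code).

Percent values are serialised at full precision; rounding happens only in
display columns of report tables.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .survey import IN_CANOPY_SKY, Hit, PlotLayout, PlotVisit, PointRecord, transect_number
from .synthetic import LandscapeConfig

__all__ = [
    "SchemaError",
    "PI_COLUMNS",
    "write_point_intercepts",
    "read_point_intercepts",
    "write_sites",
    "read_sites",
    "write_vouchers",
    "read_vouchers",
    "attach_sites",
    "write_cover_matrix",
    "write_table",
    "write_gradient_table",
    "load_config",
]

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """An input file does not match the documented column schema."""


PI_COLUMNS = [
    "plot_id",
    "visit_id",
    "transect",
    "position_m",
    "species_code",
    "canopy_species",
    "growth_form",
    "height_m",
    "green_flag",
    "substrate",
]

_GREEN_TO_TEXT = {True: "green", False: "brown", None: ""}
_TEXT_TO_GREEN = {"green": True, "brown": False, "": None}


def _write_sidecar(path: Path, columns: dict[str, str]) -> None:
    meta = {
        "file": path.name,
        "format": "csv",
        "encoding": "utf-8",
        "columns": [{"name": k, "description": v} for k, v in columns.items()],
    }
    sidecar = path.with_name(path.name + ".schema.json")
    sidecar.write_text(json.dumps(meta, indent=2) + "\n", encoding="utf-8")


def write_point_intercepts(visits: Iterable[PlotVisit], path: str | Path) -> None:
    """Serialise visits' intercept records to the point-intercept dialect."""
    path = Path(path)
    rows = []
    for v in visits:
        for rec in v.records:
            base = {
                "plot_id": rec.plot_id,
                "visit_id": rec.visit_id,
                "transect": rec.transect,
                "position_m": rec.position_m,
                "substrate": rec.substrate,
            }
            if not rec.hits:
                rows.append(
                    {
                        **base,
                        "species_code": "",
                        "canopy_species": "",
                        "growth_form": "",
                        "height_m": "",
                        "green_flag": "",
                    }
                )
            for h in rec.hits:
                rows.append(
                    {
                        **base,
                        "species_code": h.species_code,
                        "canopy_species": h.canopy_species or "",
                        "growth_form": h.growth_form or "",
                        "height_m": "" if h.height_m is None else repr(float(h.height_m)),
                        "green_flag": _GREEN_TO_TEXT[h.green],
                    }
                )
    pd.DataFrame(rows, columns=PI_COLUMNS).to_csv(path, index=False)
    _write_sidecar(
        path,
        {
            "plot_id": "plot identifier",
            "visit_id": "sampling-event identifier within the plot",
            "transect": "direction-labelled transect id (e.g. E1-W1)",
            "position_m": "integer metre mark along the transect",
            "species_code": f"species hit, or {IN_CANOPY_SKY}, or empty for a substrate-only point",
            "canopy_species": "enclosing canopy species for in-canopy-sky hits",
            "growth_form": "growth form of the hit",
            "height_m": "hit height in metres",
            "green_flag": "green (photosynthetic) / brown (dead) / empty if unrecorded",
            "substrate": "substrate category at the point",
        },
    )


def _infer_layout(records: Sequence[PointRecord]) -> PlotLayout:
    transects = sorted({r.transect for r in records}, key=transect_number)
    positions = sorted({r.position_m for r in records})
    spacing = int(np.diff(positions).min()) if len(positions) > 1 else 1
    return PlotLayout(
        transects=tuple(transects), positions=tuple(positions), spacing_m=spacing
    )


def read_point_intercepts(path: str | Path) -> list[PlotVisit]:
    """Parse a point-intercept CSV into plot visits.

    Rows are grouped into one record per (plot, visit, transect, position);
    multiple hit rows at a point merge into that record's hit list.  Extra
    columns are tolerated; a missing mandatory column raises
    ``SchemaError``, a non-integral position raises ``SchemaError`` naming
    the offending line, and fully duplicated hit rows are dropped with a
    warning.  Voucher lists are empty (vouchers live in their own file).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in PI_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {missing}")
    positions = pd.to_numeric(df["position_m"], errors="coerce")
    bad = positions.isna() | (positions != positions.round())
    if bad.any():
        line = int(df.index[bad][0]) + 2  # header is line 1
        raise SchemaError(
            f"{path}: line {line}: position_m {df['position_m'][bad].iloc[0]!r} "
            "is not an integer"
        )
    df = df.assign(position_m=positions.astype(int))
    n_before = len(df)
    df = df.drop_duplicates()
    dropped = n_before - len(df)
    if dropped:
        logger.warning("%s: dropped %d duplicate hit rows", path, dropped)

    visits: list[PlotVisit] = []
    for (plot_id, visit_id), vdf in df.groupby(["plot_id", "visit_id"], sort=False):
        records: list[PointRecord] = []
        for (transect, position), pdf in vdf.groupby(
            ["transect", "position_m"], sort=False
        ):
            transect_number(transect)  # validates the label, raising on junk
            hits = []
            for row in pdf.itertuples(index=False):
                if row.species_code == "":
                    continue
                hits.append(
                    Hit(
                        species_code=row.species_code,
                        canopy_species=row.canopy_species or None,
                        growth_form=row.growth_form or None,
                        height_m=float(row.height_m) if row.height_m else None,
                        green=_TEXT_TO_GREEN.get(row.green_flag, None),
                    )
                )
            records.append(
                PointRecord(
                    plot_id=plot_id,
                    visit_id=visit_id,
                    transect=transect,
                    position_m=int(position),
                    hits=tuple(hits),
                    substrate=pdf["substrate"].iloc[0],
                )
            )
        records = sorted(records, key=lambda r: (transect_number(r.transect), r.position_m))
        visits.append(
            PlotVisit(
                plot_id=plot_id,
                visit_id=visit_id,
                layout=_infer_layout(records),
                records=records,
            )
        )
    return visits


def write_sites(visits: Iterable[PlotVisit], path: str | Path) -> None:
    """One row per plot-visit: coordinates, vegetation group, covariates."""
    path = Path(path)
    rows = []
    for v in visits:
        rows.append(
            {
                "plot_id": v.plot_id,
                "visit_id": v.visit_id,
                "vegetation_group": v.vegetation_group or "",
                **{k: repr(float(val)) for k, val in v.covariates.items()},
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    _write_sidecar(
        path,
        {
            "plot_id": "plot identifier",
            "visit_id": "sampling-event identifier",
            "vegetation_group": "vegetation-group label (plain string)",
            "map_mm": "mean annual precipitation, mm",
            "latitude": "decimal degrees",
            "longitude": "decimal degrees",
        },
    )


def read_sites(path: str | Path) -> pd.DataFrame:
    """Site table as a DataFrame; ``map_mm`` must be positive when present."""
    df = pd.read_csv(path, dtype={"plot_id": str, "visit_id": str})
    for col in ("plot_id", "visit_id"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    if "map_mm" in df.columns and (df["map_mm"].dropna() <= 0).any():
        raise SchemaError(f"{path}: map_mm must be positive")
    return df


def write_vouchers(visits: Iterable[PlotVisit], path: str | Path) -> None:
    path = Path(path)
    rows = [
        {"plot_id": v.plot_id, "visit_id": v.visit_id, "species_code": sp}
        for v in visits
        for sp in v.vouchers
    ]
    pd.DataFrame(rows, columns=["plot_id", "visit_id", "species_code"]).to_csv(
        path, index=False
    )
    _write_sidecar(
        path,
        {
            "plot_id": "plot identifier",
            "visit_id": "sampling-event identifier",
            "species_code": "vouchered taxon",
        },
    )


def read_vouchers(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ("plot_id", "visit_id", "species_code") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {missing}")
    return df


def attach_sites(
    visits: Sequence[PlotVisit],
    sites: pd.DataFrame,
    vouchers: pd.DataFrame | None = None,
) -> list[PlotVisit]:
    """Fill visits' vegetation group, covariates and voucher lists in place."""
    site_map = {
        (str(r.plot_id), str(r.visit_id)): r for r in sites.itertuples(index=False)
    }
    voucher_map: dict[tuple[str, str], list[str]] = {}
    if vouchers is not None:
        for r in vouchers.itertuples(index=False):
            voucher_map.setdefault((r.plot_id, r.visit_id), []).append(r.species_code)
    covariate_cols = [
        c for c in sites.columns if c not in ("plot_id", "visit_id", "vegetation_group")
    ]
    for v in visits:
        row = site_map.get(v.id)
        if row is not None:
            v.vegetation_group = getattr(row, "vegetation_group", None) or None
            for c in covariate_cols:
                val = getattr(row, c)
                if pd.notna(val):
                    v.covariates[c] = float(val)
        if v.id in voucher_map:
            v.vouchers = tuple(sorted(voucher_map[v.id]))
    return list(visits)


def write_cover_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Site-by-species wide CSV with the plot-visit id columns first."""
    path = Path(path)
    matrix.reset_index().to_csv(path, index=False)
    _write_sidecar(
        path,
        {
            "plot_id": "plot identifier",
            "visit_id": "sampling-event identifier",
            "<species columns>": f"percent cover ({matrix.attrs.get('metric', 'FPC')}) "
            "per species; systematic absences are explicit zeros",
        },
    )


def write_table(df: pd.DataFrame, path: str | Path, descriptions: dict[str, str]) -> None:
    """Generic CSV writer with a schema sidecar."""
    path = Path(path)
    df.to_csv(path, index=False)
    _write_sidecar(path, descriptions)


def write_gradient_table(results: pd.DataFrame, path: str | Path) -> None:
    """Regression summary CSV shaped like the published gradient table.

    Adds display columns with the slope and interval bounds multiplied by
    10^4 (coefficients per mm of MAP are small) while keeping the raw
    machine-precision values.
    """
    out = results.copy()
    for col, disp in (
        ("slope", "coefficient_x1e4"),
        ("boot_ci_lower", "ci_lower_x1e4"),
        ("boot_ci_upper", "ci_upper_x1e4"),
    ):
        out[disp] = (out[col] * 1e4).round(2)
    write_table(
        out,
        path,
        {
            "group": "vegetation group, or Combined",
            "response": "SAD shape response (pareto_alpha | lognormal_sigma)",
            "n_obs": "plots entering the regression",
            "slope": "robust slope per mm MAP (machine precision)",
            "intercept": "robust intercept",
            "r2_wls": "weighted R^2 using the robust fit's weights",
            "boot_ci_lower": "bootstrap percentile lower bound (raw)",
            "boot_ci_upper": "bootstrap percentile upper bound (raw)",
            "overlaps_zero": "True if the bootstrap interval contains 0",
            "converged": "IRLS convergence flag",
            "coefficient_x1e4": "slope x 10^4 (display)",
            "ci_lower_x1e4": "lower bound x 10^4 (display)",
            "ci_upper_x1e4": "upper bound x 10^4 (display)",
        },
    )


def load_config(path: str | Path) -> dict:
    """Load a YAML pipeline configuration.

    Documented keys (all optional, with package defaults):

    - ``seed`` — master seed for every random stage.
    - ``layout`` — ``n_transects``, ``transect_length_m``, ``spacing_m``.
    - ``landscape`` — any ``LandscapeConfig`` field
      (``n_plots_per_group``, ``groups``, ``map_range``,
      ``shape_intercept``, ``shape_slope`` (number or per-group mapping),
      ``shape_noise_sd``, ``alpha_floor``, ``n_species``,
      ``total_cover_target``, ``species_pool_size``, ``voucher_ratio``).
    - ``sad`` — ``xmin`` (null = per-plot observed minimum),
      ``bias_correction``.
    - ``regression`` — ``n_replicates``, ``level``, ``huber_c``.
    """
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: configuration must be a mapping")
    return cfg


def landscape_config_from(cfg: dict, seed: int | None = None) -> LandscapeConfig:
    """Build a LandscapeConfig from a parsed configuration mapping."""
    from .survey import generate_plot_layout

    kwargs = dict(cfg.get("landscape", {}))
    if "map_range" in kwargs:
        kwargs["map_range"] = tuple(kwargs["map_range"])
    if "groups" in kwargs:
        kwargs["groups"] = tuple(kwargs["groups"])
    layout_cfg = cfg.get("layout")
    if layout_cfg:
        kwargs["layout"] = generate_plot_layout(**layout_cfg)
    if seed is not None:
        kwargs["seed"] = seed
    elif "seed" in cfg:
        kwargs["seed"] = cfg["seed"]
    return LandscapeConfig(**kwargs)
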