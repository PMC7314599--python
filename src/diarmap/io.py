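"""File-format plumbing: CSV tables, NetCDF rasters, GeoJSON admin polygons.

All tabular outputs are UTF-8 CSV with '.' decimals; gridded quantities
(population, covariates, draw cubes) are NetCDF with explicit year (and draw)
coordinates, indexed row-major from the north-west corner; admin units are
GeoJSON polygons with id/level/parent_id properties plus a hierarchy.csv.
Readers validate invariants and report offending line numbers or unit ids.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import box, mapping
from shapely.ops import unary_union

from .geomodel import PrevalenceDraws
from .worldgen import (
    SURVEY_COLUMNS,
    AdminHierarchy,
    Grid,
    NationalInputs,
    RiskFactor,
    Standardization,
    World,
    validate_surveys,
)

__all__ = [
    "write_surveys",
    "read_surveys",
    "write_hierarchy",
    "read_hierarchy",
    "write_admin_geojson",
    "read_admin_geojson",
    "write_geojson_join",
    "save_world",
    "load_world",
    "save_draws",
    "load_draws",
    "write_national_inputs",
    "read_national_inputs",
    "write_risk_factors",
    "read_risk_factors",
]

_ENGINE = "scipy"  # NetCDF3 backend; available wherever scipy is


# --- surveys ---------------------------------------------------------------


def write_surveys(df: pd.DataFrame, path: str | Path) -> None:
    df[SURVEY_COLUMNS].to_csv(path, index=False)


def read_surveys(path: str | Path, world: World | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    validate_surveys(df, world)
    return df


# --- admin hierarchy -------------------------------------------------------


def write_hierarchy(admin: AdminHierarchy, path: str | Path) -> None:
    admin.units.to_csv(path, index=False)


def read_hierarchy(path: str | Path) -> pd.DataFrame:
    units = pd.read_csv(path, keep_default_na=False)
    required = {"unit_id", "level", "parent_id", "country_id"}
    missing = required - set(units.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return units


def _unit_polygon(world: World, cells: np.ndarray):
    g = world.grid
    boxes = []
    for cell in cells:
        r, c = g.rowcol(int(cell))
        # row 0 is the northernmost band
        lon0 = g.origin_lon + c * g.cell_deg
        lat1 = g.origin_lat - r * g.cell_deg
        boxes.append(box(lon0, lat1 - g.cell_deg, lon0 + g.cell_deg, lat1))
    return unary_union(boxes)


def write_admin_geojson(world: World, path: str | Path) -> None:
    """All admin units as GeoJSON features with id/level/parent_id properties."""
    features = []
    for level in (0, 1, 2):
        for uid, cells in world.admin.cell_membership(level).items():
            geom = _unit_polygon(world, cells)
            features.append({
                "type": "Feature",
                "geometry": mapping(geom),
                "properties": {
                    "id": uid,
                    "level": level,
                    "parent_id": world.admin.parent(uid) if level else "",
                },
            })
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def write_geojson_join(
    world: World,
    table: pd.DataFrame,
    path: str | Path,
    level: int = 2,
) -> None:
    """Admin polygons at ``level`` with ``table`` columns joined by unit_id.

    A compact join for mapping: one feature per unit, geometry plus the
    table's columns as properties.
    """
    rows = table.set_index("unit_id")
    features = []
    for uid, cells in world.admin.cell_membership(level).items():
        props = {"id": uid, "level": level}
        if uid in rows.index:
            rec = rows.loc[uid]
            props.update({
                k: (v.item() if isinstance(v, np.generic) else v)
                for k, v in rec.items()
            })
        features.append({
            "type": "Feature",
            "geometry": mapping(_unit_polygon(world, cells)),
            "properties": props,
        })
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_admin_geojson(path: str | Path) -> pd.DataFrame:
    """Read unit properties back, checking every non-country parent exists."""
    data = json.loads(Path(path).read_text())
    rows = [f["properties"] for f in data["features"]]
    df = pd.DataFrame(rows)
    ids = set(df["id"])
    for _, row in df.iterrows():
        if row["level"] > 0 and row["parent_id"] not in ids:
            raise ValueError(
                f"admin unit {row['id']!r} references missing parent "
                f"{row['parent_id']!r}"
            )
    return df


# --- world -----------------------------------------------------------------


def save_world(world: World, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    names = sorted(world.covariates)
    ds = xr.Dataset(
        {
            "population": (("cell", "year"), world.population),
            "covariates": (
                ("covariate", "cell", "year"),
                np.stack([world.covariates[n] for n in names]),
            ),
        },
        coords={
            "year": list(world.years),
            "covariate": names,
        },
        attrs={
            "nrows": world.grid.nrows,
            "ncols": world.grid.ncols,
            "cell_deg": world.grid.cell_deg,
            "origin_lon": world.grid.origin_lon,
            "origin_lat": world.grid.origin_lat,
            "cov_means": json.dumps(
                {n: world.covariate_standardization[n].mean for n in names}
            ),
            "cov_sds": json.dumps(
                {n: world.covariate_standardization[n].sd for n in names}
            ),
            "cov_static": json.dumps(
                {n: bool(world.covariate_static[n]) for n in names}
            ),
        },
    )
    ds.to_netcdf(d / "world.nc", engine=_ENGINE)
    write_hierarchy(world.admin, d / "hierarchy.csv")
    pd.DataFrame({"cell_admin2": world.admin.cell_admin2}).to_csv(
        d / "cell_admin2.csv", index=False
    )
    write_admin_geojson(world, d / "admin.geojson")


def load_world(directory: str | Path) -> World:
    d = Path(directory)
    ds = xr.open_dataset(d / "world.nc", engine=_ENGINE)
    grid = Grid(
        nrows=int(ds.attrs["nrows"]),
        ncols=int(ds.attrs["ncols"]),
        cell_deg=float(ds.attrs["cell_deg"]),
        origin_lon=float(ds.attrs["origin_lon"]),
        origin_lat=float(ds.attrs["origin_lat"]),
    )
    units = read_hierarchy(d / "hierarchy.csv")
    cell_admin2 = pd.read_csv(d / "cell_admin2.csv")["cell_admin2"].to_numpy(
        dtype=object
    )
    admin = AdminHierarchy(units=units, cell_admin2=cell_admin2)
    names = [str(n) for n in ds["covariate"].values]
    covs = {n: ds["covariates"].values[i] for i, n in enumerate(names)}
    means = json.loads(ds.attrs["cov_means"])
    sds = json.loads(ds.attrs["cov_sds"])
    static = json.loads(ds.attrs["cov_static"])
    world = World(
        grid=grid,
        years=tuple(int(y) for y in ds["year"].values),
        admin=admin,
        population=ds["population"].values,
        covariates=covs,
        covariate_standardization={
            n: Standardization(mean=means[n], sd=sds[n]) for n in names
        },
        covariate_static={n: bool(static[n]) for n in names},
    )
    ds.close()
    return world


# --- draw cubes ------------------------------------------------------------


def save_draws(draws: PrevalenceDraws, path: str | Path) -> None:
    ds = xr.Dataset(
        {"draws": (("cell", "year", "draw"), draws.values)},
        coords={"year": list(draws.years)},
        attrs={"measure": draws.measure, "seed": -1 if draws.seed is None else draws.seed},
    )
    ds.to_netcdf(path, engine=_ENGINE)


def load_draws(path: str | Path) -> PrevalenceDraws:
    ds = xr.open_dataset(path, engine=_ENGINE)
    out = PrevalenceDraws(
        values=ds["draws"].values.copy(),
        years=tuple(int(y) for y in ds["year"].values),
        measure=str(ds.attrs["measure"]),
        seed=None if int(ds.attrs["seed"]) < 0 else int(ds.attrs["seed"]),
    )
    ds.close()
    return out


# --- national inputs and risk factors --------------------------------------


def write_national_inputs(inputs: NationalInputs, path: str | Path) -> None:
    inputs.table.to_csv(path, index=False)


def read_national_inputs(path: str | Path) -> NationalInputs:
    df = pd.read_csv(path)
    required = {"country", "year", "envelope_prevalence", "envelope_incidence",
                "envelope_mortality", "cfr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return NationalInputs(table=df)


def write_risk_factors(
    factors: list[RiskFactor], csv_path: str | Path, nc_path: str | Path,
    years: tuple[int, ...],
) -> None:
    pd.DataFrame(
        [{"name": f.name, "group": f.group, "rr": f.rr} for f in factors]
    ).to_csv(csv_path, index=False)
    ds = xr.Dataset(
        {
            "exposure": (
                ("factor", "cell", "year"),
                np.stack([f.exposure for f in factors]),
            )
        },
        coords={"factor": [f.name for f in factors], "year": list(years)},
    )
    ds.to_netcdf(nc_path, engine=_ENGINE)


def read_risk_factors(csv_path: str | Path, nc_path: str | Path) -> list[RiskFactor]:
    meta = pd.read_csv(csv_path)
    ds = xr.open_dataset(nc_path, engine=_ENGINE)
    factors = []
    names = [str(n) for n in ds["factor"].values]
    for _, row in meta.iterrows():
        i = names.index(row["name"])
        factors.append(
            RiskFactor(
                name=row["name"], group=row["group"],
                exposure=ds["exposure"].values[i].copy(), rr=float(row["rr"]),
            )
        )
    ds.close()
    return factors
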