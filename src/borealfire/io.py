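"""NetCDF / CSV input-output, unit conversion and run manifests.

Forcing files follow CF conventions with (time, lat, lon) grids; readers
accept any dimension order and the common unit variants (K, m s-1,
kg m-2 s-1) and convert to the module-internal units: degC, %, km/h,
mm/day, strikes km-2 day-1.  NetCDF is written through xarray's scipy
backend (NetCDF3 classic).
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import __version__
from .forcing import Forcing, ScenarioConfig
from .simulate import RunResult

__all__ = [
    "DEFAULT_VAR_MAP",
    "forcing_to_dataset",
    "write_forcing_netcdf",
    "read_forcing_netcdf",
    "write_outputs",
    "write_manifest",
    "verify_manifest",
]

#: CF variable name -> internal name
DEFAULT_VAR_MAP = {
    "tasmax": "tmax",
    "hurs": "rh",
    "sfcWind": "wind",
    "pr": "rain",
    "lightning": "lightning",
    "popdens": "popdens",
}

_INTERNAL_UNITS = {
    "tmax": "degC",
    "rh": "%",
    "wind": "km h-1",
    "rain": "mm day-1",
    "lightning": "km-2 day-1",
    "popdens": "km-2",
}

# recognised unit spellings -> affine conversion (scale, offset) to internal
_CONVERSIONS = {
    ("tmax", "K"): (1.0, -273.15),
    ("tmax", "degC"): (1.0, 0.0),
    ("tmax", "C"): (1.0, 0.0),
    ("rh", "%"): (1.0, 0.0),
    ("rh", "1"): (100.0, 0.0),
    ("wind", "m s-1"): (3.6, 0.0),
    ("wind", "km h-1"): (1.0, 0.0),
    ("rain", "kg m-2 s-1"): (86400.0, 0.0),
    ("rain", "mm day-1"): (1.0, 0.0),
    ("rain", "mm"): (1.0, 0.0),
    ("lightning", "km-2 day-1"): (1.0, 0.0),
    ("popdens", "km-2"): (1.0, 0.0),
}


def _grid_coords(cfg: ScenarioConfig):
    lat = 48.0 + 0.22 * np.arange(cfg.nlat)
    lon = -120.0 + 0.22 * np.arange(cfg.nlon)
    return lat, lon


def forcing_to_dataset(forcing: Forcing) -> xr.Dataset:
    """Pack generated forcing into a CF-style (time, lat, lon) dataset."""
    cfg = forcing.cfg
    lat, lon = _grid_coords(cfg)
    shape = (forcing.nday, cfg.nlat, cfg.nlon)
    data = {
        "tasmax": (forcing.tmax.reshape(shape), "degC", "daily maximum air temperature"),
        "hurs": (forcing.rh.reshape(shape), "%", "relative humidity"),
        "sfcWind": (forcing.wind.reshape(shape), "km h-1", "wind speed"),
        "pr": (forcing.rain.reshape(shape), "mm day-1", "total rainfall"),
        "lightning": (
            forcing.lightning.reshape(shape),
            "km-2 day-1",
            "cloud-to-ground lightning strike density",
        ),
    }
    ds = xr.Dataset(
        {
            name: xr.DataArray(
                arr,
                dims=("time", "lat", "lon"),
                attrs={"units": units, "long_name": long},
            )
            for name, (arr, units, long) in data.items()
        },
        coords={
            "time": np.arange(forcing.nday),
            "lat": ("lat", lat, {"units": "degrees_north"}),
            "lon": ("lon", lon, {"units": "degrees_east"}),
        },
        attrs={"Conventions": "CF-1.8", "source": f"borealfire {__version__}"},
    )
    ds["popdens"] = xr.DataArray(
        (forcing.popdens_field[None, :] * forcing.popdens_mult[:, None]).reshape(shape),
        dims=("time", "lat", "lon"),
        attrs={"units": "km-2", "long_name": "population density"},
    )
    return ds


def write_forcing_netcdf(forcing: Forcing, path) -> Path:
    path = Path(path)
    forcing_to_dataset(forcing).to_netcdf(path, engine="scipy")
    return path


def read_forcing_netcdf(path, var_map: dict | None = None) -> xr.Dataset:
    """Read a CF forcing file into internal units and (time, lat, lon) order.

    Raises KeyError naming any mapped variable missing from the file and
    ValueError for units with no registered converter.
    """
    if var_map is None:
        var_map = DEFAULT_VAR_MAP
    ds = xr.open_dataset(path, engine="scipy")
    out = {}
    for src, internal in var_map.items():
        if src not in ds:
            raise KeyError(f"forcing variable {src!r} missing from {path}")
        da = ds[src]
        missing = {"time", "lat", "lon"} - set(da.dims)
        if missing:
            raise ValueError(f"{src!r} lacks dimensions {sorted(missing)}")
        da = da.transpose("time", "lat", "lon")
        units = da.attrs.get("units", _INTERNAL_UNITS[internal])
        key = (internal, units)
        if key not in _CONVERSIONS:
            raise ValueError(
                f"no unit converter for variable {src!r} with units {units!r}"
            )
        scale, offset = _CONVERSIONS[key]
        da = da * scale + offset
        da.attrs["units"] = _INTERNAL_UNITS[internal]
        out[internal] = da
    return xr.Dataset(out)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(result: RunResult, outdir) -> dict:
    """Write annual maps (NetCDF), annual totals (CSV) and a manifest.

    Burned area is written in km^2 with Mha aggregates in the CSV;
    emissions in kg CO2 with Pg aggregates.  Returns the manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.scenario
    lat, lon = _grid_coords(cfg)
    shape = (len(result.year), cfg.nlat, cfg.nlon)
    ds = xr.Dataset(
        {
            "burned_area": xr.DataArray(
                result.burned_map_km2.reshape(shape),
                dims=("time", "lat", "lon"),
                attrs={"units": "km2", "long_name": "annual burned area"},
            ),
            "fire_co2": xr.DataArray(
                result.co2_map_kg.reshape(shape),
                dims=("time", "lat", "lon"),
                attrs={"units": "kg", "long_name": "annual fire CO2 emissions"},
            ),
        },
        coords={
            "time": result.year,
            "lat": ("lat", lat, {"units": "degrees_north"}),
            "lon": ("lon", lon, {"units": "degrees_east"}),
        },
        attrs={
            "Conventions": "CF-1.8",
            "source": f"borealfire {__version__}",
            "combustion_table": "bundled synthetic placeholder unless overridden",
        },
    )
    nc_path = outdir / "fire_diagnostics.nc"
    ds.to_netcdf(nc_path, engine="scipy")
    csv_path = outdir / "annual_totals.csv"
    result.annual_table().to_csv(csv_path, index=False)
    return write_manifest(
        outdir,
        files=[nc_path, csv_path],
        seed=cfg.seed,
        config_hash=hashlib.sha256(repr(cfg).encode()).hexdigest(),
    )


def write_manifest(outdir, files, seed: int, config_hash: str) -> dict:
    outdir = Path(outdir)
    manifest = {
        "package_version": __version__,
        "seed": int(seed),
        "config_hash": config_hash,
        "written_utc": datetime.now(timezone.utc).isoformat(),
        "files": {
            str(Path(f).name): _sha256(Path(f)) for f in files
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def verify_manifest(outdir) -> bool:
    """Re-hash every file listed in the manifest; True iff all match."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    return all(
        _sha256(outdir / name) == digest for name, digest in manifest["files"].items()
    )
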