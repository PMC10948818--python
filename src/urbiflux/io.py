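"""Readers/writers for forcing and flux series, plus provenance records.

CSV: comma-separated, UTF-8, ISO-8601 timestamps in a ``time`` column,
interval-start labeled hourly local time.  NetCDF: 1-D time series with
CF-style ``units`` attributes (written through xarray's scipy backend).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import xarray as xr

from .errors import DataError, SchemaError
from .forcing import FORCING_COLUMNS, validate_forcing

log = logging.getLogger(__name__)

__all__ = [
    "UNITS",
    "read_series",
    "write_series",
    "write_provenance",
]

#: CF-style units of every series variable the package writes.
UNITS = {
    "T_air": "degC",
    "PAR": "W m-2",
    "VPD": "kPa",
    "U": "m s-1",
    "precip": "mm h-1",
    "CO2": "ppm",
    "GPP_u": "gCO2 m-2 h-1",
    "R_u": "gCO2 m-2 h-1",
    "NEE_u": "gCO2 m-2 h-1",
    "swc": "m3 m-3",
    "theta": "1",
    "T_soil": "degC",
    "ET": "mm h-1",
    "irrigation": "mm",
    "drainage": "mm",
    "latent_cooling": "degC",
    "clamped": "1",
}

_SCHEMAS = {
    "forcing": FORCING_COLUMNS,
    "flux": ("GPP_u", "R_u", "NEE_u"),
    "soil": ("swc", "theta", "T_soil", "ET", "irrigation", "drainage"),
}


def _check_schema(df: pd.DataFrame, kind: str, path: Path) -> None:
    required = _SCHEMAS[kind]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing} for {kind} series")


def _check_time(df: pd.DataFrame, path: Path) -> None:
    if not df.index.is_monotonic_increasing or df.index.has_duplicates:
        raise DataError(f"{path}: time axis must be strictly increasing")


def write_series(df: pd.DataFrame, path: str | Path, kind: str = "forcing") -> Path:
    """Write an hourly series as CSV (.csv) or NetCDF (.nc), by extension."""
    path = Path(path)
    if kind not in _SCHEMAS:
        raise SchemaError(f"unknown series kind {kind!r}")
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".csv":
        df.to_csv(path, index_label="time", date_format="%Y-%m-%dT%H:%M:%S")
    elif path.suffix == ".nc":
        ds = xr.Dataset.from_dataframe(df.rename_axis("time"))
        for name in ds.data_vars:
            if name in UNITS:
                ds[name].attrs["units"] = UNITS[name]
        ds.attrs["featureType"] = "timeSeries"
        ds.to_netcdf(path, engine="scipy")
    else:
        raise SchemaError(f"unsupported format {path.suffix!r}; use .csv or .nc")
    return path


def read_series(path: str | Path, kind: str = "forcing") -> pd.DataFrame:
    """Read a series written by :func:`write_series`; validates the schema.

    Forcing series are additionally checked against the forcing-type
    invariants (hourly step, nonnegative PAR/wind/precipitation, positive
    CO2).
    """
    path = Path(path)
    if kind not in _SCHEMAS:
        raise SchemaError(f"unknown series kind {kind!r}")
    if path.suffix == ".csv":
        df = pd.read_csv(path, parse_dates=["time"], index_col="time")
    elif path.suffix == ".nc":
        with xr.open_dataset(path, engine="scipy") as ds:
            df = ds.to_dataframe()
        df.index = pd.DatetimeIndex(df.index)
        df.index.name = "time"
    else:
        raise SchemaError(f"unsupported format {path.suffix!r}; use .csv or .nc")
    _check_schema(df, kind, path)
    _check_time(df, path)
    if kind == "forcing":
        validate_forcing(df)
    return df


def write_provenance(
    outdir: str | Path, config: dict, seed: int, extra: dict | None = None
) -> Path:
    """Write a machine-readable provenance record next to run outputs.

    Records the package version, the seed, a SHA-256 hash of the effective
    configuration, and the configuration itself.
    """
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str)
    record = {
        "package": "urbiflux",
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "config": json.loads(blob),
    }
    if extra:
        record.update(extra)
    path = outdir / "provenance.json"
    path.write_text(json.dumps(record, indent=2, sort_keys=True))
    log.info("wrote provenance record to %s", path)
    return path
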