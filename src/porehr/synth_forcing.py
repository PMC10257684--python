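"""Synthetic gridded climate forcing for testing the HR pipeline.

Emulates the statistical structure of gridded monthly reanalysis
forcing without any downloads: latitudinal mean gradients, seasonal
cycles (hemisphere-phased), AR(1) anomalies, optional linear trends,
and an optional daily companion whose within-month mean reproduces the
monthly field exactly. All randomness derives from a single seed.

Default magnitudes are chosen to resemble land-surface climatology:
equator-to-pole temperature drop of 45 degC, seasonal amplitude growing
from 2 degC at the equator to 15 degC at the poles, monthly temperature
anomalies of 1.5 degC std with AR(1) rho = 0.5, mid-range saturation
0.55 with wetter tropics/poles and drier subtropics, saturation noise
0.05 std.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

FORCING_VARS = ("soil_temperature", "soil_moisture_saturation")


@dataclass
class ForcingSpec:
    """Parameters of the synthetic forcing generator."""

    nlat: int = 8
    nlon: int = 4
    years: tuple[int, int] = (2000, 2009)  # inclusive
    t_equator: float = 27.0  # [degC]
    t_pole_drop: float = 45.0  # equator-to-pole mean difference [degC]
    seasonal_amp_equator: float = 2.0  # [degC]
    seasonal_amp_pole: float = 15.0
    t_noise_sd: float = 1.5  # monthly AR(1) anomaly std [degC]
    t_noise_rho: float = 0.5
    t_trend: float = 0.0  # [degC / yr]
    sat_mid: float = 0.55
    sat_noise_sd: float = 0.05
    sat_noise_rho: float = 0.5
    sat_trend: float = 0.0  # [1 / yr]
    doc: float = 4.0  # [mol m-3]
    texture_scheme: str = "loam"  # single class or "latitudinal"
    daily: bool = False
    daily_noise_sd: float = 2.0  # within-month daily variability [degC]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nlat <= 0 or self.nlon <= 0:
            raise ValueError("grid dimensions must be positive")
        if not (abs(self.t_noise_rho) < 1 and abs(self.sat_noise_rho) < 1):
            raise ValueError("AR(1) coefficients must satisfy |rho| < 1")


def _ar1(rng: np.random.Generator, rho: float, sd: float, shape: tuple[int, ...]) -> np.ndarray:
    """Stationary AR(1) noise along axis 0 with marginal std ``sd``."""
    nt = shape[0]
    eps = rng.standard_normal(shape) * sd * np.sqrt(1.0 - rho**2)
    out = np.empty(shape)
    out[0] = rng.standard_normal(shape[1:]) * sd
    for t in range(1, nt):
        out[t] = rho * out[t - 1] + eps[t]
    return out


def gen_forcing(spec: ForcingSpec) -> xr.Dataset:
    """Generate a monthly forcing dataset (plus daily companion if asked).

    Deterministic for a given spec (bit-identical for equal seeds).
    Saturation is clipped to [0, 1]; temperature has a latitudinal
    gradient, hemisphere-phased seasonal cycle, AR(1) anomalies and an
    optional linear trend.
    """
    rng = np.random.default_rng(spec.seed)
    lat = np.linspace(-90 + 90 / spec.nlat, 90 - 90 / spec.nlat, spec.nlat)
    lon = np.linspace(-180 + 180 / spec.nlon, 180 - 180 / spec.nlon, spec.nlon)
    y0, y1 = spec.years
    times = pd.to_datetime(
        [f"{y}-{m:02d}-15" for y in range(y0, y1 + 1) for m in range(1, 13)]
    )
    nt = len(times)
    month = np.array([t.month for t in times])
    yearfrac = np.array([t.year - y0 for t in times], dtype=float)

    sinlat2 = np.sin(np.deg2rad(lat)) ** 2
    t_mean = spec.t_equator - spec.t_pole_drop * sinlat2  # (nlat,)
    amp = spec.seasonal_amp_equator + (spec.seasonal_amp_pole - spec.seasonal_amp_equator) * sinlat2
    phase = np.cos(2 * np.pi * (month[:, None] - 7) / 12.0)  # peak July (NH)
    hemis = np.sign(lat + 1e-12)  # southern hemisphere anti-phased
    t_clim = t_mean[None, :] + amp[None, :] * phase * hemis[None, :]

    t_noise = _ar1(rng, spec.t_noise_rho, spec.t_noise_sd, (nt, spec.nlat, spec.nlon))
    temp = (
        t_clim[:, :, None]
        + spec.t_trend * yearfrac[:, None, None]
        + t_noise
    )

    # moisture: wetter tropics and high latitudes, drier subtropics
    sat_clim = spec.sat_mid + 0.15 * np.cos(3.0 * np.deg2rad(lat)) - 0.1 * sinlat2
    s_noise = _ar1(rng, spec.sat_noise_rho, spec.sat_noise_sd, (nt, spec.nlat, spec.nlon))
    sat = np.clip(
        sat_clim[None, :, None] + spec.sat_trend * yearfrac[:, None, None] + s_noise,
        0.0,
        1.0,
    )

    if spec.texture_scheme == "latitudinal":
        classes = np.where(np.abs(lat) < 30, "clay_loam", np.where(np.abs(lat) < 60, "loam", "silt_loam"))
        texture = np.repeat(classes[:, None], spec.nlon, axis=1)
    else:
        texture = np.full((spec.nlat, spec.nlon), spec.texture_scheme)

    ds = xr.Dataset(
        {
            "soil_temperature": (
                ("time", "lat", "lon"),
                temp,
                {"units": "degC", "long_name": "topsoil temperature"},
            ),
            "soil_moisture_saturation": (
                ("time", "lat", "lon"),
                sat,
                {"units": "1", "long_name": "saturation degree theta/theta_s"},
            ),
            "texture": (("lat", "lon"), texture.astype("U16")),
            "doc": (
                ("lat", "lon"),
                np.full((spec.nlat, spec.nlon), spec.doc),
                {"units": "mol m-3"},
            ),
            "altitude": (
                ("lat", "lon"),
                np.zeros((spec.nlat, spec.nlon)),
                {"units": "m"},
            ),
        },
        coords={"time": times, "lat": ("lat", lat, {"units": "degrees_north"}),
                "lon": ("lon", lon, {"units": "degrees_east"})},
        attrs={"source": "porehr synthetic forcing generator", "seed": spec.seed},
    )
    if not spec.daily:
        return ds
    return ds, _daily_companion(spec, ds, rng)


def _daily_companion(spec: ForcingSpec, monthly: xr.Dataset, rng: np.random.Generator) -> xr.Dataset:
    """Daily fields whose within-month mean equals the monthly value exactly."""
    times = pd.DatetimeIndex(monthly["time"].values)
    days = pd.date_range(
        times[0].replace(day=1), times[-1] + pd.offsets.MonthEnd(0), freq="D"
    )
    nlat, nlon = monthly.sizes["lat"], monthly.sizes["lon"]
    t_daily = np.zeros((len(days), nlat, nlon))
    s_daily = np.zeros((len(days), nlat, nlon))
    dyear, dmonth = days.year, days.month
    for k, t in enumerate(times):
        sel = (dyear == t.year) & (dmonth == t.month)
        nd = int(sel.sum())
        anon = _ar1(rng, 0.6, spec.daily_noise_sd, (nd, nlat, nlon))
        anon -= anon.mean(axis=0, keepdims=True)  # exact monthly mean
        t_daily[sel] = monthly["soil_temperature"].values[k] + anon
        s_anon = _ar1(rng, 0.6, spec.daily_noise_sd * 0.02, (nd, nlat, nlon))
        s_anon -= s_anon.mean(axis=0, keepdims=True)
        s_daily[sel] = monthly["soil_moisture_saturation"].values[k] + s_anon
    ds = xr.Dataset(
        {
            "soil_temperature": (("time", "lat", "lon"), t_daily, {"units": "degC"}),
            "soil_moisture_saturation": (
                ("time", "lat", "lon"),
                np.clip(s_daily, 0, 1),
                {"units": "1"},
            ),
        },
        coords={"time": days, "lat": monthly["lat"], "lon": monthly["lon"]},
    )
    for aux in ("texture", "doc", "altitude"):
        ds[aux] = monthly[aux]
    return ds


# --------------------------------------------------------------------
# NetCDF round-trip (scipy backend, NetCDF3)
# --------------------------------------------------------------------

def write_forcing(ds: xr.Dataset, path) -> None:
    """Write a forcing dataset to NetCDF (classic format)."""
    enc = {}
    out = ds.copy()
    if "texture" in out:  # NetCDF3 has no strings; store as class codes
        classes = sorted(set(out["texture"].values.ravel().tolist()))
        codes = np.array(
            [[classes.index(v) for v in row] for row in out["texture"].values],
            dtype=np.int32,
        )
        out["texture"] = (("lat", "lon"), codes)
        out["texture"].attrs["classes"] = ",".join(classes)
    out.to_netcdf(path, engine="scipy", encoding=enc)


def read_forcing(path) -> xr.Dataset:
    """Read a forcing dataset, validating coordinates and units."""
    ds = xr.load_dataset(path, engine="scipy")
    for coord in ("lat", "lon"):
        if coord not in ds.coords:
            raise ValueError(f"dataset has no {coord!r} coordinate")
    for name in FORCING_VARS:
        if name in ds and "units" not in ds[name].attrs:
            raise ValueError(f"variable {name!r} has no units attribute")
    if "texture" in ds and ds["texture"].dtype.kind in "iu":
        classes = ds["texture"].attrs.get("classes", "")
        lut = classes.split(",")
        tex = np.array(
            [[lut[int(v)] for v in row] for row in ds["texture"].values], dtype="U16"
        )
        attrs = {k: v for k, v in ds["texture"].attrs.items() if k != "classes"}
        ds["texture"] = (("lat", "lon"), tex)
        ds["texture"].attrs.update(attrs)
    return ds
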