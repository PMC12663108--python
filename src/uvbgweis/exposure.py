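"""Individualized cumulative-weighted ambient UVB exposure (CW-D-UVB).

Vitamin D status reflects not a single day's sun but an exponentially
discounted history of ambient UVB: doses received recently contribute more
to circulating 25-hydroxyvitamin D than doses months ago, because vitamin D
is both produced and consumed with a half-life of roughly 35 days.  This
module turns a residential coordinate plus a blood-sampling date into

    CW-D-UVB = sum_{x=1..W} D(x) * exp(-(ln 2 / h) * x)

where ``D(x)`` is the daily ambient vitamin-D-effective UVB dose (kJ/m^2)
at the participant's grid cell on the day ``x`` days before sampling,
``h`` is the half-life in days (default 35), and ``W`` the window length
(default 135 days, beyond which contributions are negligible).

Residential coordinates arrive either as British National Grid
easting/northing (metres, OSGB36) or as latitude/longitude; the former are
converted with the inverse transverse Mercator projection on the Airy 1830
ellipsoid and then mapped onto a quarter-degree daily-dose grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "WeightingParams",
    "GridSpec",
    "DailyDoseGrid",
    "ResidenceRecord",
    "osgb_to_latlon",
    "osgb_to_wgs84",
    "latlon_to_cell",
    "daily_series",
    "decay_weights",
    "cumulative_weighted_dose",
    "build_exposure_table",
    "read_dose_grid",
    "write_dose_grid",
    "read_residences",
]


@dataclass(frozen=True)
class WeightingParams:
    """Exponential-decay weighting of past daily UVB doses.

    half_life_days : dose weight halves every this many days (default 35).
    window_days    : number of past days included; lag x runs 1..window_days,
                     x = 1 being the day before sampling (default 135).
    max_missing_fraction : maximum tolerated fraction of missing days in the
                     window before the participant is rejected.
    """

    half_life_days: float = 35.0
    window_days: int = 135
    max_missing_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.half_life_days <= 0:
            raise ValueError("half_life_days must be > 0")
        if self.window_days < 1:
            raise ValueError("window_days must be >= 1")
        if not 0 <= self.max_missing_fraction < 1:
            raise ValueError("max_missing_fraction must be in [0, 1)")


@dataclass(frozen=True)
class GridSpec:
    """Regular lat/lon grid, lower-left anchored, half-open cells."""

    lat_min: float
    lon_min: float
    n_lat: int
    n_lon: int
    cell_size_deg: float = 0.25

    def __post_init__(self) -> None:
        if self.cell_size_deg <= 0:
            raise ValueError("cell_size_deg must be > 0")
        if self.n_lat < 1 or self.n_lon < 1:
            raise ValueError("grid must have at least one cell per axis")

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.n_lat * self.cell_size_deg

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.n_lon * self.cell_size_deg

    def cell_center(self, i_lat: int, i_lon: int) -> tuple[float, float]:
        s = self.cell_size_deg
        return (self.lat_min + (i_lat + 0.5) * s, self.lon_min + (i_lon + 0.5) * s)


@dataclass
class DailyDoseGrid:
    """Daily ambient UVB doses (kJ/m^2) on a regular grid.

    ``dose`` has shape (n_days, n_lat, n_lon); missing values are NaN.
    Day index 0 corresponds to ``start_date``; every calendar day between
    start_date and end_date is addressable.
    """

    grid: GridSpec
    start_date: date
    dose: np.ndarray

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.ndim != 3:
            raise ValueError("dose must be (n_days, n_lat, n_lon)")
        if self.dose.shape[1:] != (self.grid.n_lat, self.grid.n_lon):
            raise ValueError("dose spatial shape does not match grid spec")
        with np.errstate(invalid="ignore"):
            if np.any(self.dose < 0):
                raise ValueError("daily doses must be non-negative")

    @property
    def n_days(self) -> int:
        return self.dose.shape[0]

    @property
    def end_date(self) -> date:
        return self.start_date + timedelta(days=self.n_days - 1)

    def day_index(self, d: date) -> int:
        return (d - self.start_date).days


@dataclass(frozen=True)
class ResidenceRecord:
    """One participant's residence and blood-sampling date.

    Exactly one coordinate representation must be present: OSGB
    easting/northing in metres, or latitude/longitude in degrees.
    """

    participant_id: str
    sample_date: date
    easting_m: float | None = None
    northing_m: float | None = None
    lat_deg: float | None = None
    lon_deg: float | None = None

    def __post_init__(self) -> None:
        has_osgb = self.easting_m is not None and self.northing_m is not None
        has_ll = self.lat_deg is not None and self.lon_deg is not None
        if has_osgb == has_ll:
            raise ValueError(
                f"{self.participant_id}: exactly one coordinate representation "
                "(easting/northing or lat/lon) must be given"
            )

    def to_latlon(self, helmert: bool = False) -> tuple[float, float]:
        if self.lat_deg is not None:
            return float(self.lat_deg), float(self.lon_deg)
        if helmert:
            return osgb_to_wgs84(self.easting_m, self.northing_m)
        return osgb_to_latlon(self.easting_m, self.northing_m)


# ---------------------------------------------------------------------------
# British National Grid (OSGB36 / Airy 1830 transverse Mercator)
# ---------------------------------------------------------------------------

# Airy 1830 ellipsoid and national-grid projection constants
_AIRY_A = 6_377_563.396
_AIRY_B = 6_356_256.909
_F0 = 0.9996012717          # central-meridian scale factor
_LAT0 = math.radians(49.0)  # true origin latitude
_LON0 = math.radians(-2.0)  # true origin longitude (central meridian)
_E0 = 400_000.0             # false easting
_N0 = -100_000.0            # false northing

# generous validity box for the national grid
_EXTENT = (-100_000.0, 800_000.0, -150_000.0, 1_300_000.0)


def _meridional_arc(phi: float, a: float = _AIRY_A, b: float = _AIRY_B) -> float:
    """Developed meridional arc M(phi) from the true origin, times F0."""
    n = (a - b) / (a + b)
    n2, n3 = n * n, n * n * n
    dphi = phi - _LAT0
    sphi = phi + _LAT0
    return b * _F0 * (
        (1 + n + 1.25 * n2 + 1.25 * n3) * dphi
        - (3 * n + 3 * n2 + 2.625 * n3) * math.sin(dphi) * math.cos(sphi)
        + (1.875 * n2 + 1.875 * n3) * math.sin(2 * dphi) * math.cos(2 * sphi)
        - (35.0 / 24.0) * n3 * math.sin(3 * dphi) * math.cos(3 * sphi)
    )


def osgb_to_latlon(easting_m: float, northing_m: float) -> tuple[float, float]:
    """Inverse transverse Mercator: OSGB grid coordinates -> OSGB36 lat/lon.

    Uses the standard national-grid series expansion on the Airy 1830
    ellipsoid; the meridional-arc inversion is iterated to < 1e-12 m.
    Returns (latitude, longitude) in degrees on the OSGB36 datum (no datum
    shift to WGS84; see :func:`osgb_to_wgs84`).
    """
    e_min, e_max, n_min, n_max = _EXTENT
    if not (e_min <= easting_m <= e_max and n_min <= northing_m <= n_max):
        raise ValueError(
            f"coordinates ({easting_m}, {northing_m}) outside the "
            "British National Grid extent"
        )
    a = _AIRY_A
    e2 = 1.0 - (_AIRY_B * _AIRY_B) / (a * a)

    # iterate phi' until the meridional arc reproduces the northing; the
    # arc is O(1e6 m), so 1e-9 m is at the edge of double precision
    phi = (northing_m - _N0) / (a * _F0) + _LAT0
    for _ in range(100):
        m = _meridional_arc(phi)
        delta = northing_m - _N0 - m
        if abs(delta) < 1e-9:
            break
        phi += delta / (a * _F0)

    sphi, cphi = math.sin(phi), math.cos(phi)
    tphi = sphi / cphi
    nu = a * _F0 / math.sqrt(1 - e2 * sphi * sphi)
    rho = a * _F0 * (1 - e2) * (1 - e2 * sphi * sphi) ** -1.5
    eta2 = nu / rho - 1

    t2 = tphi * tphi
    vii = tphi / (2 * rho * nu)
    viii = tphi / (24 * rho * nu**3) * (5 + 3 * t2 + eta2 - 9 * t2 * eta2)
    ix = tphi / (720 * rho * nu**5) * (61 + 90 * t2 + 45 * t2 * t2)
    sec = 1 / cphi
    x = sec / nu
    xi = sec / (6 * nu**3) * (nu / rho + 2 * t2)
    xii = sec / (120 * nu**5) * (5 + 28 * t2 + 24 * t2 * t2)
    xiia = sec / (5040 * nu**7) * (61 + 662 * t2 + 1320 * t2 * t2 + 720 * t2**3)

    de = easting_m - _E0
    lat = phi - vii * de**2 + viii * de**4 - ix * de**6
    lon = _LON0 + x * de - xi * de**3 + xii * de**5 - xiia * de**7
    return math.degrees(lat), math.degrees(lon)


def osgb_to_wgs84(easting_m: float, northing_m: float) -> tuple[float, float]:
    """OSGB grid -> WGS84 lat/lon via a 7-parameter Helmert transformation.

    The OSGB36 -> WGS84 small-angle Helmert shift is accurate to ~5 m,
    far below a quarter-degree grid cell; it is offered for callers who
    want datum-consistent coordinates.
    """
    lat, lon = osgb_to_latlon(easting_m, northing_m)
    phi, lam = math.radians(lat), math.radians(lon)
    a, b = _AIRY_A, _AIRY_B
    e2 = 1 - b * b / (a * a)
    nu = a / math.sqrt(1 - e2 * math.sin(phi) ** 2)
    x = nu * math.cos(phi) * math.cos(lam)
    y = nu * math.cos(phi) * math.sin(lam)
    z = (1 - e2) * nu * math.sin(phi)

    # OSGB36 -> WGS84 Helmert parameters (tx, ty, tz m; s ppm; rx, ry, rz arcsec)
    tx, ty, tz = 446.448, -125.157, 542.060
    s = -20.4894e-6
    rx, ry, rz = (math.radians(r / 3600.0) for r in (0.1502, 0.2470, 0.8421))
    x2 = tx + (1 + s) * x - rz * y + ry * z
    y2 = ty + rz * x + (1 + s) * y - rx * z
    z2 = tz - ry * x + rx * y + (1 + s) * z

    # back to geodetic on GRS80/WGS84
    a_w, b_w = 6_378_137.0, 6_356_752.3141
    e2w = 1 - b_w * b_w / (a_w * a_w)
    p = math.hypot(x2, y2)
    phi_w = math.atan2(z2, p * (1 - e2w))
    for _ in range(10):
        nu_w = a_w / math.sqrt(1 - e2w * math.sin(phi_w) ** 2)
        phi_w = math.atan2(z2 + e2w * nu_w * math.sin(phi_w), p)
    return math.degrees(phi_w), math.degrees(math.atan2(y2, x2))


# ---------------------------------------------------------------------------
# Grid lookup and dose weighting
# ---------------------------------------------------------------------------


def latlon_to_cell(lat: float, lon: float, grid: GridSpec) -> tuple[int, int]:
    """Map a point to its half-open grid cell (lower-left anchored).

    Cell (i, j) covers [lat_min + i*s, lat_min + (i+1)*s) x the analogous
    longitude interval; a point exactly on an interior boundary belongs to
    the higher-index cell.
    """
    s = grid.cell_size_deg
    i = math.floor((lat - grid.lat_min) / s)
    j = math.floor((lon - grid.lon_min) / s)
    if not (0 <= i < grid.n_lat and 0 <= j < grid.n_lon):
        raise ValueError(
            f"point ({lat:.4f}, {lon:.4f}) outside grid extent "
            f"[{grid.lat_min}, {grid.lat_max}) x [{grid.lon_min}, {grid.lon_max})"
        )
    return int(i), int(j)


def daily_series(
    grid_data: DailyDoseGrid,
    cell: tuple[int, int],
    sample_date: date,
    params: WeightingParams,
) -> tuple[np.ndarray, int, int]:
    """Dose series at lags x = 1..window_days before ``sample_date``.

    Returns (series, n_observed, n_imputed) with the most recent lag first
    (series[0] is the day before sampling).  Interior missing days are
    linearly interpolated between the nearest observed neighbours; missing
    runs touching the window edge carry the nearest observed value.  More
    than ``max_missing_fraction`` of the window missing is an error.
    """
    w = params.window_days
    first = sample_date - timedelta(days=w)   # lag w
    last = sample_date - timedelta(days=1)    # lag 1
    if first < grid_data.start_date or last > grid_data.end_date:
        raise ValueError(
            f"window {first}..{last} extends outside grid coverage "
            f"{grid_data.start_date}..{grid_data.end_date}"
        )
    i0 = grid_data.day_index(first)
    chunk = grid_data.dose[i0 : i0 + w, cell[0], cell[1]]
    series = chunk[::-1].copy()  # index 0 = lag 1 (most recent)
    missing = np.isnan(series)
    n_missing = int(missing.sum())
    if n_missing > params.max_missing_fraction * w:
        raise ValueError(
            f"{n_missing}/{w} days missing in window {first}..{last} "
            f"at cell {cell} exceeds max_missing_fraction="
            f"{params.max_missing_fraction}"
        )
    if n_missing:
        idx = np.arange(w)
        obs = ~missing
        # np.interp carries edge values for points outside the observed range
        series[missing] = np.interp(idx[missing], idx[obs], series[obs])
    return series, w - n_missing, n_missing


def decay_weights(params: WeightingParams) -> np.ndarray:
    """Weights e^{-(ln2/half_life) x} for lags x = 1..window_days."""
    x = np.arange(1, params.window_days + 1, dtype=float)
    return np.exp(-(math.log(2.0) / params.half_life_days) * x)


def cumulative_weighted_dose(
    series: np.ndarray, params: WeightingParams
) -> float:
    """Exponentially weighted sum of a lag-ordered daily dose series.

    ``series[x-1]`` is the dose on the day x days before sampling; the
    result is sum_x series[x-1] * 2^(-x / half_life), in kJ/m^2.
    """
    series = np.asarray(series, dtype=float)
    if series.shape != (params.window_days,):
        raise ValueError(
            f"series length {series.shape} != window_days {params.window_days}"
        )
    if np.any(series < 0) or not np.all(np.isfinite(series)):
        raise ValueError("dose series must be finite and non-negative")
    return float(series @ decay_weights(params))


def build_exposure_table(
    residences: Iterable[ResidenceRecord],
    grid_data: DailyDoseGrid,
    params: WeightingParams = WeightingParams(),
    helmert: bool = False,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Compute CW-D-UVB for every participant.

    Returns (table, failures).  The table has one row per successful
    participant with columns ``participant_id, cwduvb, n_days_observed,
    n_days_imputed``; failures collects (participant_id, reason) for
    residences that could not be resolved or whose dose window was too
    gappy, without aborting the rest.
    """
    rows, failures = [], []
    for rec in residences:
        try:
            lat, lon = rec.to_latlon(helmert=helmert)
            cell = latlon_to_cell(lat, lon, grid_data.grid)
            series, n_obs, n_imp = daily_series(
                grid_data, cell, rec.sample_date, params
            )
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "cwduvb": cumulative_weighted_dose(series, params),
                    "n_days_observed": n_obs,
                    "n_days_imputed": n_imp,
                }
            )
        except ValueError as exc:
            failures.append((rec.participant_id, str(exc)))
    table = pd.DataFrame(
        rows, columns=["participant_id", "cwduvb", "n_days_observed", "n_days_imputed"]
    )
    return table, failures


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------


def write_dose_grid(path, grid_data: DailyDoseGrid) -> None:
    """Long-format TSV with a ``#key value`` grid-spec header block."""
    g = grid_data.grid
    with open(path, "w") as fh:
        fh.write(f"#lat_min\t{g.lat_min}\n#lon_min\t{g.lon_min}\n")
        fh.write(f"#cell_size_deg\t{g.cell_size_deg}\n")
        fh.write(f"#n_lat\t{g.n_lat}\n#n_lon\t{g.n_lon}\n")
        fh.write("date\tlat_idx\tlon_idx\tdose_kjm2\n")
        for d in range(grid_data.n_days):
            day = grid_data.start_date + timedelta(days=d)
            for i in range(g.n_lat):
                for j in range(g.n_lon):
                    v = grid_data.dose[d, i, j]
                    s = "" if np.isnan(v) else f"{v:.6g}"
                    fh.write(f"{day.isoformat()}\t{i}\t{j}\t{s}\n")


def read_dose_grid(path) -> DailyDoseGrid:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, val = line[1:].rstrip("\n").split("\t")
            header[key] = float(val)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", parse_dates=["date"])
    grid = GridSpec(
        lat_min=header["lat_min"],
        lon_min=header["lon_min"],
        cell_size_deg=header["cell_size_deg"],
        n_lat=int(header["n_lat"]),
        n_lon=int(header["n_lon"]),
    )
    days = df["date"].dt.date
    start, end = days.min(), days.max()
    n_days = (end - start).days + 1
    dose = np.full((n_days, grid.n_lat, grid.n_lon), np.nan)
    d_idx = np.array([(d - start).days for d in days])
    dose[d_idx, df["lat_idx"].to_numpy(), df["lon_idx"].to_numpy()] = (
        df["dose_kjm2"].to_numpy(dtype=float)
    )
    return DailyDoseGrid(grid=grid, start_date=start, dose=dose)


def read_residences(path) -> list[ResidenceRecord]:
    """Residence TSV: participant_id, (easting, northing | lat, lon), sample_date."""
    df = pd.read_csv(path, sep="\t", dtype={"participant_id": str})
    recs = []
    osgb = {"easting", "northing"} <= set(df.columns)
    for _, r in df.iterrows():
        d = date.fromisoformat(str(r["sample_date"]))
        if osgb:
            recs.append(
                ResidenceRecord(
                    participant_id=r["participant_id"],
                    sample_date=d,
                    easting_m=float(r["easting"]),
                    northing_m=float(r["northing"]),
                )
            )
        else:
            recs.append(
                ResidenceRecord(
                    participant_id=r["participant_id"],
                    sample_date=d,
                    lat_deg=float(r["lat"]),
                    lon_deg=float(r["lon"]),
                )
            )
    return recs
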