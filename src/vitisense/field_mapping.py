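"""Survey-log I/O, microclimate de-trending, filtering and thematic maps.

A survey track is a time-ordered sequence of geo-referenced sensor polls
(one per side per stop): 15 CI sectors, 16 ST sectors, relative humidity,
air temperature, ultrasonic distance and GPS quality. Point records are
spatialized to rasters by inverse-distance weighting and exported as
ESRI ASCII grids, GeoJSON tracks and PNG renders.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .canopyct import average_sides
from .canopy_indices import BackgroundModel, center_of_gravity, ci_normalized_st, moment_of_inertia
from .sector_geometry import MACRO_SECTORS, N_CI_SECTORS, N_ST_SECTORS, vine_mean_ci

logger = logging.getLogger(__name__)

__all__ = [
    "SensorRecord",
    "SurveyTrack",
    "RasterMap",
    "read_survey_log",
    "write_survey_log",
    "detrend_microclimate",
    "filter_extraneous",
    "spatialize_idw",
    "sampling_interval",
    "export_maps",
    "MAP_CATALOG",
]

_CI_COLS = [f"ci_{i:02d}" for i in range(1, N_CI_SECTORS + 1)]
_ST_COLS = [f"st_{i:02d}" for i in range(1, N_ST_SECTORS + 1)]
_SCALAR_COLS = ["timestamp", "latitude", "longitude", "side", "rh", "at", "us",
                "n_satellites"]
SURVEY_COLUMNS = _SCALAR_COLS + _CI_COLS + _ST_COLS


@dataclass(frozen=True)
class SensorRecord:
    """One geo-referenced poll of every channel on one side."""

    timestamp: float  # seconds since survey start (or epoch)
    latitude: float
    longitude: float
    side: str  # "left" | "right"
    ci_sectors: tuple[float, ...]
    st_sectors: tuple[float, ...]
    rh: float
    at: float
    us: float
    n_satellites: int

    def __post_init__(self) -> None:
        if not (-90 <= self.latitude <= 90 and -180 <= self.longitude <= 180):
            raise ValueError("coordinates outside WGS84 bounds")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be left or right, got {self.side!r}")
        if len(self.ci_sectors) != N_CI_SECTORS:
            raise ValueError(f"expected {N_CI_SECTORS} CI sectors")
        if len(self.st_sectors) != N_ST_SECTORS:
            raise ValueError(f"expected {N_ST_SECTORS} ST sectors")
        if not (0 <= self.rh <= 100):
            raise ValueError("relative humidity outside [0, 100]")

    @property
    def vine_ci(self) -> float:
        return vine_mean_ci(self.ci_sectors)


@dataclass
class SurveyTrack:
    records: list[SensorRecord]
    polling_frequency_hz: float = 3.0
    nominal_speed_kmh: float = 6.0

    def __post_init__(self) -> None:
        ts = [r.timestamp for r in self.records]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValueError("timestamps must be non-decreasing")

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "timestamp": r.timestamp,
                "latitude": r.latitude,
                "longitude": r.longitude,
                "side": r.side,
                "rh": r.rh,
                "at": r.at,
                "us": r.us,
                "n_satellites": r.n_satellites,
            }
            row.update(dict(zip(_CI_COLS, r.ci_sectors)))
            row.update(dict(zip(_ST_COLS, r.st_sectors)))
            rows.append(row)
        return pd.DataFrame(rows, columns=SURVEY_COLUMNS)


def write_survey_log(track: SurveyTrack, path: str | Path) -> None:
    df = track.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")


def read_survey_log(path: str | Path) -> SurveyTrack:
    """Parse a survey CSV; malformed rows are skipped with a logged count."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(SURVEY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing mandatory columns: {sorted(missing)}")
    records, skipped = [], 0
    for row in df.itertuples(index=False):
        d = row._asdict()
        try:
            records.append(
                SensorRecord(
                    timestamp=float(d["timestamp"]),
                    latitude=float(d["latitude"]),
                    longitude=float(d["longitude"]),
                    side=str(d["side"]),
                    ci_sectors=tuple(float(d[c]) for c in _CI_COLS),
                    st_sectors=tuple(float(d[c]) for c in _ST_COLS),
                    rh=float(d["rh"]),
                    at=float(d["at"]),
                    us=float(d["us"]),
                    n_satellites=int(d["n_satellites"]),
                )
            )
        except (ValueError, TypeError):
            skipped += 1
    if skipped:
        logger.warning("skipped %d malformed survey rows", skipped)
    return SurveyTrack(records)


def detrend_microclimate(
    timestamps: Sequence[float],
    values: Sequence[float],
    smooth_window: int = 5,
) -> np.ndarray:
    """Smooth and de-trend an RH/AT series so time drift is removed.

    Moving-median smoothing (window 5) followed by subtraction of the OLS
    linear time trend, re-centered on the survey mean. Fewer than 5 points
    pass through unchanged with a warning.
    """
    t = np.asarray(timestamps, dtype=np.float64)
    v = np.asarray(values, dtype=np.float64)
    if t.shape != v.shape:
        raise ValueError("timestamps and values must align")
    if v.size < 5:
        warnings.warn("too few points to de-trend; passing through", stacklevel=2)
        return v.copy()
    # symmetric truncated windows keep linear ramps exactly linear at the edges
    half = smooth_window // 2
    smoothed = np.empty_like(v)
    for i in range(v.size):
        k = min(i, v.size - 1 - i, half)
        smoothed[i] = np.median(v[i - k: i + k + 1])
    slope, intercept = np.polyfit(t, smoothed, 1)
    return smoothed - (slope * t + intercept) + smoothed.mean()


def filter_extraneous(
    track: SurveyTrack,
    boundary: Optional[Polygon] = None,
    mad_window: int = 9,
    mad_multiplier: float = 4.0,
) -> SurveyTrack:
    """Drop extraneous side readings (vineyard borders, outlier polls).

    A side reading is dropped when its location falls outside the boundary
    polygon, or when its vine-level CI deviates from the running
    ``mad_window``-record median of its side by more than
    ``mad_multiplier`` times the running median absolute deviation.
    Dropped sides simply disappear from the track; the partner side stays
    usable through the single-side averaging path.
    """
    kept: list[SensorRecord] = []
    half = mad_window // 2
    by_side: dict[str, list[SensorRecord]] = {"left": [], "right": []}
    for r in track.records:
        by_side[r.side].append(r)

    flagged: set[int] = set()
    for side_records in by_side.values():
        cis = np.array([r.vine_ci for r in side_records])
        for i, r in enumerate(side_records):
            window = cis[max(0, i - half): i + half + 1]
            med = np.median(window)
            mad = np.median(np.abs(window - med))
            if abs(cis[i] - med) > mad_multiplier * mad:
                flagged.add(id(r))

    for r in track.records:
        if boundary is not None and not boundary.covers(Point(r.longitude, r.latitude)):
            continue
        if id(r) in flagged:
            continue
        kept.append(r)
    return SurveyTrack(kept, track.polling_frequency_hz, track.nominal_speed_kmh)


@dataclass
class RasterMap:
    """Regular grid of interpolated values with a no-data sentinel."""

    origin_x: float  # lower-left corner
    origin_y: float
    cell_size: float
    values: np.ndarray  # (nrows, ncols), row 0 = top
    parameter: str
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")
        if self.values.ndim != 2 or 0 in self.values.shape:
            raise ValueError("raster array must be 2-D and non-empty")

    def write_ascii_grid(self, path: str | Path) -> None:
        nrows, ncols = self.values.shape
        header = (
            f"ncols {ncols}\nnrows {nrows}\n"
            f"xllcorner {self.origin_x}\nyllcorner {self.origin_y}\n"
            f"cellsize {self.cell_size}\nNODATA_value {self.nodata}\n"
        )
        body = np.where(np.isnan(self.values), self.nodata, self.values)
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, body, fmt="%.6g")

    def write_png(self, path: str | Path, cmap: str = "RdYlGn") -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        masked = np.ma.masked_invalid(self.values)
        im = ax.imshow(masked, cmap=cmap, origin="upper")
        fig.colorbar(im, ax=ax, label=self.parameter)
        ax.set_title(self.parameter)
        fig.savefig(path, dpi=100)
        plt.close(fig)


def spatialize_idw(
    x: Sequence[float],
    y: Sequence[float],
    values: Sequence[float],
    cell_size: float = 2.0,
    power: float = 2.0,
    radius: Optional[float] = None,
    parameter: str = "value",
    padding: float = 1.0,
) -> RasterMap:
    """Inverse-distance-weighted raster of scattered point values.

    A cell whose center coincides with a sample takes the sample value
    exactly; cells with no neighbor inside ``radius`` get no-data (NaN).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    v = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        raise ValueError("no points to spatialize")
    if not (x.shape == y.shape == v.shape):
        raise ValueError("x, y, values must align")

    x0, y0 = x.min() - padding, y.min() - padding
    x1, y1 = x.max() + padding, y.max() + padding
    ncols = max(1, int(math.ceil((x1 - x0) / cell_size)))
    nrows = max(1, int(math.ceil((y1 - y0) / cell_size)))
    cx = x0 + (np.arange(ncols) + 0.5) * cell_size
    cy = y0 + (np.arange(nrows) + 0.5) * cell_size
    gx, gy = np.meshgrid(cx, cy[::-1])  # row 0 = top

    dx = gx[..., None] - x[None, None, :]
    dy = gy[..., None] - y[None, None, :]
    dist = np.hypot(dx, dy)
    if radius is not None:
        dist = np.where(dist <= radius, dist, np.inf)

    out = np.full((nrows, ncols), np.nan)
    exact = dist == 0
    has_exact = exact.any(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = 1.0 / dist**power
    w[~np.isfinite(w)] = 0.0
    wsum = w.sum(axis=-1)
    ok = wsum > 0
    out[ok] = (w[ok] @ v) / wsum[ok]
    # exact hits override the weighted sum
    if has_exact.any():
        idx = np.argmax(exact, axis=-1)
        out[has_exact] = v[idx[has_exact]]
    return RasterMap(x0, y0, cell_size, out, parameter)


def sampling_interval(speed_kmh: float, frequency_hz: float) -> float:
    """Ground spacing between polls, in meters: (speed m/s) / frequency."""
    if speed_kmh <= 0 or frequency_hz <= 0:
        raise ValueError("speed and frequency must be positive")
    return (speed_kmh * 1000.0 / 3600.0) / frequency_hz


# ---------------------------------------------------------------------------
# Thematic map catalog

def _catalog_keys() -> list[str]:
    keys = ["CI", "US", "RH", "AT", "ST", "COG", "MOI", "n_satellites"]
    keys += [f"CI_s{i}" for i in range(1, N_CI_SECTORS + 1)]
    keys += [f"ST_s{i}" for i in range(1, N_ST_SECTORS + 1)]
    keys += [f"CInormST_{name}" for name in MACRO_SECTORS]
    keys.append("GPS_track")
    return keys


MAP_CATALOG: tuple[str, ...] = tuple(_catalog_keys())

_NOT_IMPLEMENTED = {"3D_CI", "3D Canopy Index"}

#: rough meters per degree at mid latitudes, for local projection
_M_PER_DEG_LAT = 111_320.0


def _local_xy(track: SurveyTrack) -> tuple[np.ndarray, np.ndarray]:
    lat = np.array([r.latitude for r in track.records])
    lon = np.array([r.longitude for r in track.records])
    lat0, lon0 = lat.mean(), lon.mean()
    x = (lon - lon0) * _M_PER_DEG_LAT * math.cos(math.radians(lat0))
    y = (lat - lat0) * _M_PER_DEG_LAT
    return x, y


def _record_value(r: SensorRecord, key: str, background: BackgroundModel) -> float:
    if key == "CI":
        return r.vine_ci
    if key == "US":
        return r.us
    if key == "RH":
        return r.rh
    if key == "AT":
        return r.at
    if key == "ST":
        return float(np.mean(r.st_sectors))
    if key == "COG":
        return center_of_gravity(r.ci_sectors)
    if key == "MOI":
        return moment_of_inertia(r.ci_sectors)
    if key == "n_satellites":
        return float(r.n_satellites)
    if key.startswith("CI_s"):
        return r.ci_sectors[int(key[4:]) - 1]
    if key.startswith("ST_s"):
        return r.st_sectors[int(key[4:]) - 1]
    if key.startswith("CInormST_"):
        name = key.split("_", 1)[1]
        res = ci_normalized_st(r.st_sectors, r.ci_sectors, background)[name]
        return float("nan") if res.value is None else res.value
    raise KeyError(key)


def export_maps(
    track: SurveyTrack,
    out_dir: str | Path,
    selection: Optional[Sequence[str]] = None,
    cell_size: float = 2.0,
    power: float = 2.0,
    radius: Optional[float] = None,
    background: Optional[BackgroundModel] = None,
    render_png: bool = False,
) -> dict[str, Path]:
    """One raster (or GeoJSON track) per requested catalog entry.

    Unknown keys raise, listing the valid catalog; the undefined
    "3D Canopy Index" raises NotImplementedError explicitly.
    """
    if not track.records:
        raise ValueError("empty track")
    if background is None:
        background = BackgroundModel()
    selection = list(selection) if selection is not None else list(MAP_CATALOG)
    for key in selection:
        if key in _NOT_IMPLEMENTED:
            raise NotImplementedError(
                "3D Canopy Index: combination formula undefined; not produced"
            )
        if key not in MAP_CATALOG:
            raise KeyError(
                f"unknown map key {key!r}; valid keys: {', '.join(MAP_CATALOG)}"
            )

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    x, y = _local_xy(track)
    products: dict[str, Path] = {}
    for key in selection:
        if key == "GPS_track":
            path = out_dir / "gps_track.geojson"
            coords = [[r.longitude, r.latitude] for r in track.records]
            geo = {
                "type": "FeatureCollection",
                "features": [
                    {
                        "type": "Feature",
                        "geometry": {"type": "LineString", "coordinates": coords},
                        "properties": {"n_records": len(track)},
                    }
                ],
            }
            path.write_text(json.dumps(geo))
            products[key] = path
            continue
        vals = np.array(
            [_record_value(r, key, background) for r in track.records]
        )
        ok = ~np.isnan(vals)
        raster = spatialize_idw(
            x[ok], y[ok], vals[ok], cell_size=cell_size, power=power,
            radius=radius, parameter=key,
        )
        path = out_dir / f"{key}.asc"
        raster.write_ascii_grid(path)
        if render_png:
            raster.write_png(out_dir / f"{key}.png")
        products[key] = path
    return products
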