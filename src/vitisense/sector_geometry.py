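"""Canopy-wall sector layout, CI height interpolation and level repositioning.

The sensor looks up at the canopy wall from mid-row; its field of view is
sliced into 15 Canopy Index (CI) sectors and 16 surface-temperature (ST)
sectors by equally spaced viewing angles, so sector heights grow from the
base of the wall towards the top. CI sector 1 is anchored at the main
support wire; ST sector 6 shares that lower boundary, with ST sectors 1-5
extending the equal-angle slicing below it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SensorGeometry",
    "SectorLayout",
    "PQA_LEVELS",
    "MACRO_SECTORS",
    "GeometryError",
    "build_sector_layout",
    "interpolate_ci",
    "reposition_to_pqa_levels",
    "vine_mean_ci",
]

N_CI_SECTORS = 15
N_ST_SECTORS = 16
#: ST sectors below the CI range (ST 6 starts at CI 1's lower boundary).
ST_SECTORS_BELOW = 5

#: The 18 point-quadrat levels, cm relative to the support wire: -15, -5, ... 155.
PQA_LEVELS: tuple[int, ...] = tuple(10 * n - 25 for n in range(1, 19))

#: Macro-sectors pairing overlapping ST and CI sector index sets.
MACRO_SECTORS: dict[str, dict[str, tuple[int, ...]]] = {
    "Lower": {"st": (6, 7), "ci": (1, 2)},
    "Low": {"st": (8, 9), "ci": (3, 4)},
    "Center": {"st": (10, 11, 12), "ci": (5, 6, 7)},
    "Up": {"st": (13, 14), "ci": (8, 9)},
    "Upper": {"st": (15, 16), "ci": (10, 11)},
}


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class SensorGeometry:
    """Physical survey geometry, all lengths in cm, tilt in degrees."""

    row_spacing: float = 250.0
    wire_height: float = 70.0
    sensor_height: float = 50.0
    tilt_alpha: float = 41.0
    canopy_top: float = 160.0
    fov_upper_margin: float = 10.0

    def __post_init__(self) -> None:
        if self.row_spacing <= 0:
            raise GeometryError("row_spacing must be positive")
        if not (0 <= self.sensor_height < self.canopy_top):
            raise GeometryError("sensor must sit below the canopy top")
        if self.wire_height >= self.canopy_top:
            raise GeometryError("canopy_top must exceed wire_height")
        if not (0 < self.tilt_alpha < 90):
            raise GeometryError("tilt angle must lie in (0, 90) degrees")
        if self.wire_height <= self.sensor_height:
            raise GeometryError("support wire must be above the sensor")

    @property
    def stand_off(self) -> float:
        """Horizontal distance sensor-to-wall: half the row spacing."""
        return self.row_spacing / 2.0


@dataclass(frozen=True)
class SectorLayout:
    """Height intervals [h_lo, h_hi) of the CI and ST sectors, in cm."""

    ci_bounds: tuple[float, ...]  # 16 boundaries -> 15 sectors
    st_bounds: tuple[float, ...]  # 17 boundaries -> 16 sectors
    geometry: SensorGeometry

    @property
    def ci_intervals(self) -> list[tuple[float, float]]:
        return list(zip(self.ci_bounds[:-1], self.ci_bounds[1:]))

    @property
    def st_intervals(self) -> list[tuple[float, float]]:
        return list(zip(self.st_bounds[:-1], self.st_bounds[1:]))

    @property
    def ci_mid_heights(self) -> np.ndarray:
        b = np.asarray(self.ci_bounds)
        return (b[:-1] + b[1:]) / 2.0

    @property
    def st_mid_heights(self) -> np.ndarray:
        b = np.asarray(self.st_bounds)
        return (b[:-1] + b[1:]) / 2.0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "geometry": self.geometry.__dict__,
            "ci_bounds": list(self.ci_bounds),
            "st_bounds": list(self.st_bounds),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SectorLayout":
        payload = json.loads(Path(path).read_text())
        return cls(
            ci_bounds=tuple(payload["ci_bounds"]),
            st_bounds=tuple(payload["st_bounds"]),
            geometry=SensorGeometry(**payload["geometry"]),
        )


def build_sector_layout(geom: SensorGeometry) -> SectorLayout:
    """Slice the field of view into 15 CI and 16 ST equal-angle sectors.

    Boundary heights follow h = sensor_height + d * tan(theta) with d the
    mid-row stand-off; CI boundary angles run from the wire sight line to
    the canopy top plus the upper FOV margin. ST sectors reuse the CI
    angular step, shifted down by five sectors so ST 6 and CI 1 share
    their lower boundary.
    """
    d = geom.stand_off
    theta0 = math.atan2(geom.wire_height - geom.sensor_height, d)
    top = geom.canopy_top + geom.fov_upper_margin
    theta_top = math.atan2(top - geom.sensor_height, d)
    if theta_top <= theta0:
        raise GeometryError("degenerate FOV: top angle not above wire angle")

    ci_angles = np.linspace(theta0, theta_top, N_CI_SECTORS + 1)
    step = (theta_top - theta0) / N_CI_SECTORS
    st_angles = theta0 + step * np.arange(
        -ST_SECTORS_BELOW, N_ST_SECTORS - ST_SECTORS_BELOW + 1
    )

    ci_bounds = geom.sensor_height + d * np.tan(ci_angles)
    st_bounds = geom.sensor_height + d * np.tan(st_angles)
    # anchor exactly on the wire despite float noise
    ci_bounds[0] = geom.wire_height
    st_bounds[ST_SECTORS_BELOW] = geom.wire_height
    return SectorLayout(
        ci_bounds=tuple(ci_bounds), st_bounds=tuple(st_bounds), geometry=geom
    )


def interpolate_ci(
    values: Sequence[float],
    heights: Sequence[float],
    h: float,
    clamp: bool = False,
) -> float:
    """Linear CI interpolation between bracketing sector mid-heights.

    ``values`` are the 15 sector CIs, ``heights`` their mid-heights.
    Heights outside [heights[0], heights[-1]] raise unless ``clamp``.
    """
    values = np.asarray(values, dtype=np.float64)
    heights = np.asarray(heights, dtype=np.float64)
    if values.shape != heights.shape:
        raise GeometryError("values and heights must align")
    if not np.all(np.diff(heights) > 0):
        raise GeometryError("heights must be strictly increasing")
    if h < heights[0] or h > heights[-1]:
        if clamp:
            h = min(max(h, heights[0]), heights[-1])
        else:
            raise GeometryError(
                f"height {h} outside interpolable range "
                f"[{heights[0]:.1f}, {heights[-1]:.1f}]"
            )
    return float(np.interp(h, heights, values))


def reposition_to_pqa_levels(
    values: Sequence[float],
    heights: Sequence[float],
    wire_height: float,
    levels: Sequence[int] = PQA_LEVELS,
) -> dict[int, float]:
    """Interpolate a sector profile onto the point-quadrat levels.

    Levels are cm relative to the wire; a level outside the interpolable
    range maps to NaN (flagged missing) rather than raising.
    """
    out: dict[int, float] = {}
    for level in levels:
        h_abs = wire_height + level
        try:
            out[level] = interpolate_ci(values, heights, h_abs)
        except GeometryError:
            out[level] = float("nan")
    return out


def vine_mean_ci(values: Sequence[float], ignore_missing: bool = False) -> float:
    """Per-vine CI: arithmetic mean of the 15 sector values."""
    values = np.asarray(values, dtype=np.float64)
    if values.size != N_CI_SECTORS:
        raise GeometryError(f"expected {N_CI_SECTORS} sector values, got {values.size}")
    if np.isnan(values).any():
        if not ignore_missing:
            raise GeometryError("missing sector values (set ignore_missing to skip)")
        values = values[~np.isnan(values)]
        if values.size == 0:
            raise GeometryError("all sector values missing")
    return float(values.mean())
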