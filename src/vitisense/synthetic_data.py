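"""Coupled synthetic vineyard inputs driven by one virtual-canopy model.

A :class:`VirtualCanopy` carries a vertical leaf-density profile lambda(h)
(expected leaf contacts per point-quadrat insertion at height h). The same
profile drives every generated product:

* side-view RGB frames — a pixel at height h is vegetation with probability
  1 - exp(-lambda(h)), the chance a horizontal line of sight meets at least
  one leaf;
* point-quadrat insertions — leaf-contact counts are Poisson(lambda(h));
* survey logs — per-sector CI values integrate the same occupancy over
  each sector's height span.

Because a single occupancy field feeds both the imagery and the ground
truth, image-derived CI and simulated PQA metrics are correlated
mechanistically, which is what the calibration stages need to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .canopyct import canopy_index, segment_vegetation
from .pqa import CLUSTER, LEAF, Insertion
from .sector_geometry import (
    PQA_LEVELS,
    SectorLayout,
    SensorGeometry,
    build_sector_layout,
)
from .field_mapping import SensorRecord, SurveyTrack, sampling_interval, _M_PER_DEG_LAT

__all__ = [
    "VirtualCanopy",
    "SyntheticScene",
    "make_virtual_canopy",
    "render_side_view",
    "simulate_pqa",
    "simulate_survey",
    "vineyard_dataset",
]


@dataclass(frozen=True)
class VirtualCanopy:
    """Vertical leaf-density model of one vine.

    ``vigor`` scales the whole profile; the density peaks inside
    ``peak_band`` (cm above the wire) and decays above and below it.
    """

    vigor: float = 1.0
    wire_height: float = 70.0
    canopy_top: float = 160.0
    peak_band: tuple[float, float] = (15.0, 45.0)
    sigma_below: float = 20.0
    sigma_above: float = 55.0
    patchiness: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vigor < 0:
            raise ValueError("vigor must be non-negative")
        if self.canopy_top <= self.wire_height:
            raise ValueError("canopy_top must exceed wire_height")

    @property
    def peak_height(self) -> float:
        lo, hi = self.peak_band
        return self.wire_height + (lo + hi) / 2.0

    def leaf_density(self, h: Union[float, np.ndarray]) -> np.ndarray:
        """lambda(h): expected leaf contacts per insertion at height h (cm)."""
        h = np.asarray(h, dtype=np.float64)
        peak = self.peak_height
        sigma = np.where(h < peak, self.sigma_below, self.sigma_above)
        shape = np.exp(-0.5 * ((h - peak) / sigma) ** 2)
        shape = np.where(
            (h < self.wire_height - 15.0) | (h > self.canopy_top), 0.0, shape
        )
        return self.vigor * shape

    def occupancy(self, h: Union[float, np.ndarray]) -> np.ndarray:
        """Probability that a horizontal sight line at h meets vegetation."""
        return 1.0 - np.exp(-self.leaf_density(h))


def make_virtual_canopy(
    vigor: float = 1.0,
    seed: int = 0,
    **params,
) -> VirtualCanopy:
    return VirtualCanopy(vigor=vigor, seed=seed, **params)


@dataclass
class SyntheticScene:
    """A rendered frame with its per-pixel ground-truth labels."""

    image: np.ndarray  # (H, W, 3) uint8
    labels: np.ndarray  # bool, True = vegetation
    illumination: float
    sky_model: str

    @property
    def true_fraction(self) -> float:
        return float(self.labels.mean())

    def save_png(self, path: str | Path) -> None:
        from PIL import Image

        Image.fromarray(self.image).save(path)


def _hsl_to_rgb(h: np.ndarray, s: np.ndarray, l: np.ndarray) -> np.ndarray:
    """Vectorized HSL (degrees, fractions) -> RGB fractions."""
    c = (1.0 - np.abs(2.0 * l - 1.0)) * s
    hp = (h % 360.0) / 60.0
    x = c * (1.0 - np.abs(hp % 2.0 - 1.0))
    z = np.zeros_like(c)
    conds = [hp < 1, hp < 2, hp < 3, hp < 4, hp < 5, hp >= 5]
    r = np.select(conds, [c, x, z, z, x, c])
    g = np.select(conds, [x, c, c, x, z, z])
    b = np.select(conds, [z, z, x, c, c, x])
    m = l - c / 2.0
    return np.stack([r + m, g + m, b + m], axis=-1)


def render_side_view(
    canopy: VirtualCanopy,
    width: int = 256,
    height: int = 256,
    sky_model: str = "clear",
    illumination: float = 1.0,
    seed: Optional[int] = None,
    h_range: Optional[tuple[float, float]] = None,
    occupancy: Optional[Union[float, Callable[[np.ndarray], np.ndarray]]] = None,
) -> SyntheticScene:
    """Render a side-view frame of the canopy wall against a sky background.

    Rows map linearly to physical heights (top row = highest). The default
    height range spans the point-quadrat levels (wire - 15 to wire + 155).
    ``occupancy`` overrides the canopy-derived occupancy (a constant or a
    function of height) for controlled tests.
    """
    if sky_model not in ("clear", "overcast", "gradient"):
        raise ValueError(f"unknown sky model: {sky_model!r}")
    if not (0.3 <= illumination <= 1.8):
        raise ValueError("illumination factor must lie in [0.3, 1.8]")
    rng = np.random.default_rng(canopy.seed if seed is None else seed)

    if h_range is None:
        h_range = (canopy.wire_height - 15.0, canopy.wire_height + 155.0)
    h_lo, h_hi = h_range
    # pixel-row heights, top row first
    row_h = np.linspace(h_hi, h_lo, height)

    if occupancy is None:
        lam = canopy.leaf_density(row_h)[:, None]  # (H, 1)
        if canopy.patchiness > 0:
            # smooth horizontal density modulation
            raw = rng.normal(0.0, 1.0, width)
            kernel = np.exp(-0.5 * (np.arange(-10, 11) / 4.0) ** 2)
            kernel /= kernel.sum()
            smooth = np.convolve(raw, kernel, mode="same")
            mult = np.exp(canopy.patchiness * smooth)[None, :]
        else:
            mult = 1.0
        p = 1.0 - np.exp(-lam * mult)
    elif callable(occupancy):
        p = np.broadcast_to(
            np.asarray(occupancy(row_h), dtype=np.float64)[:, None], (height, width)
        )
    else:
        p = np.full((height, width), float(occupancy))

    labels = rng.random((height, width)) < p

    # vegetation: dark greens; sky: bright blue/white depending on model
    hh = np.where(
        labels,
        np.clip(rng.normal(110.0, 12.0, labels.shape), 75.0, 150.0),
        rng.normal(213.0, 6.0, labels.shape),
    )
    ss = np.where(
        labels,
        rng.uniform(0.45, 0.85, labels.shape),
        rng.uniform(0.45, 0.75, labels.shape),
    )
    ll = np.where(
        labels,
        np.clip(rng.normal(0.24, 0.05, labels.shape), 0.06, 0.42),
        np.clip(rng.normal(0.84, 0.03, labels.shape), 0.70, 0.95),
    )
    if sky_model == "overcast":
        ss = np.where(labels, ss, rng.uniform(0.0, 0.08, labels.shape))
        ll = np.where(labels, ll, np.clip(rng.normal(0.88, 0.02, labels.shape), 0.8, 0.97))
    elif sky_model == "gradient":
        grad = np.linspace(0.92, 0.74, labels.shape[0])[:, None]
        ll = np.where(labels, ll, np.clip(grad + rng.normal(0, 0.015, labels.shape), 0.6, 0.98))

    rgb = _hsl_to_rgb(hh, ss, ll)
    rgb = np.clip(rgb * illumination, 0.0, 1.0)
    image = (rgb * 255.0).round().astype(np.uint8)
    return SyntheticScene(image=image, labels=labels, illumination=illumination,
                          sky_model=sky_model)


def simulate_pqa(
    canopy: VirtualCanopy,
    levels: Sequence[int] = PQA_LEVELS,
    insertions_per_level: int = 1,
    seed: Optional[int] = None,
    vine_id: str = "v01",
    cluster_density: float = 0.0,
) -> list[Insertion]:
    """Simulate point-quadrat insertions from the canopy's density profile.

    Per insertion at level height h, the leaf-contact count is
    Poisson(lambda(h)); cluster contacts (optional) are Poisson with rate
    ``cluster_density`` inside the basal fruit zone. Contact order is
    shuffled.
    """
    if insertions_per_level < 1:
        raise ValueError("need at least 1 insertion per level")
    rng = np.random.default_rng(canopy.seed if seed is None else seed)
    out: list[Insertion] = []
    fruit_lo, fruit_hi = canopy.peak_band
    for level in levels:
        h = canopy.wire_height + level
        lam = float(canopy.leaf_density(h))
        in_fruit_zone = fruit_lo - 10.0 <= level <= fruit_hi
        for _ in range(insertions_per_level):
            n_leaf = rng.poisson(lam)
            n_cluster = rng.poisson(cluster_density) if in_fruit_zone else 0
            tokens = [LEAF] * int(n_leaf) + [CLUSTER] * int(n_cluster)
            rng.shuffle(tokens)
            out.append(Insertion(vine_id, int(level), tuple(tokens)))
    return out


def _sector_ci_from_canopy(
    canopy: VirtualCanopy, layout: SectorLayout, rng: np.random.Generator,
    noise_sd: float = 8.0,
) -> tuple[float, ...]:
    """Per-sector CI: occupancy integrated over each sector's height span."""
    cis = []
    for h_lo, h_hi in layout.ci_intervals:
        grid = np.linspace(h_lo, h_hi, 25)
        ci = 1000.0 * float(canopy.occupancy(grid).mean())
        ci += rng.normal(0.0, noise_sd)
        cis.append(float(np.clip(ci, 0.0, 1000.0)))
    return tuple(cis)


def _sector_st_from_canopy(
    canopy: VirtualCanopy, layout: SectorLayout, rng: np.random.Generator,
    t_vegetation: float = 22.0, t_background: float = 4.0, noise_sd: float = 0.3,
) -> tuple[float, ...]:
    """Per-sector ST as the vegetation/background mixture of the occupancy."""
    sts = []
    for h_lo, h_hi in layout.st_intervals:
        grid = np.linspace(h_lo, h_hi, 25)
        f_v = float(canopy.occupancy(grid).mean())
        st = t_vegetation * f_v + t_background * (1.0 - f_v)
        sts.append(float(st + rng.normal(0.0, noise_sd)))
    return tuple(sts)


def simulate_survey(
    canopies: Sequence[VirtualCanopy],
    n_rows: int = 2,
    speed_kmh: float = 6.0,
    frequency_hz: float = 3.0,
    seed: int = 0,
    geometry: Optional[SensorGeometry] = None,
    origin: tuple[float, float] = (45.1, 9.6),
    vine_spacing_m: float = 2.0,
    row_spacing_m: float = 2.4,
    rh_base: float = 55.0,
    rh_drift_per_min: float = 0.0,
    at_base: float = 24.0,
    at_drift_per_min: float = 0.0,
) -> SurveyTrack:
    """Per-vine stop records along vineyard rows, two sides per stop.

    ``canopies`` are assigned to vines row by row; each stop emits a left
    and a right record whose CI/ST sector profiles are integrated from the
    flanking canopy. RH/AT carry an optional known linear drift so the
    de-trending stage can be validated against it.
    """
    if n_rows < 1 or len(canopies) % n_rows != 0:
        raise ValueError("canopies must fill n_rows evenly")
    if geometry is None:
        geometry = SensorGeometry()
    layout = build_sector_layout(geometry)
    rng = np.random.default_rng(seed)
    per_row = len(canopies) // n_rows
    speed_ms = speed_kmh * 1000.0 / 3600.0
    lat0, lon0 = origin
    m_per_deg_lon = _M_PER_DEG_LAT * math.cos(math.radians(lat0))

    records: list[SensorRecord] = []
    t = 0.0
    for row in range(n_rows):
        for k in range(per_row):
            vine_idx = row * per_row + k
            canopy = canopies[vine_idx]
            # serpentine path
            along = k if row % 2 == 0 else per_row - 1 - k
            x_m = along * vine_spacing_m
            y_m = row * row_spacing_m
            t += vine_spacing_m / speed_ms
            minutes = t / 60.0
            rh = float(np.clip(rh_base + rh_drift_per_min * minutes
                               + rng.normal(0, 0.2), 0.0, 100.0))
            at = at_base + at_drift_per_min * minutes + rng.normal(0, 0.1)
            us = float(row_spacing_m * 100.0 / 2.0 + rng.normal(0, 3.0))
            for side in ("left", "right"):
                records.append(
                    SensorRecord(
                        timestamp=t,
                        latitude=lat0 + y_m / _M_PER_DEG_LAT,
                        longitude=lon0 + x_m / m_per_deg_lon,
                        side=side,
                        ci_sectors=_sector_ci_from_canopy(canopy, layout, rng),
                        st_sectors=_sector_st_from_canopy(canopy, layout, rng),
                        rh=rh,
                        at=at,
                        us=us,
                        n_satellites=int(rng.integers(8, 13)),
                    )
                )
    return SurveyTrack(records, polling_frequency_hz=frequency_hz,
                       nominal_speed_kmh=speed_kmh)


def vineyard_dataset(
    n_vines: int = 24,
    n_dates: int = 1,
    seed: int = 7,
    vigor_range: tuple[float, float] = (0.3, 3.0),
    insertions_per_level: int = 12,
    frame_size: int = 192,
) -> pd.DataFrame:
    """End-to-end per-vine dataset: image-derived CI vs simulated PQA truth.

    For each vine (vigor spread across ``vigor_range``) and date, a frame
    is rendered and segmented to get CI, and point-quadrat insertions are
    simulated from the same canopy to get %CG, LLN and %IL. Dates scale
    vigor to mimic seasonal growth. Columns: vine_id, date, ci, cg, lln,
    il, true_fraction, vigor.
    """
    rng = np.random.default_rng(seed)
    vigors = np.linspace(*vigor_range, n_vines)
    date_scale = np.linspace(0.55, 1.0, n_dates)
    rows = []
    for d in range(n_dates):
        for i in range(n_vines):
            vigor = float(vigors[i] * date_scale[d])
            canopy = VirtualCanopy(vigor=vigor, seed=int(rng.integers(2**31)))
            scene = render_side_view(
                canopy, width=frame_size, height=frame_size,
                seed=int(rng.integers(2**31)),
            )
            mask = segment_vegetation(scene.image)
            ci = canopy_index(mask)
            ins = simulate_pqa(
                canopy, insertions_per_level=insertions_per_level,
                seed=int(rng.integers(2**31)), vine_id=f"v{i + 1:02d}",
            )
            from .pqa import pqa_metrics

            m = pqa_metrics(ins)
            rows.append(
                {
                    "vine_id": f"v{i + 1:02d}",
                    "date": f"d{d + 1}",
                    "ci": ci,
                    "cg": m.cg_pct / 100.0,
                    "lln": m.lln,
                    "il": m.il_pct / 100.0,
                    "true_fraction": scene.true_fraction,
                    "vigor": vigor,
                }
            )
    return pd.DataFrame(rows)
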