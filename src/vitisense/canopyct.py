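"""Vegetation segmentation of side-view canopy frames and the Canopy Index.

The pipeline converts an 8-bit RGB frame into six per-pixel feature planes
(normalized R, G, B plus H, S, L), compresses them to a single scalar plane
with a linear combination, splits the scalar values into two classes with a
two-class Jenks natural-breaks partition, and labels the class with the
lower mean lightness as VEGETATION (the background is assumed to be sky).
The Canopy Index (CI) is the vegetation pixel fraction rescaled to 0-1000.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image

__all__ = [
    "FeaturePlanes",
    "FeatureWeights",
    "VegetationMask",
    "SegmentationError",
    "load_rgb",
    "compute_features",
    "project_to_scalar",
    "jenks_two_class",
    "segment_vegetation",
    "canopy_index",
    "average_sides",
]

#: Lightness above which a degenerate (single-class) frame is called all-sky.
DEFAULT_SKY_LIGHTNESS_FLOOR = 0.75


class SegmentationError(ValueError):
    """Raised on degenerate inputs (empty frames, single-class data, ...)."""


@dataclass(frozen=True)
class FeaturePlanes:
    """Per-pixel feature planes sharing the image shape.

    ``h`` is hue in degrees [0, 360) with 0 as the achromatic sentinel;
    ``s`` and ``l`` are fractions in [0, 1]; ``r``, ``g``, ``b`` are the
    channel values normalized to [0, 1].
    """

    r: np.ndarray
    g: np.ndarray
    b: np.ndarray
    h: np.ndarray
    s: np.ndarray
    l: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.l.shape

    def stacked(self) -> np.ndarray:
        """(n_pixels, 6) matrix in column order R, G, B, H/360, S, L."""
        return np.column_stack(
            [
                self.r.ravel(),
                self.g.ravel(),
                self.b.ravel(),
                self.h.ravel() / 360.0,
                self.s.ravel(),
                self.l.ravel(),
            ]
        )


@dataclass(frozen=True)
class FeatureWeights:
    """Coefficients of the 6-feature linear combination.

    ``mode`` is ``"fixed"`` (user-supplied coefficients) or ``"auto"``
    (leading principal axis of the standardized feature matrix, computed
    per image).
    """

    coefficients: Optional[tuple[float, ...]] = None
    mode: str = "auto"

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "auto"):
            raise ValueError(f"unknown weight mode: {self.mode!r}")
        if self.mode == "fixed":
            if self.coefficients is None or len(self.coefficients) != 6:
                raise ValueError("fixed mode requires exactly 6 coefficients")
            if not any(c != 0 for c in self.coefficients):
                raise SegmentationError("all-zero feature weights")

    @classmethod
    def fixed(cls, *coeffs: float) -> "FeatureWeights":
        return cls(coefficients=tuple(float(c) for c in coeffs), mode="fixed")

    @classmethod
    def auto(cls) -> "FeatureWeights":
        return cls(mode="auto")


@dataclass
class VegetationMask:
    """Two-class labeling of a frame: True where VEGETATION."""

    labels: np.ndarray  # bool, True = VEGETATION
    n_vegetation: int = field(init=False)
    n_total: int = field(init=False)
    threshold: Optional[float] = None
    weights_used: Optional[tuple[float, ...]] = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        self.n_vegetation = int(self.labels.sum())
        self.n_total = int(self.labels.size)

    def to_png(self, path: str | Path) -> None:
        Image.fromarray(self.labels.astype(np.uint8) * 255, mode="L").save(path)

    def sidecar(self) -> dict:
        return {
            "n_vegetation": self.n_vegetation,
            "n_total": self.n_total,
            "ci": canopy_index(self),
            "weights": list(self.weights_used) if self.weights_used else None,
            "threshold": self.threshold,
            "degenerate": self.degenerate,
        }

    def write(self, path: str | Path) -> None:
        path = Path(path)
        self.to_png(path)
        path.with_suffix(".json").write_text(json.dumps(self.sidecar(), indent=2))


def load_rgb(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG into an (H, W, 3) uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def _validate_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise SegmentationError(f"expected (H, W, 3) RGB array, got {image.shape}")
    if image.shape[0] == 0 or image.shape[1] == 0:
        raise SegmentationError("empty image")
    if image.min() < 0 or image.max() > 255:
        raise SegmentationError("channel values must lie in [0, 255]")
    return image


def compute_features(image: np.ndarray) -> FeaturePlanes:
    """Per-pixel HSL transform plus normalized RGB fractions.

    Hue is in degrees [0, 360); achromatic pixels (S = 0) get the hue
    sentinel 0. Lightness is (max + min) / 2 on the [0, 1] channel scale.
    """
    image = _validate_image(image)
    rgb = image.astype(np.float64) / 255.0
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]

    mx = rgb.max(axis=-1)
    mn = rgb.min(axis=-1)
    chroma = mx - mn
    lightness = (mx + mn) / 2.0

    with np.errstate(divide="ignore", invalid="ignore"):
        sat = np.where(chroma == 0, 0.0, chroma / (1.0 - np.abs(2.0 * lightness - 1.0)))
    sat = np.clip(np.nan_to_num(sat), 0.0, 1.0)

    hue = np.zeros_like(mx)
    safe = np.where(chroma == 0, 1.0, chroma)
    hr = np.mod((g - b) / safe, 6.0)
    hg = (b - r) / safe + 2.0
    hb = (r - g) / safe + 4.0
    hue = np.where(mx == r, hr, np.where(mx == g, hg, hb)) * 60.0
    hue = np.where(chroma == 0, 0.0, np.mod(hue, 360.0))

    return FeaturePlanes(r=r, g=g, b=b, h=hue, s=sat, l=lightness)


def _standardize(matrix: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance per column; constant columns map to 0."""
    mean = matrix.mean(axis=0)
    std = matrix.std(axis=0)
    constant = std <= 1e-12  # guard against float noise in constant columns
    std_safe = np.where(constant, 1.0, std)
    z = (matrix - mean) / std_safe
    z[:, constant] = 0.0
    return z


def project_to_scalar(features: FeaturePlanes, weights: FeatureWeights) -> np.ndarray:
    """Compress the six standardized feature planes to one scalar plane.

    In auto mode the weight vector is the leading principal axis of the
    standardized pixel matrix, sign-oriented so the lower-lightness class
    scores higher (vegetation above sky on the scalar axis).
    Returns the scalar plane; the weights actually used are attached as
    ``.weights_used`` metadata via a second return from
    :func:`_project_with_weights` internally — callers needing them should
    use :func:`segment_vegetation`.
    """
    plane, _ = _project_with_weights(features, weights)
    return plane


def _project_with_weights(
    features: FeaturePlanes, weights: FeatureWeights
) -> tuple[np.ndarray, tuple[float, ...]]:
    matrix = features.stacked()
    z = _standardize(matrix)

    if weights.mode == "fixed":
        w = np.asarray(weights.coefficients, dtype=np.float64)
    else:
        if not np.any(z):
            raise SegmentationError(
                "constant image: principal axis undefined in auto mode"
            )
        cov = (z.T @ z) / z.shape[0]
        eigvals, eigvecs = np.linalg.eigh(cov)
        w = eigvecs[:, -1]
        # orient so the lower-lightness class scores higher
        l_z = z[:, 5]
        if float((z @ w) @ l_z) > 0:
            w = -w

    scalar = z @ w
    return scalar.reshape(features.shape), tuple(float(c) for c in w)


def jenks_two_class(values: Sequence[float]) -> tuple[int, np.ndarray, float]:
    """Two-class Jenks natural-breaks partition of a 1-D value collection.

    Sorts the values and evaluates every contiguous split, minimizing the
    total within-class sum of squared deviations from the class means.
    Returns ``(split_index, sorted_values, ssd)`` where the low class is
    ``sorted_values[:split_index]`` and the high class the remainder.
    Ties are broken toward the smaller low class.
    """
    vals = np.sort(np.asarray(values, dtype=np.float64).ravel())
    n = vals.size
    if n < 2:
        raise SegmentationError("need at least 2 values")
    if vals[0] == vals[-1]:
        raise SegmentationError("all values identical: single-class input")

    csum = np.cumsum(vals)
    csq = np.cumsum(vals**2)
    k = np.arange(1, n)  # low-class sizes
    low_ssd = csq[k - 1] - csum[k - 1] ** 2 / k
    hi_n = n - k
    hi_sum = csum[-1] - csum[k - 1]
    hi_sq = csq[-1] - csq[k - 1]
    high_ssd = hi_sq - hi_sum**2 / hi_n
    total = low_ssd + high_ssd
    split = int(np.argmin(total)) + 1  # argmin takes first (smallest low class)
    return split, vals, float(total[split - 1])


#: Minimum goodness-of-variance fit for a Jenks split to count as two-class.
DEFAULT_MIN_SEPARATION = 0.8


def segment_vegetation(
    image: np.ndarray,
    weights: Optional[FeatureWeights] = None,
    sky_lightness_floor: float = DEFAULT_SKY_LIGHTNESS_FLOOR,
    min_separation: float = DEFAULT_MIN_SEPARATION,
) -> VegetationMask:
    """Two-class segmentation of a frame into VEGETATION vs OTHER.

    A frame is degenerate (single-class) when projection fails or when the
    best Jenks split explains less than ``min_separation`` of the scalar
    variance (goodness-of-variance fit) — i.e. the frame holds one
    population, not two. Degenerate frames are labeled all-OTHER when the
    mean lightness is at or above ``sky_lightness_floor`` (sky), otherwise
    all-VEGETATION.
    """
    if weights is None:
        weights = FeatureWeights.auto()
    features = compute_features(image)

    def degenerate_mask() -> VegetationMask:
        all_sky = float(features.l.mean()) >= sky_lightness_floor
        return VegetationMask(
            labels=np.full(features.shape, not all_sky, dtype=bool),
            degenerate=True,
        )

    try:
        scalar, used = _project_with_weights(features, weights)
        split, sorted_vals, ssd = jenks_two_class(scalar.ravel())
    except SegmentationError:
        return degenerate_mask()

    flat = scalar.ravel()
    ss_total = float(((flat - flat.mean()) ** 2).sum())
    if ss_total > 0 and 1.0 - ssd / ss_total < min_separation:
        return degenerate_mask()

    cut = sorted_vals[split]  # first value of the high class
    high = scalar >= cut
    # high scalar is oriented toward low lightness only in auto mode; decide
    # by class lightness regardless of how the weights were supplied
    l_high = features.l[high].mean()
    l_low = features.l[~high].mean()
    if l_high < l_low:
        veg = high
    elif l_high > l_low:
        veg = ~high
    else:  # lightness tie: greener mean hue (closer to 120 degrees) wins
        d_high = abs(float(features.h[high].mean()) - 120.0)
        d_low = abs(float(features.h[~high].mean()) - 120.0)
        veg = high if d_high <= d_low else ~high

    mask = VegetationMask(labels=veg, threshold=float(cut), weights_used=used)
    return mask


def canopy_index(mask: VegetationMask) -> float:
    """CI = 1000 x vegetation pixel fraction, a pure number in [0, 1000]."""
    if mask.n_total == 0:
        raise SegmentationError("empty mask: n_total = 0")
    return 1000.0 * mask.n_vegetation / mask.n_total


def average_sides(
    ci_left: Optional[float], ci_right: Optional[float]
) -> tuple[float, bool]:
    """Mean of left/right CI; a lone surviving side passes through flagged.

    Returns ``(ci, single_side)``. A side is "missing" when None or NaN
    (filtered as extraneous).
    """

    def present(v: Optional[float]) -> bool:
        return v is not None and not np.isnan(v)

    left_ok, right_ok = present(ci_left), present(ci_right)
    if left_ok and right_ok:
        return (float(ci_left) + float(ci_right)) / 2.0, False
    if left_ok:
        return float(ci_left), True
    if right_ok:
        return float(ci_right), True
    raise SegmentationError("both sides missing")
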