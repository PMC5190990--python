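"""Derived per-location canopy indices: COG, MOI and CI-normalized ST.

COG is the CI-weighted mean sector index of the vertical vegetation
distribution; MOI its second moment about COG. CI-normalized ST corrects
macro-sector surface temperature for the sky-background fraction, using
CI as the vegetated-fraction estimate:

    ST = T_V * F_V + T_B * (1 - F_V)   =>   T_V = (ST - T_B*(1 - F_V)) / F_V
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .sector_geometry import MACRO_SECTORS, N_CI_SECTORS, N_ST_SECTORS

__all__ = [
    "BackgroundModel",
    "MacroSectorResult",
    "IndexError_",
    "center_of_gravity",
    "moment_of_inertia",
    "ci_normalized_st",
]

ST_PLAUSIBLE_RANGE = (-20.0, 70.0)


class IndexError_(ValueError):
    """Degenerate profile (e.g. all-zero CI mass)."""


@dataclass(frozen=True)
class BackgroundModel:
    """Background (sky) surface temperature T_B, a few degrees C above zero."""

    t_background: float = 4.0
    source: str = "fixed"  # fixed | estimated-from-sky-sectors
    vegetation_temp_bound: float = 60.0

    def __post_init__(self) -> None:
        if self.t_background >= self.vegetation_temp_bound:
            raise ValueError("background temperature above vegetation bound")

    @classmethod
    def from_sky_sectors(cls, st_values: Sequence[float]) -> "BackgroundModel":
        """Estimate T_B from ST sectors 1-5 (below-canopy, sky-dominated)."""
        st = np.asarray(st_values, dtype=np.float64)
        if st.size != N_ST_SECTORS:
            raise ValueError(f"expected {N_ST_SECTORS} ST values")
        return cls(t_background=float(st[:5].mean()), source="estimated-from-sky-sectors")


@dataclass(frozen=True)
class MacroSectorResult:
    """CI-normalized ST output for one macro-sector."""

    name: str
    st_mean: float
    f_vegetated: float
    value: Optional[float]  # T_V (inversion) or ST/CI (ratio); None if undefined
    missing: bool = False


def _check_profile(values: Sequence[float]) -> np.ndarray:
    vals = np.asarray(values, dtype=np.float64)
    if vals.size != N_CI_SECTORS:
        raise ValueError(f"expected {N_CI_SECTORS} CI sector values, got {vals.size}")
    if np.any(vals < 0):
        raise ValueError("negative CI sector values")
    return vals


def center_of_gravity(values: Sequence[float]) -> float:
    """COG = sum(s * CI_s) / sum(CI_s) over sectors s = 1..15."""
    vals = _check_profile(values)
    total = vals.sum()
    if total == 0:
        raise IndexError_("all-zero profile: COG undefined")
    s = np.arange(1, N_CI_SECTORS + 1)
    return float((s * vals).sum() / total)


def moment_of_inertia(values: Sequence[float]) -> float:
    """MOI = sum(CI_s * (s - COG)^2); dispersion of CI mass around COG."""
    vals = _check_profile(values)
    cog = center_of_gravity(vals)
    s = np.arange(1, N_CI_SECTORS + 1)
    return float((vals * (s - cog) ** 2).sum())


def ci_normalized_st(
    st_values: Sequence[float],
    ci_values: Sequence[float],
    background: Optional[BackgroundModel] = None,
    mode: str = "inversion",
) -> dict[str, MacroSectorResult]:
    """CI-normalized surface temperature per macro-sector.

    ``inversion`` (default) removes the background contribution and returns
    the estimated vegetation temperature T_V; ``ratio`` returns the plain
    mean-ST / mean-CI quotient. Macro-sectors with no vegetated fraction
    (inversion) or zero CI (ratio) are flagged missing, not an error.
    """
    if mode not in ("inversion", "ratio"):
        raise ValueError(f"unknown mode: {mode!r}")
    if background is None:
        background = BackgroundModel()
    st = np.asarray(st_values, dtype=np.float64)
    ci = np.asarray(ci_values, dtype=np.float64)
    if st.size != N_ST_SECTORS:
        raise ValueError(f"expected {N_ST_SECTORS} ST values, got {st.size}")
    _check_profile(ci)
    lo, hi = ST_PLAUSIBLE_RANGE
    if st.min() < lo or st.max() > hi:
        warnings.warn("ST readings outside plausible range", stacklevel=2)

    results: dict[str, MacroSectorResult] = {}
    for name, members in MACRO_SECTORS.items():
        st_mean = float(st[[i - 1 for i in members["st"]]].mean())
        ci_mean = float(ci[[i - 1 for i in members["ci"]]].mean())
        f_v = ci_mean / 1000.0
        if mode == "inversion":
            if f_v <= 0:
                results[name] = MacroSectorResult(name, st_mean, f_v, None, True)
                continue
            t_v = (st_mean - background.t_background * (1.0 - f_v)) / f_v
            results[name] = MacroSectorResult(name, st_mean, f_v, t_v)
        else:
            if ci_mean == 0:
                results[name] = MacroSectorResult(name, st_mean, f_v, None, True)
                continue
            results[name] = MacroSectorResult(name, st_mean, f_v, st_mean / ci_mean)
    return results


def forward_st(t_vegetation: float, t_background: float, f_vegetated: float) -> float:
    """Compose a raw ST reading from its vegetation/background mixture."""
    if not (0.0 <= f_vegetated <= 1.0):
        raise ValueError("vegetated fraction must lie in [0, 1]")
    return t_vegetation * f_vegetated + t_background * (1.0 - f_vegetated)
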