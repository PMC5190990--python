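"""Point-quadrat ground truth and light-scanner canopy porosity.

A point-quadrat insertion is a horizontal rod pushed through the canopy at
a known height; the ordered contact sequence (leaves, clusters) is recorded,
an empty sequence marking a canopy gap. From a set of insertions:

* LLN  - mean leaf contacts per insertion,
* %CG  - percent of insertions with no contacts at all,
* %IL  - percent of leaf contacts that are interior (neither the first nor
         the last leaf touched in their insertion).

Canopy porosity from paired light scans is CP = 1 - mean(below)/mean(above).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .sector_geometry import PQA_LEVELS

__all__ = [
    "LEAF",
    "CLUSTER",
    "Insertion",
    "PqaMetrics",
    "pqa_metrics",
    "aggregate_metrics",
    "canopy_porosity",
    "read_insertions_csv",
    "write_insertions_csv",
]

LEAF = "L"
CLUSTER = "C"
_VALID_TOKENS = {LEAF, CLUSTER}


@dataclass(frozen=True)
class Insertion:
    """One rod insertion: vine, level (cm relative to the wire), contacts."""

    vine_id: str
    level_cm: int
    contacts: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        bad = set(self.contacts) - _VALID_TOKENS
        if bad:
            raise ValueError(f"unknown contact tokens: {sorted(bad)}")

    @property
    def is_gap(self) -> bool:
        return len(self.contacts) == 0

    @property
    def n_leaves(self) -> int:
        return sum(1 for c in self.contacts if c == LEAF)

    @property
    def n_interior_leaves(self) -> int:
        """Leaf contacts with another leaf both before and after them."""
        leaf_positions = [i for i, c in enumerate(self.contacts) if c == LEAF]
        return max(0, len(leaf_positions) - 2) if len(leaf_positions) >= 3 else 0


@dataclass(frozen=True)
class PqaMetrics:
    lln: float
    cg_pct: float
    il_pct: float
    n_insertions: int
    il_undefined: bool = False  # no leaf contacts at all


def pqa_metrics(insertions: Iterable[Insertion]) -> PqaMetrics:
    """LLN, %CG and %IL over a collection of insertions."""
    ins = list(insertions)
    if not ins:
        raise ValueError("no insertions")
    n = len(ins)
    total_leaves = sum(i.n_leaves for i in ins)
    n_gaps = sum(1 for i in ins if i.is_gap)
    interior = sum(i.n_interior_leaves for i in ins)
    lln = total_leaves / n
    cg = 100.0 * n_gaps / n
    if total_leaves == 0:
        return PqaMetrics(lln, cg, 0.0, n, il_undefined=True)
    return PqaMetrics(lln, cg, 100.0 * interior / total_leaves, n)


def aggregate_metrics(
    insertions: Iterable[Insertion], by: str = "vine"
) -> pd.DataFrame:
    """Per-vine or per-level metric table.

    ``by`` is ``"vine"``, ``"level"`` or ``"vine_level"``.
    """
    ins = list(insertions)
    if not ins:
        raise ValueError("no insertions")
    if by == "vine":
        keyfn = lambda i: (i.vine_id,)
        cols = ["vine_id"]
    elif by == "level":
        keyfn = lambda i: (i.level_cm,)
        cols = ["level_cm"]
    elif by == "vine_level":
        keyfn = lambda i: (i.vine_id, i.level_cm)
        cols = ["vine_id", "level_cm"]
    else:
        raise ValueError(f"unknown aggregation scope: {by!r}")

    groups: dict[tuple, list[Insertion]] = {}
    for i in ins:
        groups.setdefault(keyfn(i), []).append(i)
    rows = []
    for key in sorted(groups):
        m = pqa_metrics(groups[key])
        rows.append(
            dict(zip(cols, key))
            | {
                "lln": m.lln,
                "cg_pct": m.cg_pct,
                "il_pct": m.il_pct,
                "n_insertions": m.n_insertions,
            }
        )
    return pd.DataFrame(rows)


def canopy_porosity(
    below_readings: Sequence[float], above_readings: Sequence[float]
) -> float:
    """CP = 1 - mean(below) / mean(above), clamped to [0, 1]."""
    below = np.asarray(below_readings, dtype=np.float64)
    above = np.asarray(above_readings, dtype=np.float64)
    if below.size == 0 or above.size == 0:
        raise ValueError("empty reading set")
    if np.any(below < 0) or np.any(above < 0):
        raise ValueError("negative irradiance readings")
    max_ref = above.mean()
    if max_ref <= 0:
        raise ValueError("above-canopy reference mean must be positive")
    cp = 1.0 - below.mean() / max_ref
    if cp < 0:
        import warnings

        warnings.warn("below-canopy mean exceeds reference; clamping CP to 0",
                      stacklevel=2)
        cp = 0.0
    return float(cp)


# ---------------------------------------------------------------------------
# CSV I/O: columns vine_id, level_cm, contacts ("L;L;C;L", empty for a gap)

def read_insertions_csv(path: str | Path) -> list[Insertion]:
    df = pd.read_csv(path, dtype={"vine_id": str}, keep_default_na=False)
    required = {"vine_id", "level_cm", "contacts"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        contacts = tuple(t for t in str(row.contacts).split(";") if t)
        out.append(Insertion(str(row.vine_id), int(row.level_cm), contacts))
    return out


def write_insertions_csv(insertions: Iterable[Insertion], path: str | Path) -> None:
    rows = [
        {
            "vine_id": i.vine_id,
            "level_cm": i.level_cm,
            "contacts": ";".join(i.contacts),
        }
        for i in insertions
    ]
    pd.DataFrame(rows, columns=["vine_id", "level_cm", "contacts"]).to_csv(
        path, index=False
    )
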