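"""Percent-rescue scoring of histopathology markers and the composite
improvement score.

Rescue of a marker in one muscle is the percent reduction of the treated
level relative to the untreated level. Marker averages are arithmetic
means across muscles, optionally dropping cells whose underlying group
difference was not significant; the final composite is the mean of the
marker averages. All reported percentages are rounded to one decimal,
half away from zero.

The per-marker exclusion convention (drop non-significant cells for the
necrotic-foci marker, keep all cells otherwise) is reverse-engineered
from the printed averages of the source trial's composite table and is
exposed as explicit configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MUSCLES",
    "MARKERS",
    "DEFAULT_EXCLUSION",
    "RescueTable",
    "round_half_away",
    "percent_rescue",
    "marker_average",
    "composite_score",
    "rescue_table",
]

MUSCLES = ("cranial_sartorius", "lateral_gastrocnemius", "vastus_lateralis", "diaphragm")
MARKERS = ("inflammation", "necrotic_foci", "igg_myofibers", "regeneration")

Exclusion = Literal["none", "drop_nonsignificant"]

#: Per-marker averaging convention: foci averaging drops non-significant
#: cells; the other markers retain every muscle.
DEFAULT_EXCLUSION: Mapping[str, Exclusion] = {
    "inflammation": "none",
    "necrotic_foci": "drop_nonsignificant",
    "igg_myofibers": "none",
    "regeneration": "none",
}


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (so 30.25 -> 30.3 at one decimal)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent_rescue(untreated: float, treated: float) -> float:
    """``100 * (untreated - treated) / untreated``; untreated must be > 0."""
    if untreated <= 0:
        raise ValueError("untreated level must be > 0 (rescue undefined)")
    return float(100.0 * (untreated - treated) / untreated)


def marker_average(
    rescues: Sequence[float] | Sequence[tuple[str, float, bool]],
    exclusion: Exclusion = "none",
    significant: Sequence[bool] | None = None,
) -> float:
    """Arithmetic mean of per-muscle rescue values, to one decimal.

    Accepts either plain values (with an optional parallel ``significant``
    flag list) or ``(muscle, rescue, significant)`` triples. With
    ``drop_nonsignificant``, cells flagged not significant are excluded
    before averaging.
    """
    if len(rescues) == 0:
        raise ValueError("need at least one rescue value")
    if rescues and isinstance(rescues[0], (tuple, list)):
        values = [float(r[1]) for r in rescues]  # type: ignore[index]
        flags = [bool(r[2]) for r in rescues]  # type: ignore[index]
    else:
        values = [float(r) for r in rescues]  # type: ignore[arg-type]
        flags = list(significant) if significant is not None else [True] * len(values)
    if len(flags) != len(values):
        raise ValueError("significance flags must match rescue values")
    if exclusion == "drop_nonsignificant":
        values = [v for v, ok in zip(values, flags) if ok]
    elif exclusion != "none":
        raise ValueError(f"unknown exclusion {exclusion!r}")
    if not values:
        raise ValueError("all cells excluded; cannot average")
    return round_half_away(float(np.mean(values)), 1)


def composite_score(marker_averages: Sequence[float]) -> float:
    """Mean of the per-marker average rescues, to one decimal."""
    if len(marker_averages) == 0:
        raise ValueError("need at least one marker average")
    return round_half_away(float(np.mean([float(v) for v in marker_averages])), 1)


@dataclass
class RescueTable:
    """Per-cell rescues, per-marker averages, and the composite score."""

    rescue: pd.DataFrame            # muscles x markers, percent
    significant: pd.DataFrame       # muscles x markers, bool
    marker_averages: dict[str, float]
    composite: float


def rescue_table(
    untreated: pd.DataFrame,
    treated: pd.DataFrame,
    significant: pd.DataFrame | None = None,
    exclusion: Mapping[str, Exclusion] | None = None,
) -> RescueTable:
    """Full scoring: cellwise rescue, marker averages, composite.

    ``untreated`` and ``treated`` are muscles x markers level matrices with
    identical index/columns; ``significant`` optionally flags which cells'
    group differences reached significance (default: all True).
    """
    if not untreated.index.equals(treated.index) or not untreated.columns.equals(treated.columns):
        raise ValueError("untreated and treated tables must share index and columns")
    if significant is None:
        significant = pd.DataFrame(True, index=untreated.index, columns=untreated.columns)
    exclusion = dict(DEFAULT_EXCLUSION) | dict(exclusion or {})

    u = untreated.to_numpy(dtype=float)
    if (u <= 0).any():
        raise ValueError("untreated levels must be > 0 for rescue to be defined")
    rescue = 100.0 * (untreated - treated) / untreated

    averages: dict[str, float] = {}
    for marker in untreated.columns:
        averages[str(marker)] = marker_average(
            rescue[marker].tolist(),
            exclusion=exclusion.get(str(marker), "none"),
            significant=significant[marker].tolist(),
        )
    comp = composite_score(list(averages.values()))
    return RescueTable(
        rescue=rescue, significant=significant.copy(), marker_averages=averages, composite=comp
    )
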