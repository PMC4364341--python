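"""Reductions of raw functional measurements to trial endpoints.

Covers the torque-to-force conversion through the estimated paw moment
arm, body-mass correction, the eccentric-contraction force deficit, group
percent change, and the circumference-per-mass hypertrophy index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MOMENT_ARM_FRACTION",
    "EccentricSeries",
    "torque_to_force",
    "force_to_torque",
    "mass_correct",
    "force_deficit",
    "percent_change",
    "cs_circumference_index",
    "group_summary",
]

#: The paw's contact point on the lever, as a fraction of the
#: hock-to-distal-digit distance.
MOMENT_ARM_FRACTION = 0.75


def torque_to_force(torque: float, hock_to_digit_distance: float) -> float:
    """Convert joint torque (N*m) to force (N) via the estimated moment arm.

    The moment arm is 75% of the hock-to-digit distance (m):
    ``force = torque / (0.75 * distance)``.
    """
    if hock_to_digit_distance <= 0:
        raise ValueError("hock_to_digit_distance must be > 0")
    return torque / (MOMENT_ARM_FRACTION * hock_to_digit_distance)


def force_to_torque(force: float, hock_to_digit_distance: float) -> float:
    """Inverse of :func:`torque_to_force`."""
    if hock_to_digit_distance <= 0:
        raise ValueError("hock_to_digit_distance must be > 0")
    return force * MOMENT_ARM_FRACTION * hock_to_digit_distance


def mass_correct(value: float, body_mass: float) -> float:
    """Body-mass correction: value (N or N*m) divided by mass (kg)."""
    if body_mass <= 0:
        raise ValueError("body_mass must be > 0")
    return value / body_mass


@dataclass
class EccentricSeries:
    """Maximal isometric tetanic force Po indexed by stretch number.

    Index 0 is the pre-stretch value. The standard protocol is 3 sets of
    10 stretches (4 min between sets), each stretch at 0.7 Lo/s to 107%
    of the optimal length Lo; those parameters are carried as metadata
    only.
    """

    po: Sequence[float]
    stretch_rate_lo_per_s: float = 0.7
    stretch_to_percent_lo: float = 107.0
    sets: int = 3
    stretches_per_set: int = 10
    inter_set_rest_min: float = 4.0

    def __post_init__(self) -> None:
        self.po = np.asarray(self.po, dtype=float)
        if self.po.size < 2:
            raise ValueError("need at least a pre-stretch and one post-stretch Po")
        if np.any(self.po < 0):
            raise ValueError("Po values must be >= 0")


def force_deficit(series: EccentricSeries, through_stretch: int) -> float:
    """Percent force deficit after ``through_stretch`` lengthening contractions.

    ``Fd = 100 * (Po[0] - Po[through_stretch]) / Po[0]``. A negative value
    (post-stretch potentiation) is returned unclamped.
    """
    po = series.po
    if not 1 <= through_stretch < po.size:
        raise ValueError(f"through_stretch {through_stretch} not present in series")
    if po[0] <= 0:
        raise ValueError("pre-stretch Po must be > 0")
    return float(100.0 * (po[0] - po[through_stretch]) / po[0])


def ecd_1_10(series: EccentricSeries) -> float:
    """Force deficit after the first set of 10 stretches."""
    return force_deficit(series, 10)


def ecd_1_30(series: EccentricSeries) -> float:
    """Force deficit after all 30 stretches."""
    return force_deficit(series, 30)


def percent_change(reference_mean: float, comparison_mean: float) -> float:
    """``100 * (comparison - reference) / reference``."""
    if reference_mean == 0:
        raise ValueError("reference_mean must be nonzero")
    return float(100.0 * (comparison_mean - reference_mean) / reference_mean)


def cs_circumference_index(replicate_lengths_mm: Sequence[float], body_mass: float) -> float:
    """Muscle-belly circumference index: mean replicate length (mm) / mass (kg)."""
    lengths = np.asarray(replicate_lengths_mm, dtype=float)
    if lengths.size == 0:
        raise ValueError("need at least one replicate length")
    if np.any(lengths <= 0):
        raise ValueError("lengths must be > 0")
    if body_mass <= 0:
        raise ValueError("body_mass must be > 0")
    return float(lengths.mean() / body_mass)


def group_summary(
    cohort: pd.DataFrame, variables: Sequence[str] | None = None, group_col: str = "group"
) -> pd.DataFrame:
    """Per-group mean, sd, and n for each endpoint (long format).

    Sample sd (ddof=1); groups of size 1 report sd 0.
    """
    if group_col not in cohort.columns:
        raise KeyError(f"column {group_col!r} not in cohort table")
    if variables is None:
        variables = [
            c for c in cohort.columns
            if c not in (group_col, "animal_id") and pd.api.types.is_numeric_dtype(cohort[c])
        ]
    rows = []
    for group, sub in cohort.groupby(group_col, sort=False):
        for var in variables:
            vals = sub[var].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            rows.append(
                {
                    "group": group,
                    "variable": var,
                    "n": int(vals.size),
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)
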