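"""Seeded synthetic inputs for the full pipeline.

Three generators, all deterministic given (spec, seed):

* :func:`generate_phantom` — a multi-echo magnitude volume plus integer
  label map. Each muscle is an axis-aligned box of the requested volume
  fraction; lesions are spherical patches of elevated T2 placed uniformly
  inside the muscle until a voxel budget is met; every voxel decays
  mono-exponentially with additive Gaussian noise.
* :func:`generate_cohort` — per-animal functional/morphometric records for
  a four-group (two genotypes x two treatments) design with per-group
  normal distributions.
* :func:`generate_histo_counts` — paired untreated/treated per-muscle,
  per-marker histology levels around programmed group means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from myotex._rng import named_rng
from myotex.t2_mapping import MultiEchoVolume
from myotex.texture_analysis import LabelMap

__all__ = [
    "MuscleSpec",
    "PhantomSpec",
    "CohortSpec",
    "GROUPS",
    "generate_phantom",
    "generate_cohort",
    "generate_histo_counts",
    "treated_means_from_rescue",
]

GROUPS = ("WT", "WT+NBD", "GRMD", "GRMD+NBD")

#: Variables that are physically strictly positive; negative draws redrawn.
POSITIVE_VARIABLES = frozenset(
    {"body_mass", "flexion_force", "extension_force", "flexion_torque",
     "extension_torque", "cs_circumference"}
)


@dataclass
class MuscleSpec:
    """One synthetic muscle: label id, name, grid volume fraction, baseline T2."""

    label: int
    name: str
    volume_fraction: float
    baseline_t2: float

    def __post_init__(self) -> None:
        if self.label <= 0:
            raise ValueError("muscle label must be a positive integer")
        if not 0 < self.volume_fraction < 1:
            raise ValueError("volume_fraction must be in (0, 1)")
        if self.baseline_t2 <= 0:
            raise ValueError("baseline_t2 must be > 0")


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    muscles: Sequence[MuscleSpec] = field(
        default_factory=lambda: (
            MuscleSpec(1, "muscle_a", 0.18, 45.0),
            MuscleSpec(2, "muscle_b", 0.18, 40.0),
        )
    )
    lesion_fraction: float = 0.0
    lesion_t2_shift: float = 30.0
    lesion_patch_radius: int = 2
    echo_times: Sequence[float] = field(default_factory=lambda: tuple(np.arange(10.0, 101.0, 10.0)))
    s0: float = 1000.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.grid_shape) or len(self.grid_shape) != 3:
            raise ValueError("grid_shape must be three positive integers")
        if not 0.0 <= self.lesion_fraction <= 1.0:
            raise ValueError("lesion_fraction must be in [0, 1]")
        te = np.asarray(self.echo_times, dtype=float)
        if te.size < 2 or np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ValueError("echo_times must be >= 2 values, positive, strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.lesion_patch_radius < 1:
            raise ValueError("lesion_patch_radius must be >= 1")
        if sum(m.volume_fraction for m in self.muscles) >= 1.0:
            raise ValueError("muscle volume fractions must sum to < 1")
        labels = [m.label for m in self.muscles]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate muscle labels")


def _muscle_boxes(spec: PhantomSpec) -> dict[int, tuple[slice, slice, slice]]:
    """Lay muscles out as non-overlapping axis-aligned boxes, one slab each
    along x, sized to approximate the requested volume fraction."""
    nx, ny, nz = spec.grid_shape
    n = len(spec.muscles)
    total_vox = nx * ny * nz
    slab = nx // n
    boxes: dict[int, tuple[slice, slice, slice]] = {}
    for i, m in enumerate(spec.muscles):
        x0, x1 = i * slab, (i + 1) * slab if i < n - 1 else nx
        target = m.volume_fraction * total_vox
        dx = x1 - x0
        # square cross-section as close to the target count as the grid allows
        side = int(np.floor(np.sqrt(target / dx)))
        side = max(1, min(side, ny - 2, nz - 2))
        y0 = (ny - side) // 2
        z0 = (nz - side) // 2
        boxes[m.label] = (slice(x0 + 1, x1 - 1 if dx > 2 else x1),
                          slice(y0, y0 + side), slice(z0, z0 + side))
    return boxes


def _ball_offsets(radius: int) -> np.ndarray:
    r = int(radius)
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= r**2
    return np.stack([dx[keep], dy[keep], dz[keep]], axis=1)


def _place_lesions(
    muscle_mask: np.ndarray, name: str, fraction: float, radius: int, rng: np.random.Generator
) -> np.ndarray:
    """Non-overlapping spherical patches until ~fraction of the muscle is covered."""
    lesion = np.zeros_like(muscle_mask)
    if fraction <= 0:
        return lesion
    coords = np.argwhere(muscle_mask)
    extents = coords.max(axis=0) - coords.min(axis=0) + 1
    if 2 * radius + 1 > extents.min():
        raise ValueError(
            f"lesion_patch_radius {radius} exceeds the extent of muscle {name!r} "
            f"(bounding box {tuple(int(e) for e in extents)})"
        )
    budget = int(round(fraction * muscle_mask.sum()))
    offsets = _ball_offsets(radius)
    shape = muscle_mask.shape
    covered = 0
    attempts = 0
    max_attempts = 200 * max(budget, 1)
    while covered < budget and attempts < max_attempts:
        attempts += 1
        centre = coords[rng.integers(coords.shape[0])]
        pts = centre + offsets
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        pts = pts[ok]
        inside = muscle_mask[pts[:, 0], pts[:, 1], pts[:, 2]]
        pts = pts[inside]
        if lesion[pts[:, 0], pts[:, 1], pts[:, 2]].any():
            continue  # no overlap between patches
        lesion[pts[:, 0], pts[:, 1], pts[:, 2]] = True
        covered += pts.shape[0]
    return lesion


def generate_phantom(spec: PhantomSpec) -> tuple[MultiEchoVolume, LabelMap]:
    """Build a multi-echo phantom and its label map from ``spec``.

    Voxel signal is ``S0 * exp(-TE / T2)`` plus Gaussian noise; lesion
    voxels carry ``baseline_t2 + lesion_t2_shift``. Identical spec and
    seed yield bit-identical arrays.
    """
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    t2 = np.zeros(spec.grid_shape, dtype=float)
    boxes = _muscle_boxes(spec)
    for m in spec.muscles:
        box = boxes[m.label]
        if labels[box].any():
            raise ValueError("muscle boxes overlap; reduce volume fractions")
        labels[box] = m.label
        t2[box] = m.baseline_t2

    lesion_rng = named_rng(spec.seed, "phantom.lesions")
    lesion_mask = np.zeros(spec.grid_shape, dtype=bool)
    for m in spec.muscles:
        mm = labels == m.label
        lm = _place_lesions(mm, m.name, spec.lesion_fraction, spec.lesion_patch_radius, lesion_rng)
        lesion_mask |= lm
    t2[lesion_mask] += spec.lesion_t2_shift

    te = np.asarray(spec.echo_times, dtype=float)
    signal = np.zeros(spec.grid_shape + (te.size,))
    in_mask = labels > 0
    with np.errstate(divide="ignore"):
        decay = np.exp(-te[None, :] / t2[in_mask][:, None])
    signal[in_mask] = spec.s0 * decay
    if spec.noise_sd > 0:
        noise_rng = named_rng(spec.seed, "phantom.noise")
        signal = signal + noise_rng.normal(0.0, spec.noise_sd, size=signal.shape)

    vol = MultiEchoVolume(data=signal, echo_times=te, voxel_size=spec.voxel_size)
    lmap = LabelMap(
        labels=labels, names={m.label: m.name for m in spec.muscles}, voxel_size=spec.voxel_size
    )
    return vol, lmap


@dataclass
class CohortSpec:
    """Group sizes and per-variable (mean, sd) for each of the four groups."""

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"WT": 8, "WT+NBD": 3, "GRMD": 10, "GRMD+NBD": 6}
    )
    variables: Mapping[str, Mapping[str, tuple[float, float]]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}; expected one of {GROUPS}")
            if n < 1:
                raise ValueError(f"group {g!r} must have n >= 1")
        for var, per_group in self.variables.items():
            for g, (mean, sd) in per_group.items():
                if g not in self.n_per_group:
                    raise ValueError(f"variable {var!r} references unknown group {g!r}")
                if sd < 0:
                    raise ValueError(f"variable {var!r}, group {g!r}: sd must be >= 0")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """One row per animal with group label and normally drawn variables.

    Negative draws for strictly positive variables (mass, forces, torques,
    circumference) are redrawn; the total redraw count is reported in
    ``df.attrs['n_redraws']``.
    """
    rng = named_rng(spec.seed, "cohort")
    rows = []
    n_redraws = 0
    for group in GROUPS:
        if group not in spec.n_per_group:
            continue
        for i in range(spec.n_per_group[group]):
            row: dict = {"animal_id": f"{group}-{i + 1:02d}", "group": group}
            for var, per_group in spec.variables.items():
                if group not in per_group:
                    row[var] = np.nan
                    continue
                mean, sd = per_group[group]
                value = rng.normal(mean, sd) if sd > 0 else float(mean)
                if var in POSITIVE_VARIABLES:
                    while value <= 0:
                        n_redraws += 1
                        value = rng.normal(mean, sd)
                row[var] = float(value)
            rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["n_redraws"] = n_redraws
    return df


def treated_means_from_rescue(untreated: pd.DataFrame, rescue_percent: pd.DataFrame) -> pd.DataFrame:
    """Treated group means implied by untreated means and percent rescue R:
    ``treated = (1 - R/100) * untreated``."""
    if not untreated.index.equals(rescue_percent.index) or not untreated.columns.equals(
        rescue_percent.columns
    ):
        raise ValueError("untreated and rescue tables must share index and columns")
    return untreated * (1.0 - rescue_percent / 100.0)


def generate_histo_counts(
    untreated_means: pd.DataFrame,
    treated_means: pd.DataFrame,
    dispersion: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-muscle, per-marker histology levels for the two groups.

    ``dispersion`` is a coefficient of variation: each cell is drawn from
    Normal(mean, dispersion * mean), negatives redrawn; dispersion 0
    reproduces the means exactly.
    """
    for df, which in ((untreated_means, "untreated"), (treated_means, "treated")):
        if (df.to_numpy(dtype=float) < 0).any():
            raise ValueError(f"{which} means must be >= 0")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = named_rng(seed, "histo")

    def draw(means: pd.DataFrame) -> pd.DataFrame:
        m = means.to_numpy(dtype=float)
        if dispersion == 0:
            return means.astype(float).copy()
        out = rng.normal(m, dispersion * m)
        bad = out < 0
        while bad.any():
            out[bad] = rng.normal(m[bad], dispersion * m[bad])
            bad = out < 0
        return pd.DataFrame(out, index=means.index, columns=means.columns)

    return draw(untreated_means), draw(treated_means)
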