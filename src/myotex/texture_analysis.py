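"""Per-muscle MRI biomarkers from a T2 map and an integer label map.

Features: muscle volume, mean T2, first-order histogram entropy, and two
3D gray-level run-length features — short run emphasis (here called the
small-lesion index, SLI) and run-length non-uniformity (the heterogeneity
index, HI) — plus a proportional-volume-weighted composite across muscles.

A gray-level run is a maximal set of consecutive voxels with the same
quantized level along a direction, confined to the region of interest:
runs break at mask and volume boundaries and never bridge background.
Features are averaged, unweighted, over the 13 unique 3D directions
(the 26-neighbourhood modulo sign).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from myotex.t2_mapping import T2Map

__all__ = [
    "DIRECTIONS_13",
    "LabelMap",
    "RunLengthMatrix",
    "TextureConfig",
    "quantize",
    "run_length_matrix",
    "sli",
    "hi",
    "histogram_entropy",
    "muscle_features",
    "weighted_composite",
]

#: The 13 unique offsets of the 3D 26-neighbourhood (one per +/- pair).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)


@dataclass
class LabelMap:
    """Integer muscle labels (0 = background) with names and voxel size."""

    labels: np.ndarray
    names: dict[int, str]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if np.any(self.labels < 0):
            raise ValueError("labels must be >= 0")
        present = set(np.unique(self.labels)) - {0}
        unnamed = present - set(self.names)
        if unnamed:
            raise ValueError(f"labels without a name: {sorted(unnamed)}")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class RunLengthMatrix:
    """Run counts indexed by (gray level i=1..G, run length j=1..Jmax)."""

    counts: np.ndarray
    direction: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2D (level x run length)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_runs(self) -> int:
        return int(self.counts.sum())

    @property
    def n_voxels(self) -> int:
        j = np.arange(1, self.counts.shape[1] + 1)
        return int((self.counts.sum(axis=0) * j).sum())


@dataclass
class TextureConfig:
    """Knobs for per-muscle feature extraction."""

    n_levels: int = 16
    binning: Literal["roi_minmax", "fixed_range"] = "roi_minmax"
    fixed_range: tuple[float, float] | None = None
    directions: Sequence[tuple[int, int, int]] = DIRECTIONS_13
    n_slices: int | None = 5  # central slab along slab_axis; None = whole muscle
    slab_axis: int = 2

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.binning == "fixed_range" and self.fixed_range is None:
            raise ValueError("fixed_range binning requires a (lo, hi) range")


def quantize(
    t2map: T2Map | np.ndarray,
    mask: np.ndarray,
    n_levels: int,
    binning: Literal["roi_minmax", "fixed_range"] = "roi_minmax",
    fixed_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Quantize ROI intensities to integer levels 1..G (0 outside the mask).

    ``roi_minmax`` maps [min, max] over the mask onto G equal-width bins
    with the maximum value assigned level G; the bin width realises the
    run-length similarity range.
    """
    values = t2map.t2 if isinstance(t2map, T2Map) else np.asarray(t2map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if not mask.any():
        raise ValueError("mask is empty")
    if isinstance(t2map, T2Map) and not np.all(t2map.valid_mask[mask]):
        raise ValueError("mask contains voxels where the T2 fit is invalid")

    roi = values[mask]
    if binning == "roi_minmax":
        lo, hi = float(roi.min()), float(roi.max())
    elif binning == "fixed_range":
        if fixed_range is None:
            raise ValueError("fixed_range binning requires a (lo, hi) range")
        lo, hi = map(float, fixed_range)
        if hi <= lo:
            raise ValueError("fixed_range must satisfy lo < hi")
    else:
        raise ValueError(f"unknown binning {binning!r}")

    out = np.zeros(values.shape, dtype=np.int32)
    if hi == lo:
        warnings.warn("constant ROI: all voxels assigned level 1 (degenerate texture)", stacklevel=2)
        out[mask] = 1
        return out
    levels = np.floor((roi - lo) / (hi - lo) * n_levels).astype(np.int32) + 1
    out[mask] = np.clip(levels, 1, n_levels)
    return out


def _shift(a: np.ndarray, d: tuple[int, int, int], fill) -> np.ndarray:
    """Return s with s[v] = a[v + d] (fill where v + d is out of bounds)."""
    out = np.full_like(a, fill)
    src = tuple(slice(max(di, 0), a.shape[i] + min(di, 0)) for i, di in enumerate(d))
    dst = tuple(slice(max(-di, 0), a.shape[i] + min(-di, 0)) for i, di in enumerate(d))
    out[dst] = a[src]
    return out


def run_length_matrix(
    q: np.ndarray, mask: np.ndarray, direction: tuple[int, int, int]
) -> RunLengthMatrix:
    """Count maximal in-mask runs of equal quantized level along a direction.

    Runs break at mask and volume boundaries; ``counts[i-1, j-1]`` is the
    number of runs of level i with length j.
    """
    q = np.asarray(q)
    mask = np.asarray(mask, dtype=bool)
    if q.ndim != 3 or q.shape != mask.shape:
        raise ValueError("q and mask must be 3D arrays of equal shape")
    d = tuple(int(c) for c in direction)
    if d == (0, 0, 0) or any(c not in (-1, 0, 1) for c in d):
        raise ValueError("direction components must be in {-1, 0, 1}, not all zero")
    if not mask.any():
        raise ValueError("mask is empty")

    # cont[v]: the run through v continues at v + d
    mask_next = _shift(mask, d, False)
    q_next = _shift(q, d, 0)
    cont = mask & mask_next & (q == q_next)

    # start[v]: v is the first voxel of its run (no continuation from v - d)
    back = tuple(-c for c in d)
    cont_prev = _shift(cont, back, False)
    start = mask & ~cont_prev

    # run length by dynamic programming along layers of constant v . d,
    # processed so that v + d is always resolved before v
    idx = np.indices(q.shape)
    t = sum(idx[i] * d[i] for i in range(3))
    length = np.zeros(q.shape, dtype=np.int64)
    for tv in np.unique(t)[::-1]:
        layer = np.nonzero(t == tv)
        lx, ly, lz = layer
        nxt = (lx + d[0], ly + d[1], lz + d[2])
        has_next = cont[layer]
        nxt_len = np.zeros(lx.size, dtype=np.int64)
        if has_next.any():
            sel = np.nonzero(has_next)[0]
            nxt_len[sel] = length[nxt[0][sel], nxt[1][sel], nxt[2][sel]]
        length[layer] = np.where(mask[layer], 1 + nxt_len, 0)

    levels = q[start]
    lens = length[start]
    if levels.size == 0:
        counts = np.zeros((1, 1), dtype=np.int64)
    else:
        g_max = int(levels.max())
        j_max = int(lens.max())
        counts = np.zeros((g_max, j_max), dtype=np.int64)
        np.add.at(counts, (levels - 1, lens - 1), 1)
    return RunLengthMatrix(counts=counts, direction=d)


def _as_rlm_list(rlms: RunLengthMatrix | Iterable[RunLengthMatrix]) -> list[RunLengthMatrix]:
    out = [rlms] if isinstance(rlms, RunLengthMatrix) else list(rlms)
    if not out:
        raise ValueError("need at least one run-length matrix")
    for m in out:
        if m.n_runs < 1:
            raise ValueError("run-length matrix with zero runs")
    return out


def sli(rlms: RunLengthMatrix | Iterable[RunLengthMatrix]) -> float:
    """Short run emphasis (small-lesion index), averaged over directions.

    Per matrix: ``(1/N_r) * sum_ij counts(i, j) / j**2`` — in (0, 1], equal
    to 1 exactly when every run has length 1.
    """
    vals = []
    for m in _as_rlm_list(rlms):
        j = np.arange(1, m.counts.shape[1] + 1, dtype=float)
        vals.append(float((m.counts.sum(axis=0) / j**2).sum() / m.n_runs))
    return float(np.mean(vals))


def hi(rlms: RunLengthMatrix | Iterable[RunLengthMatrix]) -> float:
    """Run-length non-uniformity (heterogeneity index), averaged over directions.

    Per matrix: ``(1/N_r) * sum_j (sum_i counts(i, j))**2`` — large when run
    counts concentrate at few lengths; bounded by [1, N_r].
    """
    vals = []
    for m in _as_rlm_list(rlms):
        per_len = m.counts.sum(axis=0).astype(float)
        vals.append(float((per_len**2).sum() / m.n_runs))
    return float(np.mean(vals))


def histogram_entropy(
    t2map: T2Map | np.ndarray,
    mask: np.ndarray,
    n_levels: int = 16,
    binning: Literal["roi_minmax", "fixed_range"] = "roi_minmax",
    fixed_range: tuple[float, float] | None = None,
) -> float:
    """First-order histogram entropy in bits over the quantized ROI."""
    q = quantize(t2map, mask, n_levels, binning, fixed_range)
    levels = q[np.asarray(mask, dtype=bool)]
    counts = np.bincount(levels)[1:]
    f = counts[counts > 0] / levels.size
    return float(-(f * np.log2(f)).sum())


def _central_slab(mask: np.ndarray, axis: int, n_slices: int) -> np.ndarray:
    """Restrict a mask to the n central slices along ``axis`` (ROI centroid)."""
    coords = np.nonzero(mask)[axis]
    centre = int(round(float(coords.mean())))
    half = n_slices // 2
    lo = max(centre - half, int(coords.min()))
    hi_ = lo + n_slices - 1
    sel = np.zeros(mask.shape[axis], dtype=bool)
    sel[max(lo, 0) : hi_ + 1] = True
    shape = [1, 1, 1]
    shape[axis] = mask.shape[axis]
    return mask & sel.reshape(shape)


def muscle_features(
    t2map: T2Map,
    labelmap: LabelMap,
    config: TextureConfig | None = None,
    animal_id: str | None = None,
    group: str | None = None,
) -> pd.DataFrame:
    """Per-muscle volume, mean T2, entropy, SLI, and HI.

    Volume and mean T2 use the whole muscle; entropy and run-length
    features are computed on the configured slab (default: the 5 central
    slices along the through-plane axis, by ROI centroid). Muscles whose
    label is absent yield a row flagged ``missing`` rather than being
    dropped.
    """
    config = config or TextureConfig()
    rows = []
    for label, name in sorted(labelmap.names.items()):
        row: dict = {"label": label, "muscle": name, "missing": False}
        if animal_id is not None:
            row["animal_id"] = animal_id
        if group is not None:
            row["group"] = group
        mask = labelmap.mask(label) & t2map.valid_mask
        if not mask.any():
            row.update(
                missing=True, n_voxels=0, volume_mm3=0.0,
                mean_t2=np.nan, entropy=np.nan, sli=np.nan, hi=np.nan,
            )
            rows.append(row)
            continue
        n_vox = int(mask.sum())
        row["n_voxels"] = n_vox
        row["volume_mm3"] = n_vox * labelmap.voxel_volume
        row["mean_t2"] = float(t2map.t2[mask].mean())

        slab = mask
        if config.n_slices is not None:
            slab = _central_slab(mask, config.slab_axis, config.n_slices)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant-ROI degeneracy handled below
            q = quantize(t2map, slab, config.n_levels, config.binning, config.fixed_range)
        rlms = [run_length_matrix(q, slab, d) for d in config.directions]
        row["sli"] = sli(rlms)
        row["hi"] = hi(rlms)
        levels = q[slab]
        counts = np.bincount(levels)[1:]
        f = counts[counts > 0] / levels.size
        row["entropy"] = float(-(f * np.log2(f)).sum())
        rows.append(row)
    df = pd.DataFrame(rows)
    front = [c for c in ("animal_id", "group") if c in df.columns]
    order = front + ["label", "muscle", "n_voxels", "volume_mm3", "mean_t2", "entropy", "sli", "hi", "missing"]
    return df[order]


def weighted_composite(table: pd.DataFrame, feature: str) -> float:
    """Proportional-volume-weighted average of a per-muscle feature.

    Weights are each muscle's volume divided by the total; missing muscles
    (or NaN feature values) are excluded and the weights renormalised.
    """
    if feature not in table.columns:
        raise KeyError(f"feature {feature!r} not in table")
    keep = (~table["missing"]) & table[feature].notna() & (table["volume_mm3"] > 0)
    sub = table[keep]
    total = sub["volume_mm3"].sum()
    if total <= 0:
        raise ValueError("all muscle volumes are zero")
    w = sub["volume_mm3"] / total
    return float((w * sub[feature]).sum())
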