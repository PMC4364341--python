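"""Per-voxel T2 mapping from a multi-echo spin-echo series.

The signal model is a mono-exponential decay ``S(TE) = S0 * exp(-TE/T2)``.
The default fit is log-linear (ordinary least squares of ln S against TE);
a nonlinear refinement on the exponential model is available and is
initialised from the log-linear solution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = ["MultiEchoVolume", "T2Map", "fit_t2"]


@dataclass
class MultiEchoVolume:
    """A 4D magnitude image (x, y, z, echo) with its echo times in ms."""

    data: np.ndarray
    echo_times: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D (x, y, z, echo), got ndim={self.data.ndim}")
        if self.echo_times.ndim != 1 or self.echo_times.size != self.data.shape[3]:
            raise ValueError("echo_times length must equal the echo axis length")
        if self.echo_times.size < 2:
            raise ValueError("need at least 2 echoes")
        if np.any(self.echo_times <= 0) or np.any(np.diff(self.echo_times) <= 0):
            raise ValueError("echo_times must be positive and strictly increasing")

    @property
    def n_echoes(self) -> int:
        return int(self.echo_times.size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class T2Map:
    """Voxelwise fit results: T2 (ms), S0, fit quality, and validity."""

    t2: np.ndarray
    s0: np.ndarray
    r2_of_fit: np.ndarray
    valid_mask: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_negative_voxels: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        if not (self.t2.shape == self.s0.shape == self.r2_of_fit.shape == self.valid_mask.shape):
            raise ValueError("all component volumes must share one shape")


def _log_linear(signals: np.ndarray, tes: np.ndarray) -> tuple[np.ndarray, ...]:
    """OLS of ln S on TE for a (n_vox, n_echo) block of positive signals."""
    y = np.log(signals)
    x = tes - tes.mean()
    sxx = float(np.sum(x * x))
    ybar = y.mean(axis=1, keepdims=True)
    slope = (y - ybar) @ x / sxx
    intercept = ybar[:, 0] - slope * tes.mean()
    resid = y - (intercept[:, None] + slope[:, None] * tes)
    ss_res = np.sum(resid**2, axis=1)
    ss_tot = np.sum((y - ybar) ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
    return slope, intercept, r2


def _nonlinear_refine(
    signals: np.ndarray, tes: np.ndarray, t2_init: np.ndarray, s0_init: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Levenberg-style least squares on S0*exp(-TE/T2), one voxel at a time."""
    n = signals.shape[0]
    t2 = np.empty(n)
    s0 = np.empty(n)
    r2 = np.empty(n)
    for i in range(n):
        sig = signals[i]

        def resid(p: np.ndarray, sig: np.ndarray = sig) -> np.ndarray:
            return p[0] * np.exp(-tes / p[1]) - sig

        x0 = np.array([max(s0_init[i], 1e-12), max(t2_init[i], 1e-6)])
        sol = least_squares(resid, x0, bounds=([0.0, 1e-9], [np.inf, np.inf]))
        s0[i], t2[i] = sol.x
        ss_res = float(np.sum(sol.fun**2))
        ss_tot = float(np.sum((sig - sig.mean()) ** 2))
        r2[i] = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return t2, s0, r2


def fit_t2(
    vol: MultiEchoVolume,
    method: Literal["log_linear", "nonlinear"] = "log_linear",
    min_signal: float = 0.0,
    drop_first_echo: bool = False,
    mask: np.ndarray | None = None,
) -> T2Map:
    """Fit the mono-exponential decay model voxelwise.

    Parameters
    ----------
    vol:
        Multi-echo magnitude volume.
    method:
        ``log_linear`` fits ln S against TE by OLS (T2 = -1/slope,
        S0 = exp(intercept)); ``nonlinear`` refines that solution by least
        squares on the exponential model itself.
    min_signal:
        Voxels with any echo below this level are masked invalid.
    drop_first_echo:
        Discard the first echo before fitting (CPMG first echoes can be
        biased by imperfect refocusing).
    mask:
        Optional 3D boolean restriction; voxels outside are left invalid.

    Returns
    -------
    T2Map
        ``valid_mask`` is False wherever the fit failed (signal below
        ``min_signal``, nonpositive signal, or nonnegative slope).

    Raises
    ------
    ValueError
        If every voxel is invalid.
    """
    if min_signal < 0:
        raise ValueError("min_signal must be >= 0")
    data = vol.data
    tes = vol.echo_times
    if drop_first_echo:
        if tes.size < 3:
            raise ValueError("need at least 3 echoes to drop the first")
        data = data[..., 1:]
        tes = tes[1:]

    shape = data.shape[:3]
    flat = data.reshape(-1, tes.size)

    candidate = np.ones(flat.shape[0], dtype=bool)
    if mask is not None:
        candidate &= np.asarray(mask, dtype=bool).reshape(-1)

    negative = np.any(flat < 0, axis=1)
    n_negative = int(np.count_nonzero(negative & candidate))
    if n_negative:
        warnings.warn(f"{n_negative} voxel(s) with negative signal masked invalid", stacklevel=2)

    usable = candidate & ~negative & np.all(flat > 0, axis=1) & np.all(flat >= min_signal, axis=1)

    t2 = np.zeros(flat.shape[0])
    s0 = np.zeros(flat.shape[0])
    r2 = np.zeros(flat.shape[0])
    valid = np.zeros(flat.shape[0], dtype=bool)

    if np.any(usable):
        slope, intercept, r2_ll = _log_linear(flat[usable], tes)
        decaying = slope < 0
        t2_ll = np.where(decaying, -1.0 / np.where(decaying, slope, -1.0), 0.0)
        s0_ll = np.exp(intercept)
        if method == "log_linear":
            t2_fit, s0_fit, r2_fit, ok = t2_ll, s0_ll, r2_ll, decaying
        elif method == "nonlinear":
            idx = np.nonzero(decaying)[0]
            t2_fit = t2_ll.copy()
            s0_fit = s0_ll.copy()
            r2_fit = r2_ll.copy()
            if idx.size:
                t2_nl, s0_nl, r2_nl = _nonlinear_refine(
                    flat[usable][idx], tes, t2_ll[idx], s0_ll[idx]
                )
                t2_fit[idx], s0_fit[idx], r2_fit[idx] = t2_nl, s0_nl, r2_nl
            ok = decaying
        else:
            raise ValueError(f"unknown method {method!r}")
        sub_valid = ok & (t2_fit > 0)
        t2[usable] = np.where(sub_valid, t2_fit, 0.0)
        s0[usable] = np.where(sub_valid, s0_fit, 0.0)
        r2[usable] = np.where(sub_valid, r2_fit, 0.0)
        valid[usable] = sub_valid

    if not np.any(valid):
        raise ValueError("T2 fit failed for every voxel")

    return T2Map(
        t2=t2.reshape(shape),
        s0=s0.reshape(shape),
        r2_of_fit=r2.reshape(shape),
        valid_mask=valid.reshape(shape),
        voxel_size=vol.voxel_size,
        n_negative_voxels=n_negative,
    )
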