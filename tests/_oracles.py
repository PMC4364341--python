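"""Independent brute-force oracles used to check the fast implementations.

These deliberately share no code with the package: the run-length oracle
walks voxel by voxel with Python loops, the T2 oracle grid-searches the
sum of squared errors, and the permutation oracle resamples group labels.
"""

from __future__ import annotations

import numpy as np


def rlm_counts_oracle(q: np.ndarray, mask: np.ndarray, d: tuple[int, int, int]) -> dict:
    """Run counts {(level, length): n} by walking every run start explicitly."""
    shape = q.shape

    def inb(v):
        return all(0 <= v[i] < shape[i] for i in range(3))

    counts: dict[tuple[int, int], int] = {}
    for start in np.ndindex(shape):
        if not mask[start]:
            continue
        prev = tuple(start[i] - d[i] for i in range(3))
        if inb(prev) and mask[prev] and q[prev] == q[start]:
            continue  # not the first voxel of its run
        length = 1
        cur = start
        while True:
            nxt = tuple(cur[i] + d[i] for i in range(3))
            if inb(nxt) and mask[nxt] and q[nxt] == q[start]:
                length += 1
                cur = nxt
            else:
                break
        key = (int(q[start]), length)
        counts[key] = counts.get(key, 0) + 1
    return counts


def rlm_to_dict(counts: np.ndarray) -> dict:
    """Convert a (level x length) count matrix to the oracle's dict form."""
    out = {}
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            if counts[i, j]:
                out[(i + 1, j + 1)] = int(counts[i, j])
    return out


def t2_grid_oracle(signals: np.ndarray, tes: np.ndarray, t2_grid: np.ndarray) -> np.ndarray:
    """Per-voxel T2 minimizing SSE over a grid, with S0 optimal per T2.

    For fixed T2, the least-squares S0 is ``sum(S * e) / sum(e^2)`` with
    ``e = exp(-TE / T2)``.
    """
    e = np.exp(-tes[None, :] / t2_grid[:, None])  # (n_grid, n_echo)
    s0_hat = (signals @ e.T) / (e * e).sum(axis=1)  # (n_vox, n_grid)
    sse = ((s0_hat[:, :, None] * e[None, :, :] - signals[:, None, :]) ** 2).sum(axis=2)
    return t2_grid[np.argmin(sse, axis=1)]


def permutation_p_oracle(
    x1: np.ndarray, x2: np.ndarray, n_resamples: int, rng: np.random.Generator
) -> float:
    """Two-sided permutation p-value for the difference in group means."""
    pooled = np.concatenate([x1, x2])
    n1 = x1.size
    observed = abs(x1.mean() - x2.mean())
    count = 0
    for _ in range(n_resamples):
        perm = rng.permutation(pooled)
        count += abs(perm[:n1].mean() - perm[n1:].mean()) >= observed
    return (count + 1) / (n_resamples + 1)
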