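"""Shared proxy-ordered sliding-window primitives (internal)."""

from __future__ import annotations

import numpy as np


def nearest_window_starts(proxy: np.ndarray, w: int) -> np.ndarray:
    """Start index of the size-``w`` nearest-proxy window around each cell.

    ``proxy`` must be sorted ascending.  For each j the returned window
    [s, s+w) contains j and minimizes the largest proxy distance to
    proxy[j]; ties prefer the lower start (stable).
    """
    n = proxy.size
    w = min(w, n)
    starts = np.empty(n, dtype=int)
    s = 0
    for j in range(n):
        s = max(s, j - w + 1, 0)
        while s < min(j, n - w) and proxy[j] - proxy[s] > proxy[s + w] - proxy[j]:
            s += 1
        starts[j] = min(s, n - w)
    return starts


def running_mean(x: np.ndarray, starts: np.ndarray, w: int) -> np.ndarray:
    """Window means of ``x`` (cells on axis 0) at each start index."""
    w = min(w, x.shape[0])
    c = np.cumsum(x, axis=0, dtype=float)
    if x.ndim > 1:
        c = np.vstack([np.zeros((1,) + x.shape[1:]), c])
    else:
        c = np.concatenate([[0.0], c])
    return (c[starts + w] - c[starts]) / w


def windowed_mean_var(x: np.ndarray, starts: np.ndarray, w: int):
    """Per-window mean and unbiased variance for each column of ``x``."""
    w = min(w, x.shape[0])
    mean = running_mean(x, starts, w)
    mean_sq = running_mean(x * x, starts, w)
    var = (mean_sq - mean * mean) * (w / (w - 1))
    return mean, np.clip(var, 0.0, None)
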