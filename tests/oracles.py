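"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: peak detection by
exhaustive scan with textbook prominence/distance definitions, waveform
landmarks by dense numerical scanning of a high-rate rendering, and the
restricted likelihood by direct dense linear algebra on the full
covariance matrix.
"""

from __future__ import annotations

import numpy as np


def scan_peaks(f: np.ndarray, prominence: float, distance: int) -> np.ndarray:
    """Exhaustive local-maximum scan with prominence and distance pruning.

    Follows the standard definitions: a peak is a sample strictly greater
    than its neighbours (plateaus take their middle sample); its prominence
    is the height above the higher of the two deepest valleys separating it
    from higher terrain; distance pruning keeps higher peaks first.
    """
    n = len(f)
    candidates = []
    i = 1
    while i < n - 1:
        if f[i - 1] < f[i]:
            j = i
            while j < n - 1 and f[j + 1] == f[j]:
                j += 1
            if j < n - 1 and f[j + 1] < f[j]:
                candidates.append((i + j) // 2)
            i = j + 1
        else:
            i += 1

    kept = []
    for p in candidates:
        left_min = f[p]
        k = p - 1
        while k >= 0 and f[k] <= f[p]:
            left_min = min(left_min, f[k])
            k -= 1
        right_min = f[p]
        k = p + 1
        while k < n and f[k] <= f[p]:
            right_min = min(right_min, f[k])
            k += 1
        prom = f[p] - max(left_min, right_min)
        if prom >= prominence:
            kept.append(p)

    # distance pruning: highest first
    kept = sorted(kept, key=lambda p: f[p], reverse=True)
    selected: list[int] = []
    for p in kept:
        if all(abs(p - q) >= distance for q in selected):
            selected.append(p)
    return np.array(sorted(selected), dtype=int)


def dense_landmarks(t: np.ndarray, v: np.ndarray, crossing_frac: float = 0.10):
    """Rise/decay times of the largest pulse in a densely sampled waveform.

    Brute-force: global maximum, then walk outwards to the threshold
    crossings of baseline + crossing_frac * height (baseline = waveform
    minimum).
    """
    base = v.min()
    j = int(np.argmax(v))
    level = base + crossing_frac * (v[j] - base)
    k = j
    while k > 0 and v[k] > level:
        k -= 1
    t_rise = np.interp(level, [v[k], v[k + 1]], [t[k], t[k + 1]])
    k = j
    while k < len(v) - 1 and v[k] > level:
        k += 1
    t_decay = np.interp(level, [v[k], v[k - 1]], [t[k], t[k - 1]])
    return j, t[j] - t_rise, t_decay - t[j]


def dense_reml(theta_d: float, theta_p: float, y, x, z_d, z_p) -> float:
    """Restricted log-likelihood by direct dense linear algebra (no Woodbury).

    Profiles the residual variance; the constant matches the library's
    criterion so values are directly comparable.
    """
    n, p = x.shape
    w = np.eye(n) + theta_d * (z_d @ z_d.T) + theta_p * (z_p @ z_p.T)
    w_inv = np.linalg.inv(w)
    xtwx = x.T @ w_inv @ x
    beta = np.linalg.solve(xtwx, x.T @ w_inv @ y)
    r = y - x @ beta
    sigma2 = float(r @ w_inv @ r) / (n - p)
    return float(
        -0.5
        * (
            (n - p) * (1.0 + np.log(2.0 * np.pi * sigma2))
            + np.linalg.slogdet(w)[1]
            + np.linalg.slogdet(xtwx)[1]
        )
    )


def grid_search_reml(y, x, z_d, z_p, span=(1e-4, 1e3), rounds=6, width=25):
    """Brute-force grid search of the restricted likelihood over the two
    variance ratios, with successive grid refinement."""
    lo_d, hi_d = span
    lo_p, hi_p = span
    best = None
    for _ in range(rounds):
        gd = np.geomspace(lo_d, hi_d, width)
        gp = np.geomspace(lo_p, hi_p, width)
        vals = np.array([[dense_reml(a, b, y, x, z_d, z_p) for b in gp] for a in gd])
        i, j = np.unravel_index(np.argmax(vals), vals.shape)
        best = (gd[i], gp[j], vals[i, j])
        lo_d = gd[max(i - 1, 0)]
        hi_d = gd[min(i + 1, width - 1)]
        lo_p = gp[max(j - 1, 0)]
        hi_p = gp[min(j + 1, width - 1)]
    return best
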