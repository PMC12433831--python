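"""Independent brute-force / closed-form oracles used by the test suite.

Everything here is deliberately naive (loops, enumeration, textbook
formulas) and independent of the implementation paths it checks.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np
import scipy.stats as sps


def flood_fill_components(grid: np.ndarray, connectivity: int) -> list[set[tuple[int, int]]]:
    """Connected components of a binary grid by BFS flood fill."""
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    grid = np.asarray(grid).astype(bool)
    seen = np.zeros_like(grid, dtype=bool)
    comps = []
    rows, cols = grid.shape
    for r in range(rows):
        for c in range(cols):
            if grid[r, c] and not seen[r, c]:
                comp = set()
                q = deque([(r, c)])
                seen[r, c] = True
                while q:
                    cr, cc = q.popleft()
                    comp.add((cr, cc))
                    for dr, dc in nbrs:
                        nr, nc = cr + dr, cc + dc
                        if 0 <= nr < rows and 0 <= nc < cols and grid[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            q.append((nr, nc))
                comps.append(comp)
    return comps


def gaussian_kernel_1d(sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Sampled, normalized 1D Gaussian kernel (matches separable filtering)."""
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def direct_gaussian_response_at_peak(peak_value: float, sigma: float) -> float:
    """Response at an isolated bright pixel = center weight squared x peak."""
    k = gaussian_kernel_1d(sigma)
    center = k[len(k) // 2]
    return peak_value * center * center


def anova_oneway_oracle(groups) -> tuple[float, float]:
    """Textbook one-way ANOVA from sums of squares."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    f = (ss_between / (k - 1)) / (ss_within / (n_total - k))
    return float(f), float(sps.f.sf(f, k - 1, n_total - k))


def pooled_t_oracle(a, b) -> tuple[float, float]:
    """Two-sided pooled-variance Student t."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    df = a.size + b.size - 2
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
    return float(t), float(2 * sps.t.sf(abs(t), df))


def mann_whitney_exact_oracle(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by full enumeration (tie-free data)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n = a.size
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    us = np.array(
        [
            ranks[list(idx)].sum() - n * (n + 1) / 2
            for idx in itertools.combinations(range(pooled.size), n)
        ]
    )
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return float(u_obs), float(min(p, 1.0))


def holm_oracle(pvals) -> np.ndarray:
    """Step-down Holm adjustment, written from the definition."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        val = min((m - rank) * p[idx], 1.0)
        running_max = max(running_max, val)
        adj[idx] = running_max
    return adj
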