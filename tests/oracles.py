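"""Independent brute-force oracles for the interval algebra.

These deliberately avoid the package's sweep-line implementations: interval
sets are rasterized onto a fine grid (0.01 s cells) and operations are
computed by counting cells, or by O(n^2) union-find over pairwise gap
checks.  Fuzz inputs are generated on a 0.5 s lattice so every endpoint,
duration and gap is exactly representable in binary floating point and the
oracle comparison is exact.
"""

from __future__ import annotations

import numpy as np

RES = 0.01  # rasterization cell size in seconds


def _cell(x: float) -> int:
    return int(round(x / RES))


def rasterize(intervals, lo: float, hi: float) -> np.ndarray:
    """Boolean occupancy of [lo, hi) on the fine grid."""
    n = _cell(hi) - _cell(lo)
    grid = np.zeros(n, dtype=bool)
    for s, e in intervals:
        a = max(_cell(s) - _cell(lo), 0)
        b = min(_cell(e) - _cell(lo), n)
        if b > a:
            grid[a:b] = True
    return grid


def oracle_merge_gaps(intervals, max_gap: float) -> list[tuple[float, float]]:
    """Union-find over all pairs: fuse intervals whose gap is strictly < max_gap."""
    ivs = [tuple(iv) for iv in intervals]
    n = len(ivs)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            gap = max(ivs[i][0], ivs[j][0]) - min(ivs[i][1], ivs[j][1])
            if gap < max_gap:  # overlapping pairs have negative gap
                parent[find(i)] = find(j)
    groups: dict[int, list] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(ivs[i])
    out = [
        (min(s for s, _ in grp), max(e for _, e in grp)) for grp in groups.values()
    ]
    return sorted(out)


def oracle_filter(intervals, min_dur: float) -> list[tuple[float, float]]:
    return sorted((s, e) for s, e in intervals if e - s >= min_dur)


def oracle_total_duration(intervals, lo: float, hi: float) -> float:
    return rasterize(intervals, lo, hi).sum() * RES


def oracle_iou(a, b, lo: float, hi: float) -> float:
    ga, gb = rasterize(a, lo, hi), rasterize(b, lo, hi)
    union = int((ga | gb).sum())
    if union == 0:
        return 1.0
    return int((ga & gb).sum()) / union


def oracle_intersect_tracks(a, b, lo: float, hi: float) -> np.ndarray:
    return rasterize(a, lo, hi) & rasterize(b, lo, hi)


def oracle_label_epochs(window, epoch_s: float, intervals) -> np.ndarray:
    """Per-epoch positivity by counting occupied cells inside each epoch."""
    lo, hi = window
    n_epochs = int(np.floor(round((hi - lo) / RES) / round(epoch_s / RES)))
    grid = rasterize(intervals, lo, lo + n_epochs * epoch_s)
    cells_per = _cell(epoch_s)
    return np.array(
        [grid[i * cells_per : (i + 1) * cells_per].any() for i in range(n_epochs)]
    )


def random_track(rng: np.random.Generator, span: float = 120.0, max_n: int = 8):
    """Random raw intervals with endpoints on the exactly-representable 0.5 s lattice."""
    n = int(rng.integers(0, max_n + 1))
    out = []
    for _ in range(n):
        a, b = sorted(rng.integers(0, int(span * 2), size=2))
        if a == b:
            b = a + 1
        out.append((a / 2.0, b / 2.0))
    return out
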