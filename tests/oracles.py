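"""Naive brute-force reference implementations used only by the tests.

Everything here is deliberately written as plain Python loops / flood
fills, independent of the vectorized package code it cross-checks.
"""

from __future__ import annotations

import math

import numpy as np

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def naive_glcm(levels, mask, direction, n_levels=9, distance=1):
    """Symmetric normalized co-occurrence matrix by explicit pair loops."""
    H, W = levels.shape
    dr, dc = (o * distance for o in OFFSETS[direction])
    counts = np.zeros((n_levels, n_levels))
    n_pairs = 0
    for r in range(H):
        for c in range(W):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < H and 0 <= c2 < W and mask[r, c] and mask[r2, c2]:
                counts[levels[r, c], levels[r2, c2]] += 1
                n_pairs += 1
    sym = counts + counts.T
    total = sym.sum()
    return (sym / total if total else sym), n_pairs


def naive_glcm_features(p, n_pairs, n_levels=9):
    """All 21 co-occurrence features via double loops."""
    nan = float("nan")
    names = [
        "autocorrelation", "cluster prominence", "cluster shade",
        "cluster tendency", "contrast", "correlation", "difference entropy",
        "dissimilarity", "energy", "entropy", "homogeneity",
        "inverse difference moment", "inverse difference moment normalized",
        "inverse difference normalized", "inverse variance",
        "max probability", "mean", "sum average", "sum entropy",
        "sum variance", "variance",
    ]
    if n_pairs == 0:
        return {n: nan for n in names}
    L = n_levels
    mu = sum(i * p[i, j] for i in range(L) for j in range(L))
    var = sum((i - mu) ** 2 * p[i, j] for i in range(L) for j in range(L))
    sd = math.sqrt(sum((i - mu) ** 2 * p[i, :].sum() for i in range(L)))
    p_sum = [0.0] * (2 * L - 1)
    p_diff = [0.0] * L
    for i in range(L):
        for j in range(L):
            p_sum[i + j] += p[i, j]
            p_diff[abs(i - j)] += p[i, j]
    sum_avg = sum(k * v for k, v in enumerate(p_sum))
    f = {}
    f["autocorrelation"] = sum(
        i * j * p[i, j] for i in range(L) for j in range(L)
    )
    for power, name in ((4, "cluster prominence"), (3, "cluster shade"),
                        (2, "cluster tendency")):
        f[name] = sum(
            (i + j - 2 * mu) ** power * p[i, j]
            for i in range(L) for j in range(L)
        )
    f["contrast"] = sum(
        (i - j) ** 2 * p[i, j] for i in range(L) for j in range(L)
    )
    if sd > 0:
        f["correlation"] = sum(
            (i - mu) * (j - mu) * p[i, j]
            for i in range(L) for j in range(L)
        ) / (sd * sd)
    else:
        f["correlation"] = nan
    f["difference entropy"] = -sum(
        v * math.log2(v) for v in p_diff if v > 0
    )
    f["dissimilarity"] = sum(
        abs(i - j) * p[i, j] for i in range(L) for j in range(L)
    )
    f["energy"] = sum(p[i, j] ** 2 for i in range(L) for j in range(L))
    f["entropy"] = -sum(
        p[i, j] * math.log2(p[i, j])
        for i in range(L) for j in range(L) if p[i, j] > 0
    )
    f["homogeneity"] = sum(
        p[i, j] / (1 + abs(i - j)) for i in range(L) for j in range(L)
    )
    f["inverse difference moment"] = sum(
        p[i, j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L)
    )
    f["inverse difference moment normalized"] = sum(
        p[i, j] / (1 + ((i - j) / L) ** 2)
        for i in range(L) for j in range(L)
    )
    f["inverse difference normalized"] = sum(
        p[i, j] / (1 + abs(i - j) / L) for i in range(L) for j in range(L)
    )
    f["inverse variance"] = sum(
        p[i, j] / (i - j) ** 2
        for i in range(L) for j in range(L) if i != j
    )
    f["max probability"] = max(
        p[i, j] for i in range(L) for j in range(L)
    )
    f["mean"] = mu
    f["sum average"] = sum_avg
    f["sum entropy"] = -sum(v * math.log2(v) for v in p_sum if v > 0)
    f["sum variance"] = sum(
        (k - sum_avg) ** 2 * v for k, v in enumerate(p_sum)
    )
    f["variance"] = var
    return {n: float(f[n]) for n in names}


def naive_runs(levels, mask, direction):
    """All maximal in-mask runs as (level, length) via pixel-by-pixel walks."""
    H, W = levels.shape
    if direction == 0:
        starts = [((r, 0), (0, 1)) for r in range(H)]
    elif direction == 90:
        starts = [((0, c), (1, 0)) for c in range(W)]
    elif direction == 45:
        # walk along (+1, -1); lines start on the top row and right column
        starts = [((0, c), (1, -1)) for c in range(W)]
        starts += [((r, W - 1), (1, -1)) for r in range(1, H)]
    elif direction == 135:
        starts = [((0, c), (1, 1)) for c in range(W)]
        starts += [((r, 0), (1, 1)) for r in range(1, H)]
    runs = []
    for (r, c), (dr, dc) in starts:
        cur_level, cur_len = None, 0
        while 0 <= r < H and 0 <= c < W:
            if mask[r, c] and levels[r, c] == cur_level:
                cur_len += 1
            else:
                if cur_len:
                    runs.append((cur_level, cur_len))
                if mask[r, c]:
                    cur_level, cur_len = int(levels[r, c]), 1
                else:
                    cur_level, cur_len = None, 0
            r, c = r + dr, c + dc
        if cur_len:
            runs.append((cur_level, cur_len))
    return runs


def naive_glrlm_features(runs, n_pixels):
    nan = float("nan")
    names = [
        "GLNU", "RLN", "run percentage", "short run emphasis",
        "long run emphasis", "low gray level run emphasis",
        "high gray level run emphasis", "short run low gray level emphasis",
        "short run high gray level emphasis",
        "long run low gray level emphasis",
        "long run high gray level emphasis",
    ]
    if not runs:
        return {n: nan for n in names}
    n_r = len(runs)
    per_level: dict[int, int] = {}
    per_length: dict[int, int] = {}
    for lvl, ln in runs:
        per_level[lvl] = per_level.get(lvl, 0) + 1
        per_length[ln] = per_length.get(ln, 0) + 1
    f = {
        "GLNU": sum(v**2 for v in per_level.values()) / n_r,
        "RLN": sum(v**2 for v in per_length.values()) / n_r,
        "run percentage": n_r / n_pixels,
        "short run emphasis": sum(1 / ln**2 for _, ln in runs) / n_r,
        "long run emphasis": sum(ln**2 for _, ln in runs) / n_r,
        "low gray level run emphasis": sum(
            1 / (lvl + 1) ** 2 for lvl, _ in runs
        ) / n_r,
        "high gray level run emphasis": sum(
            (lvl + 1) ** 2 for lvl, _ in runs
        ) / n_r,
        "short run low gray level emphasis": sum(
            1 / ((lvl + 1) ** 2 * ln**2) for lvl, ln in runs
        ) / n_r,
        "short run high gray level emphasis": sum(
            (lvl + 1) ** 2 / ln**2 for lvl, ln in runs
        ) / n_r,
        "long run low gray level emphasis": sum(
            ln**2 / (lvl + 1) ** 2 for lvl, ln in runs
        ) / n_r,
        "long run high gray level emphasis": sum(
            (lvl + 1) ** 2 * ln**2 for lvl, ln in runs
        ) / n_r,
    }
    return {n: float(f[n]) for n in names}


def naive_zones(levels, mask):
    """All maximal 8-connected constant-level zones via flood fill."""
    H, W = levels.shape
    seen = np.zeros((H, W), dtype=bool)
    zones = []
    for r in range(H):
        for c in range(W):
            if not mask[r, c] or seen[r, c]:
                continue
            lvl = int(levels[r, c])
            stack = [(r, c)]
            seen[r, c] = True
            size = 0
            while stack:
                rr, cc = stack.pop()
                size += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        r2, c2 = rr + dr, cc + dc
                        if (
                            0 <= r2 < H and 0 <= c2 < W
                            and mask[r2, c2] and not seen[r2, c2]
                            and int(levels[r2, c2]) == lvl
                        ):
                            seen[r2, c2] = True
                            stack.append((r2, c2))
            zones.append((lvl, size))
    return zones


def naive_glszm_features(zones, n_pixels):
    nan = float("nan")
    names = [
        "Small area emphasis", "Large area emphasis", "Intensity variability",
        "Size zone variability", "Zone percentage", "Low intensity emphasis",
        "High intensity emphasis", "Small area low intensity emphasis",
        "Small area high intensity emphasis",
        "Large area low intensity emphasis",
        "Large area high intensity emphasis",
    ]
    if not zones:
        return {n: nan for n in names}
    n_z = len(zones)
    per_level: dict[int, int] = {}
    per_size: dict[int, int] = {}
    for lvl, s in zones:
        per_level[lvl] = per_level.get(lvl, 0) + 1
        per_size[s] = per_size.get(s, 0) + 1
    f = {
        "Small area emphasis": sum(1 / s**2 for _, s in zones) / n_z,
        "Large area emphasis": sum(s**2 for _, s in zones) / n_z,
        "Intensity variability": sum(
            v**2 for v in per_level.values()
        ) / n_z,
        "Size zone variability": sum(
            v**2 for v in per_size.values()
        ) / n_z,
        "Zone percentage": n_z / n_pixels,
        "Low intensity emphasis": sum(
            1 / (lvl + 1) ** 2 for lvl, _ in zones
        ) / n_z,
        "High intensity emphasis": sum(
            (lvl + 1) ** 2 for lvl, _ in zones
        ) / n_z,
        "Small area low intensity emphasis": sum(
            1 / ((lvl + 1) ** 2 * s**2) for lvl, s in zones
        ) / n_z,
        "Small area high intensity emphasis": sum(
            (lvl + 1) ** 2 / s**2 for lvl, s in zones
        ) / n_z,
        "Large area low intensity emphasis": sum(
            s**2 / (lvl + 1) ** 2 for lvl, s in zones
        ) / n_z,
        "Large area high intensity emphasis": sum(
            (lvl + 1) ** 2 * s**2 for lvl, s in zones
        ) / n_z,
    }
    return {n: float(f[n]) for n in names}


def naive_first_order(values):
    """13 first-order statistics by direct formula evaluation."""
    x = [float(v) for v in values]
    n = len(x)
    mu = sum(x) / n
    var = sum((v - mu) ** 2 for v in x) / n
    sd = math.sqrt(var)
    xs = sorted(x)
    median = (
        xs[n // 2] if n % 2 else 0.5 * (xs[n // 2 - 1] + xs[n // 2])
    )
    counts: dict[float, int] = {}
    for v in x:
        counts[v] = counts.get(v, 0) + 1
    pk = [c / n for c in counts.values()]
    nan = float("nan")
    return {
        "Energy": sum(v**2 for v in x),
        "Entropy": -sum(p * math.log2(p) for p in pk),
        "Kurtosis": (
            sum((v - mu) ** 4 for v in x) / n / var**2 if var > 0 else nan
        ),
        "Maximum": max(x),
        "Mean": mu,
        "Mean deviation": sum(abs(v - mu) for v in x) / n,
        "Median": median,
        "Minimum": min(x),
        "RMS": math.sqrt(sum(v**2 for v in x) / n),
        "Skewness": (
            sum((v - mu) ** 3 for v in x) / n / sd**3 if sd > 0 else nan
        ),
        "Standard deviation": sd,
        "Uniformity": sum(p**2 for p in pk),
        "Variance": var,
    }


def naive_discretize(values, n_levels=9):
    lo, hi = min(values), max(values)
    if hi == lo:
        return [0 for _ in values]
    return [
        min(n_levels - 1, math.floor(n_levels * (v - lo) / (hi - lo)))
        for v in values
    ]
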