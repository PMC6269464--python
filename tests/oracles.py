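"""Independent brute-force oracles used only by the test suite.

Everything here works on explicit Python sets of voxel coordinates so that
no scipy/vectorized code path is shared with the implementation under test.
"""

from __future__ import annotations

import itertools

import numpy as np

FACE6_OFFSETS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
ALL26_OFFSETS = [
    o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)
]
EDGE18_OFFSETS = [o for o in ALL26_OFFSETS if sum(abs(c) for c in o) <= 2]


def offsets_for(element_name: str) -> list[tuple[int, int, int]]:
    return {
        "FACE6": FACE6_OFFSETS,
        "EDGE18": EDGE18_OFFSETS,
        "FULL26": ALL26_OFFSETS,
    }[element_name]


def set_dilate(voxels: set, offsets, shape) -> set:
    """One dilation step by explicit neighbor enumeration, clipped to shape."""
    out = set(voxels)
    for z, y, x in voxels:
        for dz, dy, dx in offsets:
            nz, ny, nx = z + dz, y + dy, x + dx
            if 0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2]:
                out.add((nz, ny, nx))
    return out


def set_cycles_to_fill(voxels: set, pattern_names: list[str], shape, target: float) -> int:
    """Cycle count to reach the target fill using set arithmetic."""
    total = shape[0] * shape[1] * shape[2]
    current = set(voxels)
    cycles = 0
    while len(current) / total < target:
        offsets = offsets_for(pattern_names[cycles % len(pattern_names)])
        current = set_dilate(current, offsets, shape)
        cycles += 1
    return cycles


def components_2d(mask: np.ndarray, connectivity8: bool = True) -> list[set]:
    """2D connected components by breadth-first flood fill."""
    if connectivity8:
        offs = [o for o in itertools.product((-1, 0, 1), repeat=2) if o != (0, 0)]
    else:
        offs = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    seen = set()
    comps = []
    coords = {tuple(c) for c in np.argwhere(mask)}
    for start in sorted(coords):
        if start in seen:
            continue
        comp = {start}
        frontier = [start]
        while frontier:
            y, x = frontier.pop()
            for dy, dx in offs:
                n = (y + dy, x + dx)
                if n in coords and n not in comp:
                    comp.add(n)
                    frontier.append(n)
        seen |= comp
        comps.append(comp)
    return comps


def components_3d_26(mask: np.ndarray) -> list[set]:
    """3D 26-connected components by flood fill."""
    offs = ALL26_OFFSETS
    coords = {tuple(c) for c in np.argwhere(mask)}
    seen = set()
    comps = []
    for start in sorted(coords):
        if start in seen:
            continue
        comp = {start}
        frontier = [start]
        while frontier:
            z, y, x = frontier.pop()
            for dz, dy, dx in offs:
                n = (z + dz, y + dy, x + dx)
                if n in coords and n not in comp:
                    comp.add(n)
                    frontier.append(n)
        seen |= comp
        comps.append(comp)
    return comps


def min_cross_section_voxels(mask: np.ndarray, z: int, y: int, x: int) -> int:
    """Minimal per-plane component size through one voxel, by flood fill."""
    assert mask[z, y, x]
    sizes = []
    for plane, idx in (("xy", z), ("xz", y), ("yz", x)):
        if plane == "xy":
            sl = mask[idx, :, :]
            pos = (y, x)
        elif plane == "xz":
            sl = mask[:, idx, :]
            pos = (z, x)
        else:
            sl = mask[:, :, idx]
            pos = (z, y)
        for comp in components_2d(sl):
            if pos in comp:
                sizes.append(len(comp))
                break
    return min(sizes)


def fill_holes_2d(mask: np.ndarray) -> np.ndarray:
    """Fill background not connected (4-conn) to the slice border."""
    h, w = mask.shape
    reachable = set()
    frontier = []
    for y in range(h):
        for x in range(w):
            if (y in (0, h - 1) or x in (0, w - 1)) and not mask[y, x]:
                reachable.add((y, x))
                frontier.append((y, x))
    while frontier:
        y, x = frontier.pop()
        for dy, dx in [(1, 0), (-1, 0), (0, 1), (0, -1)]:
            n = (y + dy, x + dx)
            if 0 <= n[0] < h and 0 <= n[1] < w and not mask[n] and n not in reachable:
                reachable.add(n)
                frontier.append(n)
    out = mask.copy()
    for y in range(h):
        for x in range(w):
            if not mask[y, x] and (y, x) not in reachable:
                out[y, x] = True
    return out


def ols_normal_equations(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, R² from the closed-form normal equations."""
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    resid = y - (slope * x + intercept)
    ss_res = (resid ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    return float(slope), float(intercept), float(1 - ss_res / ss_tot)


def two_sample_t(a: np.ndarray, b: np.ndarray) -> float:
    """Unpaired two-sample t statistic with pooled variance (closed form)."""
    na, nb = len(a), len(b)
    va = ((a - a.mean()) ** 2).sum() / (na - 1)
    vb = ((b - b.mean()) ** 2).sum() / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    return float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb)))
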