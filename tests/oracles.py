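"""Brute-force reference implementations used as independent oracles.

Deliberately slow and simple: flood-fill segmentation, exhaustive prominence
computation for maxima counting, and exhaustive enumeration of particle
matchings. They share no code with the package implementations they check.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np

NEIGH8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
NEIGH4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]


def _flood(start, member, visited, shape, neigh):
    h, w = shape
    comp = []
    q = deque([start])
    visited.add(start)
    while q:
        y, x = q.popleft()
        comp.append((y, x))
        for dy, dx in neigh:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and (ny, nx) not in visited and member(ny, nx):
                visited.add((ny, nx))
                q.append((ny, nx))
    return comp


def flood_fill_particles(
    image: np.ndarray,
    threshold: float,
    min_size: int = 10,
    fill_holes: bool = True,
    max_area_fraction: float = 0.5,
) -> set[frozenset]:
    """Reference segmentation: threshold (inclusive) -> fill holes -> 8-conn
    components -> size filters. Returns the set of particle pixel sets."""
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    fg = image >= threshold

    if fill_holes:
        # holes = background components (4-connectivity, the complement of
        # 8-connected foreground) not reachable from the border
        visited: set = set()
        reachable: set = set()
        for y in range(h):
            for x in (0, w - 1):
                if not fg[y, x] and (y, x) not in visited:
                    reachable.update(
                        _flood((y, x), lambda a, b: not fg[a, b], visited, (h, w), NEIGH4)
                    )
        for x in range(w):
            for y in (0, h - 1):
                if not fg[y, x] and (y, x) not in visited:
                    reachable.update(
                        _flood((y, x), lambda a, b: not fg[a, b], visited, (h, w), NEIGH4)
                    )
        fg = fg.copy()
        for y in range(h):
            for x in range(w):
                if not fg[y, x] and (y, x) not in reachable:
                    fg[y, x] = True

    visited = set()
    out = set()
    for y in range(h):
        for x in range(w):
            if fg[y, x] and (y, x) not in visited:
                comp = _flood((y, x), lambda a, b: fg[a, b], visited, (h, w), NEIGH8)
                if min_size <= len(comp) <= max_area_fraction * h * w:
                    out.add(frozenset(comp))
    return out


def _plateaus(image: np.ndarray):
    """Connected equal-value regions with no strictly higher 8-neighbour."""
    h, w = image.shape
    visited: set = set()
    plateaus = []
    for y in range(h):
        for x in range(w):
            if (y, x) in visited:
                continue
            v = image[y, x]
            comp = _flood(
                (y, x), lambda a, b: image[a, b] == v, visited, (h, w), NEIGH8
            )
            is_max = True
            for cy, cx in comp:
                for dy, dx in NEIGH8:
                    ny, nx = cy + dy, cx + dx
                    if 0 <= ny < h and 0 <= nx < w and image[ny, nx] > v:
                        is_max = False
                        break
                if not is_max:
                    break
            if is_max and len(comp) < h * w:
                plateaus.append((float(v), comp))
    return plateaus


def prominence_maxima_count(image: np.ndarray, tolerance: float) -> int:
    """Reference maxima count: a maximal plateau with peak v is counted
    unless the connected component of {image >= v - tolerance} containing it
    holds a strictly higher pixel; equal maxima sharing that component merge
    into one count."""
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    counted: set[frozenset] = set()
    for v, comp in _plateaus(image):
        visited: set = set()
        region = _flood(
            comp[0],
            lambda a, b: image[a, b] >= v - tolerance,
            visited,
            (h, w),
            NEIGH8,
        )
        if any(image[y, x] > v for y, x in region):
            continue
        counted.add(frozenset(region))
    return len(counted)


def exhaustive_match(coords_a, coords_b, radius):
    """Reference matching: maximum-cardinality then minimum-total-distance
    assignment, found by enumerating all subsets/permutations.

    Returns ``(cardinality, total_distance, pair_set)`` where the pair set
    belongs to one optimal solution.
    """
    coords_a = [tuple(map(float, p)) for p in coords_a]
    coords_b = [tuple(map(float, p)) for p in coords_b]
    na, nb = len(coords_a), len(coords_b)

    def dist(i, j):
        return math.hypot(
            coords_a[i][0] - coords_b[j][0], coords_a[i][1] - coords_b[j][1]
        )

    best = (0, 0.0, frozenset())
    k_max = min(na, nb)
    for k in range(k_max, -1, -1):
        found = None
        for subset_a in itertools.combinations(range(na), k):
            for subset_b in itertools.permutations(range(nb), k):
                total = 0.0
                ok = True
                for i, j in zip(subset_a, subset_b):
                    d = dist(i, j)
                    if d > radius:
                        ok = False
                        break
                    total += d
                if ok and (found is None or total < found[0]):
                    found = (total, frozenset(zip(subset_a, subset_b)))
        if found is not None:
            best = (k, found[0], found[1])
            break
    return best
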