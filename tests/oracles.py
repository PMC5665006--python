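"""Independent brute-force oracles used only by the test suite.

Each function re-derives a quantity from first principles with a
different algorithm than the implementation under test.
"""

from itertools import combinations

import numpy as np


def hull_area_gift_wrapping(points: np.ndarray) -> float:
    """Convex-hull area via gift wrapping + shoelace (no geometry library).

    Degenerate inputs (n < 3 or collinear) have area 0.
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    n = len(pts)
    if n < 3:
        return 0.0
    start = int(np.lexsort((pts[:, 1], pts[:, 0]))[0])
    hull = [start]
    current = start
    while True:
        candidate = (current + 1) % n
        for j in range(n):
            if j == current:
                continue
            u = pts[candidate] - pts[current]
            v = pts[j] - pts[current]
            cross = u[0] * v[1] - u[1] * v[0]
            if cross < 0 or (
                cross == 0
                and np.linalg.norm(pts[j] - pts[current])
                > np.linalg.norm(pts[candidate] - pts[current])
            ):
                candidate = j
        current = candidate
        if current == start:
            break
        hull.append(current)
        if len(hull) > n:  # safety against numerical cycling
            break
    xy = pts[hull]
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def aoo_cells_enumeration(points: np.ndarray, cell: float = 2000.0) -> int:
    """Distinct occupied 2-km cells by direct floor-division enumeration."""
    return len({(int(np.floor(x / cell)), int(np.floor(y / cell))) for x, y in points})


def point_in_polygon_raycast(x: float, y: float, ring: np.ndarray) -> bool:
    """Even-odd ray casting; points exactly on an edge count as inside."""
    n = len(ring)
    inside = False
    for i in range(n):
        x1, y1 = ring[i]
        x2, y2 = ring[(i + 1) % n]
        # on-edge check
        d = abs((x2 - x1) * (y - y1) - (y2 - y1) * (x - x1))
        if d < 1e-12 and min(x1, x2) - 1e-12 <= x <= max(x1, x2) + 1e-12 and min(y1, y2) - 1e-12 <= y <= max(y1, y2) + 1e-12:
            return True
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xint:
                inside = not inside
    return inside


def nearest_data_cell_scan(point, mask: np.ndarray, cell_size: float, origin) -> tuple:
    """Exhaustive nearest-data-cell search over the whole grid."""
    best, best_d = None, np.inf
    x0, ytop = origin
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if not mask[r, c]:
                continue
            cx = x0 + (c + 0.5) * cell_size
            cy = ytop - (r + 0.5) * cell_size
            d = (cx - point[0]) ** 2 + (cy - point[1]) ** 2
            if d < best_d:
                best, best_d = (cx, cy), d
    return best


def max_independent_set_size(dist: np.ndarray, threshold: float) -> int:
    """Largest subset with all pairwise distances >= threshold, by 2^n scan."""
    n = len(dist)
    best = 0
    for mask in range(1, 1 << n):
        members = [i for i in range(n) if mask >> i & 1]
        if len(members) <= best:
            continue
        if all(dist[i, j] >= threshold for i, j in combinations(members, 2)):
            best = len(members)
    return best


def flood_fill(binary: np.ndarray, seed_rc: tuple, connectivity: int = 8) -> set:
    """BFS flood fill over True cells from a seed; returns the component."""
    rows, cols = binary.shape
    if connectivity == 8:
        moves = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        moves = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = set()
    frontier = [seed_rc]
    while frontier:
        r, c = frontier.pop()
        if (r, c) in seen or not (0 <= r < rows and 0 <= c < cols) or not binary[r, c]:
            continue
        seen.add((r, c))
        frontier.extend((r + dr, c + dc) for dr, dc in moves)
    return seen


def auc_pair_enumeration(presence, background) -> float:
    """AUC by enumerating all presence/background pairs, ties as 1/2."""
    wins = ties = 0
    for p in presence:
        for b in background:
            if p > b:
                wins += 1
            elif p == b:
                ties += 1
    return (wins + 0.5 * ties) / (len(presence) * len(background))


def morans_i(grid: np.ndarray) -> float:
    """Moran's I with rook adjacency on a full grid."""
    z = grid - grid.mean()
    num = 0.0
    w = 0
    rows, cols = grid.shape
    for r in range(rows):
        for c in range(cols):
            for dr, dc in ((0, 1), (1, 0)):
                r2, c2 = r + dr, c + dc
                if r2 < rows and c2 < cols:
                    num += 2 * z[r, c] * z[r2, c2]
                    w += 2
    return (grid.size / w) * num / np.sum(z**2)
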