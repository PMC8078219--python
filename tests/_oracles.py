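"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive (O(n^2) scans, explicit loops, no
shared code with the implementation) so agreement is evidence, not
tautology.
"""

import numpy as np


def point_in_polygon(px: float, py: float, vertices) -> bool:
    """Even-odd ray casting with an explicit boundary check (boundary counts
    as inside, matching the package's convention)."""
    verts = [(float(x), float(y)) for x, y in vertices]
    n = len(verts)
    eps = 1e-9
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        if (abs(cross) <= eps * max(1.0, abs(x2 - x1) + abs(y2 - y1))
                and min(x1, x2) - eps <= px <= max(x1, x2) + eps
                and min(y1, y2) - eps <= py <= max(y1, y2) + eps):
            return True
    inside = False
    j = n - 1
    for i in range(n):
        xi, yi = verts[i]
        xj, yj = verts[j]
        if (yi > py) != (yj > py):
            x_int = (xj - xi) * (py - yi) / (yj - yi) + xi
            if px < x_int:
                inside = not inside
        j = i
    return inside


def brute_dbscan(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Reachability-closure DBSCAN from the definition: full distance matrix,
    cores expanded in ascending index order, borders claimed by the first
    cluster discovered."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    labels = np.full(n, -1, dtype=np.int64)
    if n == 0:
        return labels
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
    neighbors = [np.nonzero(d[i] <= eps)[0] for i in range(n)]  # self included
    core = np.array([len(nb) >= min_pts for nb in neighbors])
    cluster = 0
    for seed in range(n):
        if not core[seed] or labels[seed] != -1:
            continue
        frontier = [seed]
        labels[seed] = cluster
        while frontier:
            i = frontier.pop()
            for j in neighbors[i]:
                if labels[j] == -1:
                    labels[j] = cluster
                    if core[j]:
                        frontier.append(int(j))
        cluster += 1
    return labels


def summarize(values: np.ndarray) -> dict:
    """Independent per-column summary (plain numpy, no pandas)."""
    v = np.asarray(values, dtype=float)
    return {"mean": float(np.mean(v)), "median": float(np.median(v)),
            "min": float(np.min(v)), "max": float(np.max(v))}
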