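"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's implementation paths: plain-Python
loops and fixed-point relaxation instead of vectorized scans and BFS
queues, so that agreement is evidence of correctness rather than of shared
code.
"""

from __future__ import annotations

import math

import numpy as np

NEIGHBORS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def otsu_bruteforce(hist) -> int:
    """Exhaustive search over all 256 thresholds for the between-class
    variance maximum (classes <= t vs > t; smallest t wins ties)."""
    hist = [float(h) for h in hist]
    total = sum(hist)
    best_t, best_v = 0, -1.0
    for t in range(len(hist)):
        n0 = sum(hist[: t + 1])
        n1 = total - n0
        if n0 == 0 or n1 == 0:
            v = 0.0
        else:
            mu0 = sum(i * hist[i] for i in range(t + 1)) / n0
            mu1 = sum(i * hist[i] for i in range(t + 1, len(hist))) / n1
            v = (n0 / total) * (n1 / total) * (mu0 - mu1) ** 2
        if v > best_v + 1e-12:
            best_t, best_v = t, v
    return best_t


def gaussian_kernel_1d(sigma: float) -> list[float]:
    """Sampled, normalized 1-D Gaussian truncated at radius ceil(3*sigma)."""
    radius = math.ceil(3.0 * sigma)
    w = [math.exp(-0.5 * (x / sigma) ** 2) for x in range(-radius, radius + 1)]
    s = sum(w)
    return [x / s for x in w]


def ramanujan_ellipse_roundness(a: float, b: float) -> float:
    """4*pi*A/S^2 with Ramanujan's ellipse-perimeter approximation."""
    per = math.pi * (3 * (a + b) - math.sqrt((3 * a + b) * (a + 3 * b)))
    return 4.0 * math.pi * (math.pi * a * b) / per ** 2


def flood_bruteforce(grad: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Level-by-level watershed flood by fixed-point relaxation.

    Semantics match the production convention: per ascending level, each
    unassigned plateau component either seeds a new basin (no adjacent
    basin), joins its unique adjacent basin, or is divided among several
    adjacent basins by geodesic distance inside the plateau with ties
    becoming watershed-line pixels (-1).  Implemented with plain loops and
    repeated sweeps until convergence.
    """
    h, w = grad.shape
    labels = np.zeros((h, w), dtype=np.int64)
    nxt = 1
    inside = lambda r, c: 0 <= r < h and 0 <= c < w

    for level in sorted({float(grad[r, c]) for r in range(h) for c in range(w) if mask[r, c]}):
        todo = {(r, c) for r in range(h) for c in range(w)
                if mask[r, c] and labels[r, c] == 0 and float(grad[r, c]) == level}
        # split todo into connected components by naive agglomeration
        comps: list[set] = []
        pool = set(todo)
        while pool:
            comp = {pool.pop()}
            grew = True
            while grew:
                grew = False
                for (r, c) in list(pool):
                    for dr, dc in NEIGHBORS8:
                        if (r + dr, c + dc) in comp:
                            comp.add((r, c))
                            pool.discard((r, c))
                            grew = True
                            break
            comps.append(comp)
        for comp in comps:
            adj = set()
            for (r, c) in comp:
                for dr, dc in NEIGHBORS8:
                    rr, cc = r + dr, c + dc
                    if inside(rr, cc) and labels[rr, cc] > 0:
                        adj.add(int(labels[rr, cc]))
            if not adj:
                for (r, c) in comp:
                    labels[r, c] = nxt
                nxt += 1
                continue
            if len(adj) == 1:
                b = adj.pop()
                for (r, c) in comp:
                    labels[r, c] = b
                continue
            # geodesic distances to each adjacent basin: Bellman-Ford sweeps
            INF = float("inf")
            dist = {b: {p: INF for p in comp} for b in adj}
            for b in adj:
                for (r, c) in comp:
                    for dr, dc in NEIGHBORS8:
                        rr, cc = r + dr, c + dc
                        if inside(rr, cc) and labels[rr, cc] == b:
                            dist[b][(r, c)] = 1.0
                changed = True
                while changed:
                    changed = False
                    for p in comp:
                        r, c = p
                        for dr, dc in NEIGHBORS8:
                            q = (r + dr, c + dc)
                            if q in dist[b] and dist[b][q] + 1 < dist[b][p]:
                                dist[b][p] = dist[b][q] + 1
                                changed = True
            for p in comp:
                ds = sorted((dist[b][p], b) for b in adj)
                if ds[0][0] == INF:
                    # unreachable from any basin: its own new basin is
                    # impossible inside a component adjacent to basins
                    labels[p] = -1
                elif len(ds) > 1 and ds[0][0] == ds[1][0]:
                    labels[p] = -1
                else:
                    labels[p] = ds[0][1]
    return labels


def partitions_match(lab_a: np.ndarray, lab_b: np.ndarray) -> bool:
    """Same basin partition up to label permutation, ignoring pixels that
    are watershed lines in either labeling."""
    a = np.asarray(lab_a)
    b = np.asarray(lab_b)
    keep = (a > 0) & (b > 0)
    if (a > 0).sum() == 0 and (b > 0).sum() == 0:
        return True
    n_a = len(np.unique(a[a > 0]))
    n_b = len(np.unique(b[b > 0]))
    if n_a != n_b:
        return False
    fwd: dict[int, int] = {}
    rev: dict[int, int] = {}
    for va, vb in zip(a[keep].ravel(), b[keep].ravel()):
        va, vb = int(va), int(vb)
        if fwd.setdefault(va, vb) != vb:
            return False
        if rev.setdefault(vb, va) != va:
            return False
    return True
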