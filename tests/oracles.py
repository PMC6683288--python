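"""Independent brute-force oracles used only by the tests.

Each oracle recomputes a quantity the package computes, by a different and
deliberately naive route: facet enumeration for convex hulls, pairwise
distances for the periventricular rule, normal equations for OLS, a
grid-refined likelihood search for logistic regression, and textbook
sum-of-squares / contingency formulas for ANOVA and chi-square.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


# ---------------------------------------------------------------------------
# convex hull by facet enumeration (O(n^4); fine for n <~ 100 points)

def _jarvis_march(xy: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """2D convex-polygon vertices by gift wrapping (counterclockwise)."""
    xy = np.unique(np.round(xy, 9), axis=0)
    if len(xy) <= 3:
        return xy
    start = np.lexsort((xy[:, 1], xy[:, 0]))[0]
    hull = [start]
    while True:
        p = hull[-1]
        q = (p + 1) % len(xy)
        for r in range(len(xy)):
            if r == p:
                continue
            a, b = xy[q] - xy[p], xy[r] - xy[p]
            cross = a[0] * b[1] - a[1] * b[0]
            d_q = np.linalg.norm(xy[q] - xy[p])
            d_r = np.linalg.norm(xy[r] - xy[p])
            if cross < -tol or (abs(cross) <= tol and d_r > d_q):
                q = r
        if q == start:
            break
        hull.append(q)
    return xy[hull]

def brute_force_hull(points: np.ndarray, tol: float = 1e-9) -> tuple[float, float]:
    """Hull volume and area: every point triple whose plane supports the whole
    set is a facet plane; faces are the in-plane convex polygons of the points
    on each plane; volume is the sum of pyramids to the interior centroid."""
    pts = np.asarray(points, float)
    n = len(pts)
    scale = np.ptp(pts, axis=0).max()
    tol = tol * max(scale, 1.0)
    planes = {}
    for i, j, k in combinations(range(n), 3):
        normal = np.cross(pts[j] - pts[i], pts[k] - pts[i])
        norm = np.linalg.norm(normal)
        if norm < 1e-12:
            continue
        normal = normal / norm
        s = (pts - pts[i]) @ normal
        if s.max() <= tol:
            nrm, off = normal, float(normal @ pts[i])
        elif s.min() >= -tol:
            nrm, off = -normal, float(-normal @ pts[i])
        else:
            continue
        key = tuple(np.round(np.r_[nrm, off], 7))
        planes.setdefault(key, (nrm, off))

    centroid = pts.mean(axis=0)
    area = 0.0
    volume = 0.0
    for nrm, off in planes.values():
        on = pts[np.abs(pts @ nrm - off) <= 10 * tol]
        if len(on) < 3:
            continue
        # orthonormal in-plane basis
        u = np.cross(nrm, [1.0, 0.0, 0.0])
        if np.linalg.norm(u) < 1e-6:
            u = np.cross(nrm, [0.0, 1.0, 0.0])
        u /= np.linalg.norm(u)
        v = np.cross(nrm, u)
        ctr2 = on.mean(axis=0)
        xy = np.column_stack([(on - ctr2) @ u, (on - ctr2) @ v])
        xy = _jarvis_march(xy)  # drop points interior to the face polygon
        face_area = 0.5 * abs(
            np.sum(xy[:, 0] * np.roll(xy[:, 1], -1) - np.roll(xy[:, 0], -1) * xy[:, 1])
        )
        area += face_area
        volume += face_area * (off - centroid @ nrm) / 3.0
    return volume, area


def points_in_hull(points: np.ndarray, query: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Half-space membership test against the brute-force supporting planes."""
    pts = np.asarray(points, float)
    n = len(pts)
    inside = np.ones(len(query), bool)
    for i, j, k in combinations(range(n), 3):
        normal = np.cross(pts[j] - pts[i], pts[k] - pts[i])
        norm = np.linalg.norm(normal)
        if norm < 1e-12:
            continue
        normal = normal / norm
        s = (pts - pts[i]) @ normal
        if s.max() <= tol:
            inside &= (query - pts[i]) @ normal <= tol
        elif s.min() >= -tol:
            inside &= (query - pts[i]) @ normal >= -tol
    return inside


# ---------------------------------------------------------------------------
# distances

def brute_force_min_distances(
    lesion_idx: np.ndarray, ventricle_idx: np.ndarray, spacing
) -> np.ndarray:
    """Min Euclidean mm distance from each lesion voxel center to any
    ventricle voxel center, by explicit pairwise computation."""
    spacing = np.asarray(spacing, float)
    a = lesion_idx * spacing
    b = ventricle_idx * spacing
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    return np.sqrt(d2.min(axis=1))


# ---------------------------------------------------------------------------
# regression

def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """beta-hat = (X'X)^-1 X'y."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    return np.linalg.solve(X.T @ X, X.T @ y)


def logistic_loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    eta = X @ beta
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def logistic_mle_grid(
    X: np.ndarray, y: np.ndarray, rounds: int = 250, width: float = 8.0,
    shrink: float = 0.93,
) -> np.ndarray:
    """Maximize the Bernoulli likelihood by coordinatewise grid refinement —
    slow, derivative-free, and independent of any optimizer library.  Sweeps
    coordinates until no grid point improves, then shrinks the grid width."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    beta = np.zeros(X.shape[1])
    for _ in range(rounds):
        improved = True
        while improved:
            improved = False
            for j in range(len(beta)):
                grid = beta[j] + np.linspace(-width, width, 33)
                lls = [
                    logistic_loglik(np.r_[beta[:j], g, beta[j + 1:]], X, y)
                    for g in grid
                ]
                best = grid[int(np.argmax(lls))]
                if best != beta[j]:
                    beta[j] = best
                    improved = True
        width *= shrink
    return beta


# ---------------------------------------------------------------------------
# classical tests

def anova_f(groups: list[np.ndarray]) -> float:
    """Textbook one-way ANOVA F from between/within sums of squares."""
    groups = [np.asarray(g, float) for g in groups]
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = sum(len(g) for g in groups) - len(groups)
    return float((ss_between / df_b) / (ss_within / df_w))


def chi2_statistic(table: np.ndarray) -> float:
    """Pearson chi-square from observed and product-margin expected counts."""
    table = np.asarray(table, float)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))
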